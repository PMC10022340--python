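import numpy as np
import pandas as pd
import pytest

from swdea.panel import PanelDataset


@pytest.fixture
def toy_abc():
    """Three equal-input DMUs: A and B span the frontier, C sits inside."""
    x = np.array([1.0, 1.0, 1.0])
    Y = np.array([[2.0, 1.0], [1.0, 2.0], [1.0, 1.0]])
    return x, Y


def make_panel(n_countries=6, years=(2010, 2011, 2012), covariates=("z1", "z2"),
               seed=0, missing_rate=0.0):
    """A small, valid panel for I/O and imputation tests."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_countries):
        for yr in years:
            rows.append({
                "country_code": f"C{i:02d}", "year": yr,
                "spend_total": rng.uniform(1e5, 1e7),
                "plhiv": rng.integers(100, 100000),
                "pct_art": rng.uniform(5, 95),
                "pct_pmtct": rng.uniform(5, 95),
                **{c: rng.normal() for c in covariates},
                "who_region": rng.choice(["AFRO", "EURO"]),
                "unaids_region": rng.choice(["ESA", "LAC"]),
                "income_group": rng.choice(["low", "high"]),
            })
    df = pd.DataFrame(rows)
    if missing_rate:
        for c in covariates:
            holes = rng.uniform(size=len(df)) < missing_rate
            df.loc[holes, c] = np.nan
    return PanelDataset(df, list(covariates))


@pytest.fixture
def small_panel():
    return make_panel()
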