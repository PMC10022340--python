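"""Panel model, I/O round-trips, income classification, diagnostics."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_panel
from swdea.exceptions import DomainError, IntegrityError, SchemaError
from swdea.panel import (PanelDataset, classify_income, derive_input,
                         diagnostics, load_panel, write_panel)


class TestIO:
    def test_load_three_row_csv(self, tmp_path):
        p = tmp_path / "panel.csv"
        p.write_text(
            "country_code,year,spend_total,plhiv,pct_art,pct_pmtct,z1,"
            "who_region,unaids_region,income_group\n"
            "KEN,2010,1000000,2000,35.5,60.0,0.1,AFRO,ESA,low\n"
            "KEN,2011,1100000,2100,38.0,62.0,,AFRO,ESA,low\n"
            "BRA,2010,9000000,50000,55.0,80.0,-0.3,AMRO,LAC,upper-middle\n"
        )
        panel = load_panel(p)
        assert len(panel) == 3
        assert panel.covariates == ["z1"]
        assert panel.missingness_mask()["z1"].sum() == 1

    def test_round_trip_preserves_values(self, tmp_path):
        panel = make_panel(missing_rate=0.2, seed=3)
        f1, f2 = tmp_path / "a.csv", tmp_path / "b.csv"
        write_panel(panel, f1)
        write_panel(load_panel(f1), f2)
        assert f1.read_bytes() == f2.read_bytes()
        re = load_panel(f1)
        for c in ("year", "plhiv"):
            np.testing.assert_array_equal(re.df[c], panel.df[c])
        for c in ("spend_total", "pct_art", "pct_pmtct", "z1", "z2"):
            np.testing.assert_allclose(re.df[c], panel.df[c], rtol=1e-12)

    def test_schema_mapping_and_missing_column(self, tmp_path):
        p = tmp_path / "odd.csv"
        p.write_text("iso3,yr,spend_total,plhiv,pct_art,pct_pmtct\n"
                     "UGA,2012,5e5,1000,40,70\n")
        panel = load_panel(p, schema={"iso3": "country_code", "yr": "year"})
        assert panel.df.loc[0, "country_code"] == "UGA"
        with pytest.raises(SchemaError, match="missing required"):
            load_panel(p)

    def test_duplicate_country_year_rejected(self):
        df = make_panel().df
        dup = pd.concat([df, df.iloc[[0]]], ignore_index=True)
        with pytest.raises(IntegrityError, match=r"C00.*2010"):
            PanelDataset(dup, ["z1", "z2"])

    def test_out_of_range_percent_reported_with_row(self):
        df = make_panel().df
        df.loc[2, "pct_art"] = 120.0
        from swdea.exceptions import PanelValidationError
        with pytest.raises(PanelValidationError) as exc:
            PanelDataset(df, ["z1", "z2"])
        assert exc.value.rows[0][0] == 2


class TestDeriveInput:
    @pytest.mark.parametrize("spend,plhiv,expected", [
        (1_000_000, 2_000, 500.0),
        (0.0, 50, 0.0),
        (488.25e6, 1e6, 488.25),
    ])
    def test_per_person_spend(self, spend, plhiv, expected):
        assert derive_input(spend, plhiv) == pytest.approx(expected)

    def test_nonpositive_plhiv_rejected(self):
        with pytest.raises(DomainError):
            derive_input(100.0, 0)


class TestClassifyIncome:
    @pytest.mark.parametrize("gni,group", [
        (0, "low"), (1045, "low"), (1046, "lower-middle"),
        (4095, "lower-middle"), (4096, "upper-middle"),
        (12695, "upper-middle"), (12696, "high"), (50000, "high"),
    ])
    def test_world_bank_thresholds(self, gni, group):
        assert classify_income(gni) == group

    def test_negative_gni_rejected(self):
        with pytest.raises(DomainError):
            classify_income(-1.0)

    def test_vectorised(self):
        out = classify_income([500, 2000, 9000, 20000])
        assert list(out) == ["low", "lower-middle", "upper-middle", "high"]


def panel_with_covariates(C, seed=0):
    """Wrap a covariate matrix into a minimal valid panel."""
    rng = np.random.default_rng(seed)
    n, p = C.shape
    df = pd.DataFrame({
        "country_code": [f"C{i:04d}" for i in range(n)],
        "year": 2015,
        "spend_total": rng.uniform(1e5, 1e6, n),
        "plhiv": rng.integers(100, 10000, n),
        "pct_art": rng.uniform(10, 90, n),
        "pct_pmtct": rng.uniform(10, 90, n),
    })
    names = [f"z{j}" for j in range(p)]
    df[names] = C
    return PanelDataset(df, names)


class TestDiagnostics:
    def test_independent_covariates_have_unit_vif(self):
        rng = np.random.default_rng(0)
        panel = panel_with_covariates(rng.normal(size=(1000, 2)))
        rep = diagnostics(panel)
        assert rep.vif["z0"] == pytest.approx(1.0, abs=0.05)
        assert rep.vif["z1"] == pytest.approx(1.0, abs=0.05)
        assert not rep.flagged_pairs
        assert np.allclose(np.diag(rep.pearson), 1.0)

    def test_duplicated_covariate_flagged_infinite(self):
        rng = np.random.default_rng(1)
        z = rng.normal(size=200)
        panel = panel_with_covariates(np.column_stack([z, z, rng.normal(size=200)]))
        rep = diagnostics(panel)
        assert any({a, b} == {"z0", "z1"} for a, b, _ in rep.flagged_pairs)
        assert rep.vif["z0"] > 1e6

    def test_constant_covariate_reported_infinite(self):
        rng = np.random.default_rng(2)
        panel = panel_with_covariates(
            np.column_stack([np.full(50, 3.0), rng.normal(size=50)]))
        rep = diagnostics(panel)
        assert np.isinf(rep.vif["z0"])
        assert any(a == b == "z0" for a, b, _ in rep.flagged_pairs)

    @pytest.mark.parametrize("seed", range(4))
    def test_vif_equals_one_over_one_minus_r2(self, seed):
        rng = np.random.default_rng(10 + seed)
        n = 40
        base = rng.normal(size=(n, 2))
        third = 0.6 * base[:, 0] + 0.8 * rng.normal(size=n)
        panel = panel_with_covariates(np.column_stack([base, third]))
        rep = diagnostics(panel)
        C = panel.df[["z0", "z1", "z2"]].to_numpy()
        for j, name in enumerate(["z0", "z1", "z2"]):
            others = np.column_stack(
                [np.ones(n), np.delete(C, j, axis=1)])
            beta, *_ = np.linalg.lstsq(others, C[:, j], rcond=None)
            resid = C[:, j] - others @ beta
            r2 = 1 - resid.var() / C[:, j].var()
            assert rep.vif[name] == pytest.approx(1 / (1 - r2), rel=1e-6)

    def test_affine_rescaling_leaves_diagnostics_unchanged(self):
        rng = np.random.default_rng(20)
        C = rng.normal(size=(80, 3))
        p1 = panel_with_covariates(C, seed=5)
        C2 = C.copy()
        C2[:, 1] = 1e4 * C2[:, 1] - 77.0
        p2 = panel_with_covariates(C2, seed=5)
        r1, r2 = diagnostics(p1), diagnostics(p2)
        np.testing.assert_allclose(np.abs(r1.pearson), np.abs(r2.pearson),
                                   atol=1e-10)
        np.testing.assert_allclose(r1.vif, r2.vif, rtol=1e-8)

    def test_isotonicity_correlation_recovers_generator_truth(self):
        # bivariate-normal link with rho = 0.2 between spend and outputs
        rng = np.random.default_rng(30)
        n = 581
        rho = 0.2
        u = rng.normal(size=n)
        df = pd.DataFrame({
            "country_code": [f"C{i:04d}" for i in range(n)],
            "year": 2015,
            "plhiv": 1,
            "spend_total": 500 + 100 * u,
            "pct_art": np.clip(
                50 + 10 * (rho * u + np.sqrt(1 - rho**2) * rng.normal(size=n)),
                0, 100),
            "pct_pmtct": np.clip(
                50 + 10 * (rho * u + np.sqrt(1 - rho**2) * rng.normal(size=n)),
                0, 100),
            "z0": rng.normal(size=n),
        })
        rep = diagnostics(PanelDataset(df, ["z0"]))
        assert rep.input_output_corr["pct_art"] == pytest.approx(rho, abs=0.1)
        assert rep.input_output_corr["pct_pmtct"] == pytest.approx(rho, abs=0.1)
        assert set(rep.input_output_corr_by_year.index) == {2015}
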