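"""Synthetic country-year panels with a known production frontier.

The generator emulates the shape of the cross-country HIV-spending panel:
~78 countries observed over 2010-2018, one input (spending per PLHIV,
log-normal within the observed range 45-3,502 USD), two percentage
outputs in (0, 100], about ten weakly correlated covariates, and
covariate-driven inefficiency

    delta_i = z_i' beta_true + eps_i,   eps_i ~ N(0, sigma_true^2)
                                        truncated so delta_i >= 1,

with outputs placed at y_im = g_m(x_i) / delta_i below a monotone concave
frontier g_m(x) = a_m x^{b_m} (0 < b_m < 1) whose peak is calibrated to
100.  Ground truth (frontier parameters, true distances, true beta/sigma)
is returned alongside the panel so every pipeline stage can be tested for
parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr, spearmanr

from .exceptions import DomainError, GenerationError, IntegrityError
from .panel import PanelDataset, classify_income
from .truncreg import draw_truncated_normal

__all__ = ["SyntheticTruth", "generate_panel", "recovery_metrics",
           "BASE_COVARIATES", "AUX_COVARIATES"]

BASE_COVARIATES = [
    "rule_of_law", "anc_coverage", "gni_pc", "che_gdp", "che_pc",
    "pop_density", "hdi", "hiv_prev", "oop_share", "dahs_ratio",
]
AUX_COVARIATES = [
    "nurses_per_10k", "health_posts_per_100k", "gov_share", "external_che",
]

_WHO_REGIONS = ["AFRO", "AMRO", "EMRO", "EURO", "SEARO", "WPRO"]
_UNAIDS_REGIONS = ["ESA", "WCA", "AP", "EECA", "LAC", "MENA", "WCENA"]

# frontier exponents per output; concave (VRS-compatible) and gentle enough
# that the input-output correlation lands in the weak-positive band seen in
# cross-country spending data
_FRONTIER_B = (0.14, 0.10)
_X_RANGE = (45.0, 3502.0)


@dataclass
class SyntheticTruth:
    frontier_a: np.ndarray
    frontier_b: np.ndarray
    beta_true: np.ndarray
    sigma_true: float
    delta_true: np.ndarray
    missing_rate: float
    seed: int
    dmu_ids: list

    def frontier(self, x):
        """True maximal outputs g_m(x) at input level x."""
        x = np.asarray(x, dtype=float)
        return self.frontier_a * x[..., None] ** self.frontier_b


def _random_correlation(p: int, rng, max_abs: float = 0.7,
                        max_tries: int = 200) -> np.ndarray:
    for _ in range(max_tries):
        G = rng.normal(size=(p, p + 6))
        S = G @ G.T
        d = np.sqrt(np.diag(S))
        C = S / np.outer(d, d)
        off = np.abs(C - np.eye(p)).max()
        if off < max_abs:
            return C
    raise GenerationError(
        f"could not draw a {p}x{p} correlation matrix with max |rho| < {max_abs}"
    )


def generate_panel(
    n_countries: int = 78,
    years=range(2010, 2019),
    beta_true=(1.5, 0.4, -0.4),
    sigma_true: float = 0.3,
    missing_rate: float = 0.15,
    seed: int = 0,
    covariate_names: list[str] | None = None,
    year_effect: float = 0.0,
    group_effects: dict | None = None,
):
    """Generate one country-year panel plus its ground truth.

    Parameters
    ----------
    beta_true : inefficiency coefficients, intercept first; the slope
        coefficients act on the first ``len(beta_true) - 1`` covariates.
    sigma_true : scale of the truncated-normal inefficiency noise; 0 puts
        every unit exactly on the frontier (when the linear predictor is 1).
    missing_rate : MCAR deletion probability per covariate cell.
    covariate_names : covariate registry; defaults to the ten base names
        plus the four auxiliary (sensitivity-model) names.
    year_effect : added to the linear predictor per year since the first
        study year; negative values yield efficiency improving over time.
    group_effects : optional {column: {label: shift}} additive shifts to
        the linear predictor by group label, for grouped-summary tests.
    """
    if n_countries < 5:
        raise DomainError("need at least 5 countries")
    if not 0.0 <= missing_rate < 0.5:
        raise DomainError("missing_rate must lie in [0, 0.5)")
    beta_true = np.asarray(beta_true, dtype=float)
    if covariate_names is None:
        covariate_names = BASE_COVARIATES + AUX_COVARIATES
    p = len(covariate_names)
    if len(beta_true) - 1 > p:
        raise DomainError("more slope coefficients than covariates")

    years = list(years)
    rng = np.random.default_rng(seed)
    n = n_countries * len(years)

    country = [f"C{i:03d}" for i in range(n_countries)]
    idx = pd.MultiIndex.from_product([country, years],
                                     names=["country_code", "year"])
    df = idx.to_frame(index=False)

    # input: spending per PLHIV, log-normal clipped to the observed range
    x = rng.lognormal(mean=5.7, sigma=0.75, size=n)
    x = np.clip(x, *_X_RANGE)

    # covariates: Gaussian copula with a random weak-correlation structure
    C = _random_correlation(p, rng)
    L = np.linalg.cholesky(C)
    Zc = rng.normal(size=(n, p)) @ L.T
    cov_df = pd.DataFrame(Zc, columns=covariate_names)

    # group labels: regions fixed per country; income from a GNI transform
    who = rng.choice(_WHO_REGIONS, size=n_countries)
    unaids = rng.choice(_UNAIDS_REGIONS, size=n_countries)
    df["who_region"] = np.repeat(who, len(years))
    df["unaids_region"] = np.repeat(unaids, len(years))
    if "gni_pc" in covariate_names:
        gni_usd = np.exp(7.8 + 1.1 * cov_df["gni_pc"].to_numpy())
    else:
        gni_usd = np.exp(7.8 + 1.1 * rng.normal(size=n))
    df["income_group"] = classify_income(np.clip(gni_usd, 100.0, 34000.0))

    # inefficiency: delta = z'beta (+ trends/shifts) + truncated noise
    k = len(beta_true) - 1
    mu = np.full(n, beta_true[0])
    if k:
        mu = mu + cov_df.iloc[:, :k].to_numpy() @ beta_true[1:]
    if year_effect:
        mu = mu + year_effect * (df["year"].to_numpy() - years[0])
    if group_effects:
        for col, shifts in group_effects.items():
            mu = mu + df[col].map(shifts).fillna(0.0).to_numpy()
    if sigma_true > 0:
        delta = draw_truncated_normal(mu, sigma_true, 1.0, rng)
    else:
        delta = np.maximum(mu, 1.0)

    # frontier calibrated so the maximal output peaks at 100
    b = np.array(_FRONTIER_B)
    a = 100.0 / _X_RANGE[1] ** b
    G = a * x[:, None] ** b
    Y = G / delta[:, None]
    if np.any(Y <= 0) or np.any(Y > 100.0 + 1e-9):
        raise GenerationError(
            f"outputs outside (0, 100]: range [{Y.min():.3g}, {Y.max():.3g}]"
        )

    plhiv = np.round(rng.lognormal(mean=10.5, sigma=1.0, size=n)) + 1
    df["plhiv"] = plhiv
    df["spend_total"] = x * plhiv
    df["pct_art"] = Y[:, 0]
    df["pct_pmtct"] = Y[:, 1]
    for c in covariate_names:
        df[c] = cov_df[c]

    if missing_rate > 0:
        holes = rng.uniform(size=(n, p)) < missing_rate
        block = df[covariate_names].to_numpy()
        block[holes] = np.nan
        df[covariate_names] = block

    panel = PanelDataset(df, covariate_names)
    ids = list(zip(df["country_code"], df["year"]))
    truth = SyntheticTruth(
        frontier_a=a, frontier_b=b, beta_true=beta_true,
        sigma_true=float(sigma_true), delta_true=delta,
        missing_rate=float(missing_rate), seed=seed, dmu_ids=ids,
    )
    return panel, truth


def recovery_metrics(truth: SyntheticTruth, result) -> dict:
    """How well a double-bootstrap run recovered the generator's truth.

    Returns rank and linear correlations between the bias-corrected
    efficiencies and the true efficiencies 1/delta_true, plus a
    per-coefficient table of estimate, truth, bias and CI coverage.
    """
    if len(result.dmu_ids) != len(truth.dmu_ids):
        raise IntegrityError("result and truth refer to different panels")
    if (result.dmu_ids and isinstance(result.dmu_ids[0], tuple)
            and list(result.dmu_ids) != list(truth.dmu_ids)):
        raise IntegrityError("result and truth DMU ids disagree")
    eff_true = 1.0 / truth.delta_true
    eff_bc = result.efficiency_bc
    rho_s = float(spearmanr(eff_bc, eff_true).statistic)
    rho_p = float(pearsonr(eff_bc, eff_true).statistic)

    rows = []
    bt = truth.beta_true
    bh = result.beta_hat
    for j in range(len(bt)):
        row = {"coefficient": f"beta_{j}", "truth": float(bt[j]),
               "estimate": float(bh[j]) if bh is not None else np.nan,
               "bias": float(bh[j] - bt[j]) if bh is not None else np.nan}
        if result.beta_ci_low is not None:
            row["ci_low"] = float(result.beta_ci_low[j])
            row["ci_high"] = float(result.beta_ci_high[j])
            row["covered"] = bool(result.beta_ci_low[j] <= bt[j]
                                  <= result.beta_ci_high[j])
        rows.append(row)
    if result.sigma_hat is not None:
        rows.append({"coefficient": "sigma", "truth": truth.sigma_true,
                     "estimate": float(result.sigma_hat),
                     "bias": float(result.sigma_hat - truth.sigma_true)})
    return {
        "spearman_eff": rho_s,
        "pearson_eff": rho_p,
        "coefficients": pd.DataFrame(rows),
        "rmse_beta": float(np.sqrt(np.mean((bh - bt) ** 2)))
        if bh is not None else np.nan,
    }
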