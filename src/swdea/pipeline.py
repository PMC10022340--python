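"""End-to-end study orchestration.

Chains panel loading, covariate imputation, optional outlier trimming,
the pooled DEA + double bootstrap, and the reporting tables: pooled
descriptives, annual mean efficiency with 95% CIs, grouped summaries by
region and income group, the second-stage regression table, and the
sensitivity comparison across covariate models and trimming rules.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm, ttest_ind

from .exceptions import DomainError
from .imputation import impute_mvn
from .panel import PanelDataset, load_panel
from .simar_wilson import SWConfig, SWResult, run_double_bootstrap
from .synthetic import AUX_COVARIATES, BASE_COVARIATES

__all__ = ["StudyConfig", "StudyReport", "COVARIATE_MODELS",
           "descriptive_stats", "trim_outliers", "group_summary",
           "compare_models", "run_study"]

# covariate model registry: the ten-variable base model and the
# sensitivity extensions adding workforce/infrastructure (A) and
# funding-source (B) covariates
COVARIATE_MODELS = {
    "base": list(BASE_COVARIATES),
    "A": list(BASE_COVARIATES) + AUX_COVARIATES[:2],
    "B": list(BASE_COVARIATES) + AUX_COVARIATES[2:],
    "A+B": list(BASE_COVARIATES) + list(AUX_COVARIATES),
}

TRIM_SPECS = ("none", "lower5", "upper5", "both")


@dataclass
class StudyConfig:
    covariate_model: str = "base"
    trim: str = "none"
    trim_fraction: float = 0.05
    sw: SWConfig = field(default_factory=SWConfig)
    grouping: tuple = ("who_region", "unaids_region", "income_group")
    imputation_m: int = 50
    sensitivity_models: tuple = ()
    sensitivity_trims: tuple = ()
    outdir: str | None = None
    covariates: list | None = None   # overrides the registry when given

    def __post_init__(self):
        if self.covariates is None and \
                self.covariate_model not in COVARIATE_MODELS:
            raise DomainError(
                f"unknown covariate model {self.covariate_model!r}; "
                f"registered: {sorted(COVARIATE_MODELS)}"
            )
        if self.trim not in TRIM_SPECS:
            raise DomainError(f"trim must be one of {TRIM_SPECS}")
        if not 0.0 <= self.trim_fraction <= 0.25:
            raise DomainError("trim_fraction must lie in [0, 0.25]")

    def model_covariates(self) -> list:
        if self.covariates is not None:
            return list(self.covariates)
        return COVARIATE_MODELS[self.covariate_model]


@dataclass
class StudyReport:
    descriptives: pd.DataFrame
    scores: pd.DataFrame
    annual: pd.DataFrame
    groups: pd.DataFrame
    regression: pd.DataFrame
    sensitivity: pd.DataFrame
    manifest: dict


def descriptive_stats(panel: PanelDataset) -> pd.DataFrame:
    """Mean, SD, P25, P75, min, max per analysis variable.

    Percentiles use linear interpolation between order statistics.
    Variables with zero observations are omitted.
    """
    df = panel.df
    block = {"spend_per_plhiv": panel.spend_per_plhiv,
             "pct_art": df["pct_art"], "pct_pmtct": df["pct_pmtct"]}
    for c in panel.covariates:
        block[c] = df[c]
    rows = {}
    for name, s in block.items():
        v = pd.to_numeric(s, errors="coerce").dropna().to_numpy(dtype=float)
        if v.size == 0:
            continue
        rows[name] = {
            "mean": v.mean(), "sd": v.std(ddof=1) if v.size > 1 else 0.0,
            "p25": np.percentile(v, 25), "p75": np.percentile(v, 75),
            "min": v.min(), "max": v.max(), "n": v.size,
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def trim_outliers(panel: PanelDataset, spec: str,
                  fraction: float = 0.05):
    """Drop observations in the tails of the input/output distributions.

    ``lower5`` drops rows strictly below the ``fraction`` percentile of
    any of the three analysis variables, ``upper5`` strictly above the
    ``1 - fraction`` percentile, ``both`` applies both tails.  Returns the
    trimmed panel and a drop log.
    """
    if spec not in TRIM_SPECS:
        raise DomainError(f"trim spec must be one of {TRIM_SPECS}")
    if len(panel) == 0:
        raise DomainError("panel is empty")
    if spec == "none":
        return panel, pd.DataFrame(columns=["variable", "tail", "n_dropped"])
    df = panel.df
    variables = {"spend_per_plhiv": panel.spend_per_plhiv.to_numpy(),
                 "pct_art": df["pct_art"].to_numpy(),
                 "pct_pmtct": df["pct_pmtct"].to_numpy()}
    keep = np.ones(len(df), dtype=bool)
    log = []
    for name, v in variables.items():
        if spec in ("lower5", "both"):
            lo = np.percentile(v, 100 * fraction)
            drop = v < lo
            keep &= ~drop
            log.append({"variable": name, "tail": "lower",
                        "n_dropped": int(drop.sum())})
        if spec in ("upper5", "both"):
            hi = np.percentile(v, 100 * (1 - fraction))
            drop = v > hi
            keep &= ~drop
            log.append({"variable": name, "tail": "upper",
                        "n_dropped": int(drop.sum())})
    if keep.sum() < 10:
        raise DomainError(
            f"trimming would leave only {int(keep.sum())} observations"
        )
    return panel.replace_df(df.loc[keep]), pd.DataFrame(log)


def group_summary(scores: pd.DataFrame, by: str,
                  value: str = "eff_bc", per_year: bool = True
                  ) -> pd.DataFrame:
    """Per-group (and year) efficiency summaries.

    Reports mean, median, IQR, n, and a normal-approximation 95% CI for
    the mean; groups of size one get their CI suppressed and flagged.
    """
    if scores[by].isna().any():
        raise DomainError(f"every score must carry a {by!r} label")
    keys = [by, "year"] if per_year and "year" in scores else [by]
    rows = []
    for key, sub in scores.groupby(keys, observed=True):
        v = sub[value].to_numpy(dtype=float)
        n = v.size
        row = dict(zip(keys, key if isinstance(key, tuple) else (key,)))
        row.update({
            "mean": v.mean(), "median": np.median(v),
            "iqr": np.percentile(v, 75) - np.percentile(v, 25), "n": n,
        })
        if n > 1:
            half = 1.96 * v.std(ddof=1) / np.sqrt(n)
            row["ci_low"], row["ci_high"] = v.mean() - half, v.mean() + half
            row["ci_suppressed"] = False
        else:
            row["ci_low"] = row["ci_high"] = np.nan
            row["ci_suppressed"] = True
        rows.append(row)
    return pd.DataFrame(rows)


def compare_models(results: dict, base: str = "base") -> pd.DataFrame:
    """Mean bias-corrected efficiency per variant and Welch t-tests vs base.

    Variants run on non-identical panels are compared on the intersection
    of their DMU ids (a warning column records the restriction).
    """
    if base not in results or len(results) < 2:
        raise DomainError("need the base variant plus at least one other")
    base_res = results[base]
    base_ids = list(base_res.dmu_ids)
    rows = []
    for name, res in results.items():
        ids = list(res.dmu_ids)
        common = [i for i in ids if i in set(base_ids)]
        restricted = len(common) != len(ids) or len(common) != len(base_ids)
        pos = {d: k for k, d in enumerate(ids)}
        bpos = {d: k for k, d in enumerate(base_ids)}
        a = res.efficiency_bc[[pos[d] for d in common]]
        b = base_res.efficiency_bc[[bpos[d] for d in common]]
        if name == base:
            t, p = 0.0, 1.0
        elif np.allclose(a, b):
            t, p = 0.0, 1.0
        else:
            t, p = ttest_ind(a, b, equal_var=False)
        rows.append({
            "model": name,
            "mean_eff_bc": float(np.mean(res.efficiency_bc)),
            "mean_diff_vs_base": float(np.mean(a) - np.mean(b)),
            "t_stat": float(t), "p_value": float(p),
            "n": len(res.efficiency_bc), "restricted": restricted,
        })
    return pd.DataFrame(rows)


def _regression_table(res: SWResult, names: list) -> pd.DataFrame:
    rows = []
    labels = ["(Intercept)"] + list(names)
    for j, lab in enumerate(labels):
        se = res.beta_se[j] if res.beta_se is not None else np.nan
        est = res.beta_hat[j]
        p = 2 * norm.sf(abs(est) / se) if np.isfinite(se) and se > 0 else np.nan
        row = {"variable": lab, "coefficient": est, "se": se, "p_value": p}
        if res.beta_ci_low is not None:
            row["ci_low"] = res.beta_ci_low[j]
            row["ci_high"] = res.beta_ci_high[j]
        rows.append(row)
    rows.append({"variable": "sigma", "coefficient": res.sigma_hat,
                 "se": res.sigma_se if res.sigma_se is not None else np.nan,
                 "p_value": np.nan})
    return pd.DataFrame(rows)


def _sw_inputs(panel: PanelDataset, covariates: list):
    df = panel.df
    X = panel.spend_per_plhiv.to_numpy(dtype=float)
    Y = df[["pct_art", "pct_pmtct"]].to_numpy(dtype=float)
    Z = np.column_stack([np.ones(len(df)),
                         df[covariates].to_numpy(dtype=float)])
    if np.isnan(Z).any():
        raise DomainError("covariates contain missing values; impute first")
    ids = list(zip(df["country_code"], df["year"].astype(int)))
    return X, Y, Z, ids


def _run_variant(panel: PanelDataset, covariates: list, sw: SWConfig
                 ) -> SWResult:
    X, Y, Z, ids = _sw_inputs(panel, covariates)
    res = run_double_bootstrap(X, Y, Z, sw)
    res.dmu_ids = ids
    return res


def run_study(config: StudyConfig, panel) -> StudyReport:
    """Execute the full analysis and assemble the report tables.

    ``panel`` may be a file path or an in-memory :class:`PanelDataset`.
    When ``config.outdir`` is set the tables are written as CSV alongside
    a JSON manifest (seed, config hash, exclusion and clamp counts) from
    which the run can be reproduced bit-identically.
    """
    if not isinstance(panel, PanelDataset):
        panel = load_panel(panel)
    n_loaded = len(panel)
    panel = panel.complete_cases()
    n_excluded = n_loaded - len(panel)

    imp = impute_mvn(panel, M=config.imputation_m, seed=config.sw.seed)
    completed = imp.panel
    trimmed, drop_log = trim_outliers(completed, config.trim,
                                      config.trim_fraction)

    covs = config.model_covariates()
    covs = [c for c in covs if c in completed.covariates]
    res = _run_variant(trimmed, covs, config.sw)

    scores = pd.DataFrame({
        "country_code": [d[0] for d in res.dmu_ids],
        "year": [d[1] for d in res.dmu_ids],
        "delta_hat": res.delta_hat, "bias": res.bias_hat,
        "delta_bc": res.delta_bc, "eff_bc": res.efficiency_bc,
        "ci_low": res.eff_ci_low, "ci_high": res.eff_ci_high,
    })
    labels = trimmed.df[["country_code", "year"] + list(config.grouping)]
    labels = labels.assign(year=labels["year"].astype(int))
    scores = scores.merge(labels, on=["country_code", "year"], how="left")

    annual = group_summary(scores.assign(_all="all"), "_all",
                           per_year=True).drop(columns="_all")
    groups = pd.concat(
        [group_summary(scores, g).assign(grouping=g).rename(
            columns={g: "group"})
         for g in config.grouping if scores[g].notna().any()],
        ignore_index=True,
    )
    regression = _regression_table(res, covs)

    # sensitivity: alternative covariate models and trimming rules,
    # run without loop 2 (only mean scores are compared)
    variants = {"base": res}
    sens_sw = SWConfig(L1=config.sw.L1, L2=0, alpha=config.sw.alpha,
                       seed=config.sw.seed,
                       include_boundary=config.sw.include_boundary)
    for m in config.sensitivity_models:
        mcovs = [c for c in COVARIATE_MODELS[m] if c in completed.covariates]
        variants[f"model:{m}"] = _run_variant(trimmed, mcovs, sens_sw)
    for t in config.sensitivity_trims:
        tpanel, _ = trim_outliers(completed, t, config.trim_fraction)
        variants[f"trim:{t}"] = _run_variant(tpanel, covs, sens_sw)
    if len(variants) > 1:
        sensitivity = compare_models(variants)
    else:
        sensitivity = pd.DataFrame([{
            "model": "base",
            "mean_eff_bc": float(np.mean(res.efficiency_bc)),
            "mean_diff_vs_base": 0.0, "t_stat": 0.0, "p_value": 1.0,
            "n": len(res.efficiency_bc), "restricted": False,
        }])

    cfg_dict = {
        "covariate_model": config.covariate_model,
        "covariates": covs, "trim": config.trim,
        "trim_fraction": config.trim_fraction,
        "L1": config.sw.L1, "L2": config.sw.L2,
        "alpha": config.sw.alpha, "seed": config.sw.seed,
        "imputation_m": config.imputation_m,
        "sensitivity_models": list(config.sensitivity_models),
        "sensitivity_trims": list(config.sensitivity_trims),
    }
    manifest = {
        "config": cfg_dict,
        "config_hash": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True).encode()).hexdigest()[:16],
        "n_loaded": int(n_loaded),
        "n_excluded_missing_io": int(n_excluded),
        "n_analysed": int(len(trimmed)),
        "n_trimmed": int(len(completed) - len(trimmed)),
        "n_bias_clamped": int(res.n_clamped),
        "n_boundary_excluded": int(res.n_boundary_excluded),
        "mean_eff_bc": float(np.mean(res.efficiency_bc)),
        "mean_bias_eff": float(np.mean(res.efficiency_bc
                                       - 1.0 / res.delta_hat)),
    }
    report = StudyReport(
        descriptives=descriptive_stats(completed), scores=scores,
        annual=annual, groups=groups, regression=regression,
        sensitivity=sensitivity, manifest=manifest,
    )
    if config.outdir:
        _write_report(report, Path(config.outdir))
    return report


def _write_report(report: StudyReport, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    report.descriptives.to_csv(outdir / "descriptives.csv",
                               index_label="variable")
    report.scores.to_csv(outdir / "scores_bc.csv", index=False)
    report.annual.to_csv(outdir / "annual.csv", index=False)
    report.groups.to_csv(outdir / "groups.csv", index=False)
    report.regression.to_csv(outdir / "regression.csv", index=False)
    report.sensitivity.to_csv(outdir / "sensitivity.csv", index=False)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(report.manifest, fh, indent=2)
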