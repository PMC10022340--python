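"""Country-year panel model, I/O and pre-analysis diagnostics.

The unit of analysis is a country-year observation of a national HIV
programme: one input (total HIV spending per person living with HIV, in
constant USD), two outputs (% of PLHIV on ART and % of HIV-positive
pregnant women receiving ARVs for PMTCT, both on the 0-100 scale), a
vector of country covariates, and group labels (WHO region, UNAIDS
region, World Bank income group).  Long-format CSV is the canonical
interchange; XLSX is accepted read-only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from statsmodels.stats.outliers_influence import variance_inflation_factor

from .exceptions import (DomainError, IntegrityError, PanelValidationError,
                         SchemaError)

__all__ = ["CountryYearRecord", "PanelDataset", "DiagnosticsReport",
           "load_panel", "write_panel", "derive_input", "classify_income",
           "diagnostics", "BASE_COLUMNS", "LABEL_COLUMNS"]

BASE_COLUMNS = ["country_code", "year", "spend_total", "plhiv",
                "pct_art", "pct_pmtct"]
LABEL_COLUMNS = ["who_region", "unaids_region", "income_group"]

# World Bank FY2022 income thresholds (GNI per capita, 2020 USD, Atlas)
INCOME_BINS = (1045.0, 4095.0, 12695.0)
INCOME_LABELS = ("low", "lower-middle", "upper-middle", "high")


@dataclass
class CountryYearRecord:
    """One observation; used for record-level construction and validation."""

    country_code: str
    year: int
    spend_total: float
    plhiv: float
    pct_art: float
    pct_pmtct: float
    covariates: dict = field(default_factory=dict)
    who_region: str | None = None
    unaids_region: str | None = None
    income_group: str | None = None

    def validate(self, year_range=(1990, 2030)):
        errs = []
        if not year_range[0] <= self.year <= year_range[1]:
            errs.append(f"year {self.year} outside {year_range}")
        for name, v in (("pct_art", self.pct_art),
                        ("pct_pmtct", self.pct_pmtct)):
            if not np.isnan(v) and not 0.0 <= v <= 100.0:
                errs.append(f"{name}={v} outside [0, 100]")
        if not np.isnan(self.spend_total) and self.spend_total < 0:
            errs.append(f"spend_total={self.spend_total} negative")
        if not np.isnan(self.plhiv) and self.plhiv <= 0:
            errs.append(f"plhiv={self.plhiv} not positive")
        return errs


class PanelDataset:
    """An ordered collection of country-year records.

    Wraps a DataFrame with the canonical columns plus a covariate name
    registry.  ``(country_code, year)`` must be unique.  Missing covariate
    cells stay NaN and are tracked by :meth:`missingness_mask` — never
    silently zero-filled.
    """

    def __init__(self, df: pd.DataFrame, covariates: list[str],
                 year_range=(1990, 2030), validate: bool = True):
        missing = [c for c in BASE_COLUMNS + list(covariates) if c not in df]
        if missing:
            raise SchemaError(f"missing required column(s): {missing}")
        self.df = df.reset_index(drop=True).copy()
        for c in LABEL_COLUMNS:
            if c not in self.df:
                self.df[c] = pd.NA
        self.covariates = list(covariates)
        self.year_range = tuple(year_range)
        dup = self.df.duplicated(subset=["country_code", "year"])
        if dup.any():
            pairs = self.df.loc[dup, ["country_code", "year"]]
            pairs = [tuple(r) for r in pairs.itertuples(index=False)]
            raise IntegrityError(f"duplicate (country, year) pair(s): {pairs}")
        if validate:
            self._validate_rows()

    def _validate_rows(self):
        errs = []
        for i, row in self.df.iterrows():
            rec = CountryYearRecord(
                country_code=row["country_code"], year=int(row["year"]),
                spend_total=float(row["spend_total"]),
                plhiv=float(row["plhiv"]),
                pct_art=float(row["pct_art"]),
                pct_pmtct=float(row["pct_pmtct"]),
            )
            for msg in rec.validate(self.year_range):
                errs.append((i, msg))
        if errs:
            raise PanelValidationError(errs)

    # -- convenience ------------------------------------------------------
    def __len__(self):
        return len(self.df)

    @property
    def spend_per_plhiv(self) -> pd.Series:
        return derive_input(self.df["spend_total"], self.df["plhiv"])

    def missingness_mask(self) -> pd.DataFrame:
        return self.df[self.covariates].isna()

    def replace_df(self, df: pd.DataFrame) -> "PanelDataset":
        return PanelDataset(df, self.covariates, self.year_range,
                            validate=False)

    def complete_cases(self) -> "PanelDataset":
        """Drop records lacking input or either output (exclusion flow)."""
        need = ["spend_total", "plhiv", "pct_art", "pct_pmtct"]
        keep = self.df[need].notna().all(axis=1) & (self.df["plhiv"] > 0)
        return self.replace_df(self.df.loc[keep])


def derive_input(spend_total, plhiv):
    """Spending per person living with HIV: total spending / PLHIV count."""
    spend = np.asarray(spend_total, dtype=float)
    n = np.asarray(plhiv, dtype=float)
    if np.any(n[~np.isnan(n)] <= 0):
        raise DomainError("plhiv must be positive to derive per-person spend")
    out = spend / n
    if out.ndim == 0:
        return float(out)
    return pd.Series(out, index=getattr(spend_total, "index", None),
                     name="spend_per_plhiv")


def classify_income(gni_per_capita):
    """World Bank income group from GNI per capita (2020 USD).

    low <= $1,045 < lower-middle <= $4,095 < upper-middle <= $12,695 < high.
    """
    g = np.asarray(gni_per_capita, dtype=float)
    if np.any(g < 0):
        raise DomainError("GNI per capita must be nonnegative")
    # side="left" keeps boundary values in the lower group
    idx = np.searchsorted(INCOME_BINS, g, side="left")
    if g.ndim == 0:
        return INCOME_LABELS[int(idx)]
    return np.array(INCOME_LABELS, dtype=object)[idx]


@dataclass
class DiagnosticsReport:
    """Pre-analysis screens: collinearity and isotonicity."""

    pearson: pd.DataFrame                 # covariate x covariate
    input_output_corr: pd.Series          # pooled, per output
    input_output_corr_by_year: pd.DataFrame
    vif: pd.Series
    mean_vif: float
    flagged_pairs: list
    corr_threshold: float


def diagnostics(panel: PanelDataset, corr_threshold: float = 0.7
                ) -> DiagnosticsReport:
    """Correlation and VIF screens on a panel's covariates.

    Pairwise Pearson correlations are computed on pairwise-complete
    observations and pairs with |rho| >= ``corr_threshold`` are flagged.
    VIF of covariate j is 1/(1 - R^2) from an OLS fit of j on the
    remaining covariates (complete cases, with intercept); a covariate
    constant across the panel gets an infinite VIF and a flag.  The
    input-output (isotonicity) correlations are reported both pooled over
    country-years and per year.
    """
    df = panel.df
    cov = panel.covariates
    C = df[cov].astype(float)
    pearson = C.corr(method="pearson", min_periods=3)

    flagged = []
    for i, a in enumerate(cov):
        for b in cov[i + 1:]:
            r = pearson.loc[a, b]
            if pd.notna(r) and abs(r) >= corr_threshold:
                flagged.append((a, b, float(r)))

    x = panel.spend_per_plhiv
    io = pd.Series({
        "pct_art": x.corr(df["pct_art"]),
        "pct_pmtct": x.corr(df["pct_pmtct"]),
    }, name="pearson_with_input")
    rows = {}
    for yr, sub in df.assign(_x=x).groupby("year"):
        rows[yr] = {
            "pct_art": sub["_x"].corr(sub["pct_art"]),
            "pct_pmtct": sub["_x"].corr(sub["pct_pmtct"]),
        }
    io_by_year = pd.DataFrame.from_dict(rows, orient="index").sort_index()

    complete = C.dropna()
    vifs = {}
    const = complete.std(ddof=0) < 1e-12
    live = [c for c in cov if not const.get(c, False)]
    X = np.column_stack([np.ones(len(complete)),
                         complete[live].to_numpy()]) if live else None
    for c in cov:
        if const.get(c, False):
            vifs[c] = np.inf
            flagged.append((c, c, np.nan))
            continue
        j = live.index(c) + 1  # skip the intercept column
        with np.errstate(divide="ignore"):
            vifs[c] = float(variance_inflation_factor(X, j))
    vif = pd.Series(vifs, name="vif")
    finite = vif[np.isfinite(vif)]
    return DiagnosticsReport(
        pearson=pearson,
        input_output_corr=io,
        input_output_corr_by_year=io_by_year,
        vif=vif,
        mean_vif=float(finite.mean()) if len(finite) else np.nan,
        flagged_pairs=flagged,
        corr_threshold=corr_threshold,
    )


def load_panel(path, schema: dict | None = None,
               covariates: list[str] | None = None,
               year_range=(1990, 2030)) -> PanelDataset:
    """Read a panel from CSV (canonical) or XLSX (read-only).

    Parameters
    ----------
    path : file path; ``.xlsx`` files are read via openpyxl.
    schema : optional {file column -> canonical column} rename mapping.
    covariates : covariate registry; defaults to every column that is not
        a base or label column.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"no such file: {path}")
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path)
    else:
        df = pd.read_csv(path, float_precision="round_trip")
    if schema:
        missing = [c for c in schema if c not in df.columns]
        if missing:
            raise SchemaError(f"mapped column(s) absent from file: {missing}")
        df = df.rename(columns=schema)
    missing = [c for c in BASE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")
    if covariates is None:
        covariates = [c for c in df.columns
                      if c not in BASE_COLUMNS + LABEL_COLUMNS]
    return PanelDataset(df, covariates, year_range)


def write_panel(panel: PanelDataset, path) -> None:
    """Write a panel as long-format CSV with empty cells for missing."""
    cols = BASE_COLUMNS + panel.covariates + LABEL_COLUMNS
    panel.df[cols].to_csv(path, index=False)
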