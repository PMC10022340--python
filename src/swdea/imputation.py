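"""Two-step missing-covariate handling.

Step 1 (temporal): within each country's yearly series of a covariate,
interior gaps are filled with the within-country mean of the observed
values, and years outside the observed span carry the earliest value back
or the latest value forward.

Step 2 (multivariate normal): remaining gaps — countries with no
observation at all for a covariate — are imputed from a multivariate
normal model fitted to the standardized covariate matrix by EM; M
completed datasets are drawn from the conditionals of missing given
observed and averaged into a single analysis panel.

Inputs and outputs of the efficiency model are never imputed; units
lacking them are excluded upstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ConvergenceError, DomainError

__all__ = ["ImputationResult", "fill_within_country", "temporal_fill",
           "impute_mvn", "PROVENANCE_CODES"]

PROVENANCE_CODES = ("observed", "temporal_fill", "edge_carry", "mvn_imputed")


@dataclass
class ImputationResult:
    panel: "PanelDataset"          # completed panel
    provenance: pd.DataFrame       # same shape as covariate block
    M: int
    seed: int

    def counts(self) -> pd.Series:
        return self.provenance.stack().value_counts()


def fill_within_country(series: pd.Series):
    """Fill one country's yearly covariate series.

    Parameters
    ----------
    series : values indexed by consecutive study years; NaN = missing.

    Returns
    -------
    (filled, provenance) — two Series aligned with the input.  Interior
    gaps get the mean of the observed values (``temporal_fill``); years
    before the first or after the last observation carry the nearest
    observed value (``edge_carry``).  An all-missing series passes through
    untouched for the multivariate step.
    """
    filled = series.astype(float).copy()
    prov = pd.Series(
        np.where(series.notna(), "observed", "missing"), index=series.index
    )
    obs = series.dropna()
    if obs.empty:
        return filled, prov
    first, last = obs.index[0], obs.index[-1]
    mean = float(obs.mean())
    for yr in series.index:
        if pd.notna(series.loc[yr]):
            continue
        if yr < first:
            filled.loc[yr] = float(obs.loc[first])
            prov.loc[yr] = "edge_carry"
        elif yr > last:
            filled.loc[yr] = float(obs.loc[last])
            prov.loc[yr] = "edge_carry"
        else:
            filled.loc[yr] = mean
            prov.loc[yr] = "temporal_fill"
    return filled, prov


def temporal_fill(panel):
    """Apply :func:`fill_within_country` to every (country, covariate) series.

    Returns a completed copy of the panel (still possibly containing NaN
    for countries with no observation of a covariate) plus the provenance
    frame.
    """
    df = panel.df
    cov = panel.covariates
    out = df.copy()
    prov = pd.DataFrame("observed", index=df.index, columns=cov)
    for country, idx in df.groupby("country_code", sort=False).groups.items():
        sub = df.loc[idx].sort_values("year")
        years = pd.Index(sub["year"].to_numpy())
        for c in cov:
            s = pd.Series(sub[c].to_numpy(), index=years)
            if not s.isna().any():
                continue
            filled, p = fill_within_country(s)
            out.loc[sub.index, c] = filled.to_numpy()
            prov.loc[sub.index, c] = p.to_numpy()
    prov = prov.where(out[cov].notna(), "missing")
    return panel.replace_df(out), prov


def _em_mvn(W: np.ndarray, ridge: float = 1e-6, max_iter: int = 200,
            tol: float = 1e-6):
    """EM estimate of (mu, Sigma) of a MVN from data with missing entries."""
    n, p = W.shape
    miss = np.isnan(W)
    X = np.where(miss, np.nanmean(W, axis=0), W)
    mu = X.mean(axis=0)
    Sigma = np.cov(X, rowvar=False) + ridge * np.eye(p)
    delta = np.inf
    for _ in range(max_iter):
        # E-step: conditional means + conditional covariance contributions
        C = np.zeros((p, p))
        for i in range(n):
            mi = miss[i]
            if not mi.any():
                continue
            oi = ~mi
            if not oi.any():
                X[i] = mu
                C[np.ix_(mi, mi)] += Sigma[np.ix_(mi, mi)]
                continue
            S_oo = Sigma[np.ix_(oi, oi)]
            S_mo = Sigma[np.ix_(mi, oi)]
            sol = np.linalg.solve(S_oo, (X[i, oi] - mu[oi]))
            X[i, mi] = mu[mi] + S_mo @ sol
            C[np.ix_(mi, mi)] += (
                Sigma[np.ix_(mi, mi)] - S_mo @ np.linalg.solve(S_oo, S_mo.T)
            )
        mu_new = X.mean(axis=0)
        Xc = X - mu_new
        Sigma_new = (Xc.T @ Xc + C) / n + ridge * np.eye(p)
        delta = max(np.abs(mu_new - mu).max(), np.abs(Sigma_new - Sigma).max())
        mu, Sigma = mu_new, Sigma_new
        if delta < tol:
            return mu, Sigma
    raise ConvergenceError(f"EM did not converge: last delta = {delta:.3g}")


def impute_mvn(panel, M: int = 50, seed: int = 0) -> ImputationResult:
    """Complete a panel's covariates via MVN multiple imputation.

    Runs the temporal step first if the caller has not, fits the MVN model
    by EM on standardized covariates, draws ``M`` completed datasets from
    the conditional distribution of missing given observed, and averages
    the draws cell-wise into one analysis panel.  Deterministic given
    ``seed``; observed cells are never altered.
    """
    if M < 1:
        raise DomainError("M must be >= 1")
    filled_panel, prov = temporal_fill(panel)
    df = filled_panel.df
    cov = filled_panel.covariates
    W = df[cov].to_numpy(dtype=float)
    miss = np.isnan(W)
    if not miss.any():
        return ImputationResult(filled_panel, prov, M, seed)

    # columns with zero observed values carry no correlation information:
    # fall back to the pooled mean (0 after standardization) with a flag
    n_obs_col = (~miss).sum(axis=0)
    dead = n_obs_col == 0

    mean = np.nanmean(np.where(dead[None, :], 0.0, W), axis=0)
    sd = np.nanstd(np.where(dead[None, :], 1.0, W), axis=0)
    sd = np.where(sd < 1e-12, 1.0, sd)
    S = (W - mean) / sd

    live = ~dead
    if live.sum() >= 1:
        mu, Sigma = _em_mvn(S[:, live])
    rng = np.random.default_rng(seed)
    Sl = S[:, live]
    miss_l = np.isnan(Sl)
    avg = Sl.copy()
    # group rows by missingness pattern: the conditional coefficients are
    # shared within a pattern, so draws vectorise over rows and over M
    patterns = {}
    for i in range(Sl.shape[0]):
        if miss_l[i].any():
            patterns.setdefault(tuple(miss_l[i]), []).append(i)
    for pat in sorted(patterns):
        rows = np.array(patterns[pat])
        mi = np.array(pat)
        oi = ~mi
        if oi.any():
            S_oo = Sigma[np.ix_(oi, oi)]
            S_mo = Sigma[np.ix_(mi, oi)]
            W = np.linalg.solve(S_oo, S_mo.T).T
            cm = mu[mi] + (Sl[np.ix_(rows, oi)] - mu[oi]) @ W.T
            cv = Sigma[np.ix_(mi, mi)] - S_mo @ W.T
        else:
            cm = np.broadcast_to(mu[mi], (len(rows), mi.sum()))
            cv = Sigma[np.ix_(mi, mi)]
        cv = 0.5 * (cv + cv.T) + 1e-10 * np.eye(int(mi.sum()))
        L = np.linalg.cholesky(cv)
        eps = rng.standard_normal((M, len(rows), int(mi.sum()))) @ L.T
        filled = cm[None, :, :] + eps          # M completed datasets
        avg[np.ix_(rows, np.nonzero(mi)[0])] = filled.mean(axis=0)
    acc = np.zeros_like(S)
    acc[:, live] = avg
    S_completed = np.where(np.isnan(S), acc, S)
    S_completed[:, dead] = np.where(np.isnan(S[:, dead]), 0.0,
                                    S[:, dead])
    W_completed = S_completed * sd + mean

    out = df.copy()
    out[cov] = W_completed
    prov = prov.mask(pd.DataFrame(miss, index=df.index, columns=cov),
                     "mvn_imputed")
    return ImputationResult(filled_panel.replace_df(out), prov, M, seed)
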