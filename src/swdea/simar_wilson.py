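"""Simar-Wilson double bootstrap for covariate-adjusted DEA scores.

Two nested bootstrap loops around the output-oriented VRS DEA:

* **Loop 1** (bias correction): fit a left-truncated normal regression of
  the initial distances on the covariates, draw covariate-conditional
  pseudo-distances, shrink each unit's outputs onto the implied
  pseudo-frontier, rescore every observed unit against that pseudo
  reference set, and use the distribution of rescored distances to
  estimate and remove the inward bias of the empirical frontier.
* **Loop 2** (inference): refit the truncated regression on the
  bias-corrected distances, then parametrically bootstrap that fit to
  obtain percentile confidence intervals and standard errors for the
  coefficients and the scale.

Distances live on the :math:`[1, \\infty)` scale throughout; efficiencies
are their reciprocals in :math:`(0, 1]`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import dea
from .exceptions import DomainError
from .truncreg import TruncRegFit, draw_truncated_normal, fit_truncated_regression

__all__ = ["SWConfig", "SWResult", "pseudo_outputs", "bias_correct",
           "run_double_bootstrap"]

_BOUNDARY_TOL = 1e-9


@dataclass
class SWConfig:
    """Replication counts and options for the double bootstrap.

    L1/L2 defaults follow common practice for this estimator (1,000
    frontier replications, 3,000 regression replications); scale them down
    for simulation studies.
    """

    L1: int = 1000
    L2: int = 3000
    alpha: float = 0.05
    seed: int = 0
    include_boundary: bool = False

    def __post_init__(self):
        if self.L1 < 1 or self.L2 < 0:
            raise DomainError("L1 must be >= 1 and L2 >= 0")
        if not 0.0 < self.alpha < 1.0:
            raise DomainError("alpha must lie in (0, 1)")


@dataclass
class SWResult:
    """Per-unit bias-corrected scores and second-stage bootstrap inference."""

    dmu_ids: list
    delta_hat: np.ndarray
    bias_hat: np.ndarray
    delta_bc: np.ndarray
    efficiency_bc: np.ndarray
    ci_low: np.ndarray            # distance scale
    ci_high: np.ndarray
    eff_ci_low: np.ndarray        # efficiency scale (reciprocal, swapped)
    eff_ci_high: np.ndarray
    beta_hat: np.ndarray | None
    sigma_hat: float | None
    beta_se: np.ndarray | None
    sigma_se: float | None
    beta_ci_low: np.ndarray | None
    beta_ci_high: np.ndarray | None
    stage1_fit: TruncRegFit | None
    stage2_fit: TruncRegFit | None
    config: SWConfig = field(default=None)
    n_clamped: int = 0
    n_boundary_excluded: int = 0
    loop2_nonconverged: int = 0
    boot_delta_mean: np.ndarray | None = None
    boot_delta_sd: np.ndarray | None = None

    @property
    def efficiency_hat(self) -> np.ndarray:
        return 1.0 / self.delta_hat


def pseudo_outputs(Y: np.ndarray, delta_hat: np.ndarray,
                   delta_star: np.ndarray) -> np.ndarray:
    """Project outputs onto the bootstrap pseudo-frontier.

    Row i of the result is ``y_i * delta_hat_i / delta_star_i``: a unit with
    a drawn distance larger than its estimated one has its outputs shrunk,
    placing the pseudo observation deeper inside the frontier.
    """
    delta_hat = np.asarray(delta_hat, dtype=float)
    delta_star = np.asarray(delta_star, dtype=float)
    if np.any(delta_star < 1.0 - 1e-12):
        raise DomainError("pseudo distances must be >= 1")
    if np.any(delta_hat < 1.0 - 1e-12):
        raise DomainError("initial distances must be >= 1")
    return np.asarray(Y, dtype=float) * (delta_hat / delta_star)[:, None]


def bias_correct(delta_hat, bootstrap_deltas):
    """Bootstrap bias estimate and bias-corrected distance for one unit.

    bias = mean(bootstrap) - delta_hat;  corrected = delta_hat - bias,
    clamped at the boundary 1.
    """
    bootstrap_deltas = np.asarray(bootstrap_deltas, dtype=float)
    if bootstrap_deltas.size == 0:
        raise DomainError("bootstrap_deltas must be nonempty")
    bias = float(np.mean(bootstrap_deltas)) - float(delta_hat)
    return bias, max(2.0 * float(delta_hat) - float(np.mean(bootstrap_deltas)),
                     1.0)


def _stage_fit(delta, Z, include_boundary, start=None):
    """Truncated regression of distances on Z, excluding boundary units."""
    if include_boundary:
        mask = np.ones(len(delta), dtype=bool)
    else:
        mask = delta > 1.0 + _BOUNDARY_TOL
    if mask.sum() <= Z.shape[1] + 1:
        raise DomainError(
            "too few strictly inefficient units for the truncated regression"
        )
    fit = fit_truncated_regression(delta[mask], Z[mask], 1.0, start=start)
    return fit, mask


def run_double_bootstrap(X, Y, Z, config: SWConfig) -> SWResult:
    """Full two-stage double bootstrap on a pooled DEA panel.

    Parameters
    ----------
    X : (n, 1) or (n,) strictly positive input.
    Y : (n, 2) nonnegative outputs.
    Z : (n, p) covariate matrix *including* the intercept column.
    config : replication counts, CI level, master seed.

    Setting ``config.L2 = 0`` skips loop 2 (useful when only the
    bias-corrected scores are needed, e.g. for sensitivity summaries).
    """
    X = np.asarray(X, dtype=float).reshape(-1, 1)
    Y = np.asarray(Y, dtype=float)
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    n = X.shape[0]
    if Y.shape[0] != n or Z.shape[0] != n:
        raise DomainError("X, Y, Z must have the same number of rows")

    problem = dea.DEAProblem(X, Y, returns_to_scale="vrs")
    delta_hat = np.array([s.delta for s in dea.score_all(problem)])

    # stage-1 fit on initial distances -> (beta_tilde, sigma_tilde)
    fit1, _ = _stage_fit(delta_hat, Z, config.include_boundary)
    mu_tilde = Z @ fit1.beta

    master = np.random.SeedSequence(config.seed)
    ss_loop1, ss_loop2 = master.spawn(2)
    streams1 = ss_loop1.spawn(config.L1)

    boot = np.empty((config.L1, n))
    for b in range(config.L1):
        rng = np.random.default_rng(streams1[b])
        delta_star = draw_truncated_normal(mu_tilde, fit1.sigma, 1.0, rng)
        Y_star = pseudo_outputs(Y, delta_hat, delta_star)
        boot[b] = dea.score_against(X, Y_star, X, Y)

    boot_mean = boot.mean(axis=0)
    bias_hat = boot_mean - delta_hat
    delta_bc = 2.0 * delta_hat - boot_mean
    n_clamped = int(np.sum(delta_bc < 1.0))
    delta_bc = np.maximum(delta_bc, 1.0)

    # percentile CI on the distance scale from the bootstrap distribution,
    # re-centred at the bias-corrected score
    shifted = boot - 2.0 * bias_hat[None, :]
    lo_q, hi_q = 100 * config.alpha / 2, 100 * (1 - config.alpha / 2)
    ci_low = np.maximum(np.percentile(shifted, lo_q, axis=0), 1.0)
    ci_high = np.maximum(np.percentile(shifted, hi_q, axis=0), 1.0)

    # stage-2 fit on bias-corrected distances
    fit2, mask2 = _stage_fit(delta_bc, Z, config.include_boundary)
    beta_hat, sigma_hat = fit2.beta, fit2.sigma

    beta_se = sigma_se = beta_lo = beta_hi = None
    nonconv = 0
    if config.L2 > 0:
        Z2 = Z[mask2]
        mu_hat = Z2 @ beta_hat
        streams2 = ss_loop2.spawn(config.L2)
        draws = np.empty((config.L2, Z.shape[1] + 1))
        warm = np.append(beta_hat, sigma_hat)
        for b in range(config.L2):
            rng = np.random.default_rng(streams2[b])
            dss = draw_truncated_normal(mu_hat, sigma_hat, 1.0, rng)
            f = fit_truncated_regression(dss, Z2, 1.0, start=warm)
            if not f.converged:
                nonconv += 1
            draws[b] = np.append(f.beta, f.sigma)
        if nonconv > 0.01 * config.L2:
            warnings.warn(
                f"{nonconv}/{config.L2} loop-2 refits did not converge",
                stacklevel=2,
            )
        se = draws.std(axis=0, ddof=1)
        lo = np.percentile(draws, lo_q, axis=0)
        hi = np.percentile(draws, hi_q, axis=0)
        beta_se, sigma_se = se[:-1], float(se[-1])
        beta_lo, beta_hi = lo[:-1], hi[:-1]

    return SWResult(
        dmu_ids=list(problem.dmu_ids),
        delta_hat=delta_hat,
        bias_hat=bias_hat,
        delta_bc=delta_bc,
        efficiency_bc=1.0 / delta_bc,
        ci_low=ci_low,
        ci_high=ci_high,
        eff_ci_low=1.0 / ci_high,
        eff_ci_high=1.0 / ci_low,
        beta_hat=beta_hat,
        sigma_hat=sigma_hat,
        beta_se=beta_se,
        sigma_se=sigma_se,
        beta_ci_low=beta_lo,
        beta_ci_high=beta_hi,
        stage1_fit=fit1,
        stage2_fit=fit2,
        config=config,
        n_clamped=n_clamped,
        n_boundary_excluded=int(n - mask2.sum()),
        loop2_nonconverged=nonconv,
        boot_delta_mean=boot_mean,
        boot_delta_sd=boot.std(axis=0, ddof=1),
    )
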