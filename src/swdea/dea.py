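"""Output-oriented data envelopment analysis (DEA).

Solves the envelopment-form linear program for the output distance of each
decision-making unit (DMU): the largest factor :math:`\\delta` by which a
unit's outputs can be expanded while staying inside the production set
spanned by the observed units.  Under variable returns to scale (VRS) the
intensity weights are constrained to the simplex; dropping the convexity
constraint gives constant returns to scale (CRS).

Two solution paths are provided.  ``score_dmu`` solves one LP per unit
(scipy/HiGHS) and recovers the intensity weights :math:`\\lambda`.  For the
single-input, two-output VRS geometry used throughout the pipeline,
``score_against`` instead builds the facet description of the free-disposal
convex hull of the reference units once (Qhull) and scores every query unit
by a vectorised ray-facet intersection; the two paths agree to solver
tolerance and the hull path is two to three orders of magnitude faster,
which is what makes the bootstrap loops affordable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog
from scipy.spatial import ConvexHull, QhullError

from .exceptions import DomainError, ScoringError

__all__ = ["DEAProblem", "DEAScore", "score_dmu", "score_all",
           "score_against", "score_within_groups"]

_CLAMP_TOL = 1e-9


@dataclass
class DEAProblem:
    """A pooled DEA instance: DMU-by-input matrix X, DMU-by-output matrix Y."""

    X: np.ndarray
    Y: np.ndarray
    orientation: str = "output"
    returns_to_scale: str = "vrs"
    dmu_ids: list | None = None

    def __post_init__(self):
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.Y = np.atleast_2d(np.asarray(self.Y, dtype=float))
        if self.X.ndim != 2 or self.Y.ndim != 2:
            raise DomainError("X and Y must be 2-d (DMU by variable)")
        if self.X.shape[0] != self.Y.shape[0]:
            raise DomainError(
                f"row mismatch: X has {self.X.shape[0]} DMUs, Y has {self.Y.shape[0]}"
            )
        if self.orientation != "output":
            raise DomainError("only output orientation is supported")
        if self.returns_to_scale not in ("vrs", "crs"):
            raise DomainError("returns_to_scale must be 'vrs' or 'crs'")
        if not np.all(self.X > 0):
            raise DomainError("inputs must be strictly positive")
        if np.any(self.Y < 0):
            raise DomainError("outputs must be nonnegative")
        if np.any(np.all(self.Y <= 0, axis=1)):
            bad = np.nonzero(np.all(self.Y <= 0, axis=1))[0]
            raise DomainError(f"DMU(s) {bad.tolist()} have all-zero outputs")
        if self.dmu_ids is None:
            self.dmu_ids = list(range(self.n_dmus))
        if len(self.dmu_ids) != self.n_dmus:
            raise DomainError("dmu_ids length does not match number of DMUs")

    @property
    def n_dmus(self) -> int:
        return self.X.shape[0]


@dataclass
class DEAScore:
    """Result for one DMU: distance delta >= 1, efficiency = 1/delta, peers."""

    dmu_id: object
    delta: float
    efficiency: float
    lam: np.ndarray | None = None
    solver_status: str = "optimal"

    def peers(self, tol: float = 1e-9) -> dict:
        """Reference-set DMU indices with intensity weight above ``tol``."""
        if self.lam is None:
            return {}
        idx = np.nonzero(self.lam > tol)[0]
        return {int(j): float(self.lam[j]) for j in idx}


def _solve_lp(x_ref, Y_ref, x_q, y_q, vrs: bool):
    """One envelopment LP: max delta s.t. lam@X <= x_q, lam@Y >= delta*y_q."""
    n = x_ref.shape[0]
    k, m = x_ref.shape[1], Y_ref.shape[1]
    # variables: [delta, lam_1..lam_n]
    A_ub = np.zeros((k + m, n + 1))
    A_ub[:k, 1:] = x_ref.T
    A_ub[k:, 1:] = -Y_ref.T
    A_ub[k:, 0] = y_q
    b_ub = np.concatenate([x_q, np.zeros(m)])
    c = np.zeros(n + 1)
    c[0] = -1.0
    bounds = [(None, None)] + [(0.0, None)] * n
    if vrs:
        A_eq = np.zeros((1, n + 1))
        A_eq[0, 1:] = 1.0
        res = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=[1.0],
                      bounds=bounds, method="highs")
    else:
        res = linprog(c, A_ub=A_ub, b_ub=b_ub, bounds=bounds, method="highs")
    return res


def score_dmu(problem: DEAProblem, i: int) -> DEAScore:
    """Score DMU ``i`` of ``problem`` by the envelopment LP, with peer weights."""
    res = _solve_lp(problem.X, problem.Y, problem.X[i], problem.Y[i],
                    problem.returns_to_scale == "vrs")
    if res.status != 0:
        raise ScoringError(
            f"LP failed for DMU {problem.dmu_ids[i]!r}: {res.message}"
        )
    delta = max(-res.fun, 1.0)
    return DEAScore(
        dmu_id=problem.dmu_ids[i],
        delta=delta,
        efficiency=1.0 / delta,
        lam=res.x[1:],
        solver_status="optimal",
    )


def _hull_facets(x_ref: np.ndarray, Y_ref: np.ndarray, xhi: float):
    """Facet description of the VRS production set, clipped to x <= xhi, y >= 0.

    The production set is conv{(x_j, y_j)} extended by free disposal (more
    input, fewer outputs).  Clipping with ghost vertices at every disposal
    combination makes the set bounded so Qhull applies.
    """
    n = x_ref.shape[0]
    xcol = x_ref[:, 0]
    zeros = np.zeros(n)
    pts = []
    for xv in (xcol, np.full(n, xhi)):
        for y1 in (Y_ref[:, 0], zeros):
            for y2 in (Y_ref[:, 1], zeros):
                pts.append(np.column_stack([xv, y1, y2]))
    P = np.unique(np.vstack(pts), axis=0)
    hull = ConvexHull(P, qhull_options="Qt")
    # hull.equations rows: a . p + b0 <= 0
    a = hull.equations[:, :3]
    b = -hull.equations[:, 3]
    return a, b


def score_against(
    x_ref: np.ndarray,
    Y_ref: np.ndarray,
    x_query: np.ndarray,
    Y_query: np.ndarray,
    clamp: bool = False,
) -> np.ndarray:
    """Output distances of query units relative to a VRS reference frontier.

    Specialised to one input and two outputs.  Returns the vector of
    distances; values below 1 are legitimate when a query unit lies outside
    the reference production set (as happens when rescoring observed units
    against bootstrap pseudo-frontiers), so clamping is off by default.

    Parameters
    ----------
    x_ref, Y_ref : reference-set input (n,) or (n,1) and outputs (n, 2).
    x_query, Y_query : units to score against that frontier.
    """
    x_ref = np.asarray(x_ref, dtype=float).reshape(-1, 1)
    Y_ref = np.asarray(Y_ref, dtype=float)
    x_q = np.asarray(x_query, dtype=float).ravel()
    Y_q = np.asarray(Y_query, dtype=float)
    if Y_ref.shape[1] != 2 or x_ref.shape[1] != 1:
        raise DomainError("score_against requires 1 input and 2 outputs")
    if np.any(x_q < x_ref.min() - 1e-12):
        raise ScoringError("query input below the reference minimum: infeasible")

    xhi = max(x_ref.max(), x_q.max()) * 1.5 + 1.0
    try:
        a, b = _hull_facets(x_ref, Y_ref, xhi)
    except QhullError:
        # degenerate geometry (coplanar points, tiny n): fall back to LPs
        out = np.empty(len(x_q))
        for i, (xi, yi) in enumerate(zip(x_q, Y_q)):
            res = _solve_lp(x_ref, Y_ref, np.array([xi]), yi, True)
            if res.status != 0:
                raise ScoringError(f"LP fallback failed for query {i}: {res.message}")
            out[i] = -res.fun
        if clamp:
            out = np.maximum(out, 1.0)
        return out
    # delta_i = min over facets with positive output-normal component of
    #   (b - a_x * x_i) / (a . y_i)
    den = a[:, 1:] @ Y_q.T                      # (facets, queries)
    num = b[:, None] - np.outer(a[:, 0], x_q)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(den > 1e-12, num / den, np.inf)
    delta = ratio.min(axis=0)
    if clamp:
        delta = np.maximum(delta, 1.0)
    return delta


def _use_fast_path(problem: DEAProblem) -> bool:
    return (
        problem.returns_to_scale == "vrs"
        and problem.X.shape[1] == 1
        and problem.Y.shape[1] == 2
        and problem.n_dmus >= 4
    )


def score_all(problem: DEAProblem, peer_weights: bool = False) -> list[DEAScore]:
    """Score every DMU against the pooled frontier.

    Uses the hull path for the 1-input/2-output VRS geometry (peer weights
    then require ``peer_weights=True``, which re-solves the LP per unit);
    otherwise solves one LP per DMU.
    """
    if _use_fast_path(problem) and not peer_weights:
        deltas = score_against(problem.X, problem.Y, problem.X, problem.Y,
                               clamp=True)
        if np.any(~np.isfinite(deltas)):
            bad = np.nonzero(~np.isfinite(deltas))[0]
            raise ScoringError(f"scoring failed for DMUs {bad.tolist()}")
        return [
            DEAScore(dmu_id=problem.dmu_ids[i], delta=float(d),
                     efficiency=1.0 / float(d))
            for i, d in enumerate(deltas)
        ]
    return [score_dmu(problem, i) for i in range(problem.n_dmus)]


def deltas(problem: DEAProblem) -> np.ndarray:
    """Convenience: the vector of output distances for all DMUs."""
    return np.array([s.delta for s in score_all(problem)])


def score_within_groups(x, Y, groups) -> np.ndarray:
    """Distances against separate frontiers per group (e.g. per year).

    Exploration tool: the pipeline's default is the pooled frontier, which
    makes scores comparable across groups; per-group frontiers use fewer
    reference units, so each score is weakly smaller than its pooled
    counterpart.
    """
    x = np.asarray(x, dtype=float).ravel()
    Y = np.asarray(Y, dtype=float)
    groups = np.asarray(groups)
    out = np.empty(len(x))
    for g in np.unique(groups):
        m = groups == g
        prob = DEAProblem(x[m][:, None], Y[m])
        out[m] = [s.delta for s in score_all(prob)]
    return out
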