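"""Independent oracles: brute-force implementations used only by tests.

These deliberately avoid the code paths they check: the DEA oracle
searches the intensity-weight simplex on a grid instead of solving the
LP, and the regression oracle evaluates the likelihood on a parameter
grid instead of running the optimizer.
"""

from __future__ import annotations

import itertools

import numpy as np


def grid_delta(x, Y, i, resolution=400):
    """Output distance of DMU ``i`` by exhaustive simplex grid search.

    Searches lambda over all supports of at most three DMUs (an optimal
    basic solution of the 4-row envelopment LP has at most three positive
    intensity weights) at the given grid resolution, keeping combinations
    that satisfy the input constraint, and maximises the proportional
    output expansion min_m (lambda . Y_m) / y_im.
    """
    x = np.asarray(x, dtype=float).ravel()
    Y = np.asarray(Y, dtype=float)
    n = len(x)
    yi = Y[i]
    xi = x[i]
    best = 0.0
    grids = {1: np.array([[1.0]]), 2: _simplex_grid_2(resolution),
             3: _simplex_grid_3(resolution)}
    s = min(3, n)
    for support in itertools.combinations(range(n), s):
        sx = x[list(support)]
        sY = Y[list(support), :]
        lam = grids[s]
        feas = lam @ sx <= xi + 1e-12
        if not feas.any():
            continue
        outs = lam[feas] @ sY                      # (pts, m)
        with np.errstate(divide="ignore"):
            ratios = np.where(yi > 0, outs / yi, np.inf)
        best = max(best, float(ratios.min(axis=1).max()))
    return best


def _simplex_grid_2(resolution):
    """All (a, b) >= 0 with a + b = 1 on a 1/resolution grid."""
    a = np.arange(resolution + 1) / resolution
    return np.column_stack([a, 1.0 - a])


def _simplex_grid_3(resolution):
    """All (a, b, c) >= 0 with a + b + c = 1 on a 1/resolution grid."""
    ks = np.arange(resolution + 1)
    a, b = np.meshgrid(ks, ks, indexing="ij")
    mask = a + b <= resolution
    a, b = a[mask], b[mask]
    c = resolution - a - b
    return np.column_stack([a, b, c]) / resolution


def truncreg_grid_best(delta, Z, b0_range, b1_range, s_range, steps=25):
    """Best log-likelihood over a coarse (beta0, beta1, sigma) grid.

    Used to confirm the MLE's log-likelihood dominates every grid point.
    """
    from swdea.truncreg import loglik

    best = -np.inf
    argbest = None
    for b0 in np.linspace(*b0_range, steps):
        for b1 in np.linspace(*b1_range, steps):
            for s in np.linspace(*s_range, steps):
                ll = loglik(np.array([b0, b1]), s, delta, Z)
                if ll > best:
                    best, argbest = ll, (b0, b1, s)
    return best, argbest


def random_dea_instance(rng, n=None, spread=1.0):
    """A random well-posed 1-input / 2-output DEA instance."""
    if n is None:
        n = int(rng.integers(2, 6))
    x = rng.uniform(1.0, 10.0, n) * spread
    Y = rng.uniform(1.0, 100.0, (n, 2))
    return x, Y
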