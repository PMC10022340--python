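"""Output-oriented VRS DEA: worked examples, oracle agreement, invariants."""

import numpy as np
import pytest

from _oracles import grid_delta, random_dea_instance
from swdea.dea import (DEAProblem, score_against, score_all, score_dmu)
from swdea.exceptions import DomainError


def deltas_of(x, Y, rts="vrs"):
    prob = DEAProblem(np.asarray(x, float)[:, None], Y, returns_to_scale=rts)
    return np.array([s.delta for s in score_all(prob)])


class TestWorkedExamples:
    def test_single_dmu_is_its_own_frontier(self):
        prob = DEAProblem(np.array([[2.0]]), np.array([[3.0, 4.0]]))
        s = score_dmu(prob, 0)
        assert s.delta == pytest.approx(1.0, abs=1e-9)
        assert s.peers() == {0: pytest.approx(1.0, abs=1e-8)}

    def test_interior_unit_reaches_frontier_midpoint(self, toy_abc):
        # C can expand both outputs 1.5x onto the A-B midpoint
        x, Y = toy_abc
        prob = DEAProblem(x[:, None], Y)
        s = score_dmu(prob, 2)
        assert s.delta == pytest.approx(1.5, abs=1e-9)
        oracle = grid_delta(x, Y, 2, resolution=200)
        assert abs(oracle - 1.5) <= 0.01
        lam = s.lam
        assert lam[0] == pytest.approx(0.5, abs=1e-6)
        assert lam[1] == pytest.approx(0.5, abs=1e-6)

    def test_output_orientation_ignores_input_slack(self, toy_abc):
        # D uses twice A's input for A's outputs: weakly efficient in the
        # output direction
        x, Y = toy_abc
        x2 = np.append(x, 2.0)
        Y2 = np.vstack([Y, [2.0, 1.0]])
        prob = DEAProblem(x2[:, None], Y2)
        assert score_dmu(prob, 3).delta == pytest.approx(1.0, abs=1e-9)
        assert abs(grid_delta(x2, Y2, 3) - 1.0) <= 0.01

    def test_efficiencies_of_toy_set(self, toy_abc):
        x, Y = toy_abc
        effs = 1.0 / deltas_of(x, Y)
        np.testing.assert_allclose(effs, [1.0, 1.0, 2.0 / 3.0], atol=1e-9)

    def test_identical_dmus_all_on_frontier(self):
        x = np.full(6, 3.0)
        Y = np.tile([10.0, 20.0], (6, 1))
        np.testing.assert_allclose(deltas_of(x, Y), 1.0, atol=1e-9)


class TestValidation:
    def test_rejects_nonpositive_input(self):
        with pytest.raises(DomainError):
            DEAProblem(np.array([[0.0]]), np.array([[1.0, 1.0]]))

    def test_rejects_all_zero_outputs(self):
        with pytest.raises(DomainError, match="all-zero"):
            DEAProblem(np.array([[1.0], [1.0]]),
                       np.array([[1.0, 1.0], [0.0, 0.0]]))

    def test_single_zero_output_is_allowed(self):
        x = np.array([1.0, 1.0])
        Y = np.array([[2.0, 0.0], [1.0, 1.0]])
        d = deltas_of(x, Y)
        assert np.all(d >= 1.0 - 1e-9)


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(12))
    def test_lp_matches_simplex_grid(self, seed):
        rng = np.random.default_rng(seed)
        x, Y = random_dea_instance(rng)
        prob = DEAProblem(x[:, None], Y)
        for i in range(len(x)):
            lp = score_dmu(prob, i).delta
            grid = grid_delta(x, Y, i, resolution=400)
            assert abs(lp - grid) <= 0.01


class TestFastPathAgreement:
    @pytest.mark.parametrize("n", [10, 40, 100])
    def test_hull_scorer_matches_lp(self, n):
        rng = np.random.default_rng(n)
        x = rng.lognormal(5.0, 0.8, n)
        Y = rng.uniform(5.0, 100.0, (n, 2))
        fast = score_against(x, Y, x, Y, clamp=True)
        prob = DEAProblem(x[:, None], Y)
        idx = rng.choice(n, min(n, 15), replace=False)
        for i in idx:
            assert fast[i] == pytest.approx(score_dmu(prob, i).delta,
                                            abs=1e-9)


class TestInvariants:
    @pytest.mark.parametrize("seed", range(10))
    def test_delta_bounds_and_frontier_attained(self, seed):
        rng = np.random.default_rng(100 + seed)
        x, Y = random_dea_instance(rng, n=int(rng.integers(4, 15)))
        d = deltas_of(x, Y)
        assert np.all(d >= 1.0 - 1e-9)
        assert d.min() == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("seed", range(5))
    def test_units_invariance(self, seed):
        rng = np.random.default_rng(200 + seed)
        x, Y = random_dea_instance(rng, n=12)
        d0 = deltas_of(x, Y)
        # rescale the input and one output column by arbitrary factors
        d1 = deltas_of(x * 37.5, Y)
        Y2 = Y.copy()
        Y2[:, 1] *= 0.01
        d2 = deltas_of(x, Y2)
        np.testing.assert_allclose(d0, d1, atol=1e-8)
        np.testing.assert_allclose(d0, d2, atol=1e-8)

    def test_percent_rescaling_matches_fraction_scale(self):
        # outputs on 0-100 vs 0-1 give identical scores
        rng = np.random.default_rng(3)
        x, Y = random_dea_instance(rng, n=10)
        np.testing.assert_allclose(deltas_of(x, Y), deltas_of(x, Y * 0.01),
                                   atol=1e-8)

    @pytest.mark.parametrize("seed", range(5))
    def test_appending_dmu_never_decreases_delta(self, seed):
        rng = np.random.default_rng(300 + seed)
        x, Y = random_dea_instance(rng, n=10)
        d0 = deltas_of(x, Y)
        xn = np.append(x, rng.uniform(1, 10))
        Yn = np.vstack([Y, rng.uniform(1, 120, 2)])
        d1 = deltas_of(xn, Yn)[:10]
        assert np.all(d1 >= d0 - 1e-8)

    @pytest.mark.parametrize("seed", range(5))
    def test_deleting_non_peer_leaves_scores_unchanged(self, seed):
        rng = np.random.default_rng(400 + seed)
        x, Y = random_dea_instance(rng, n=10)
        prob = DEAProblem(x[:, None], Y)
        scores = [score_dmu(prob, i) for i in range(10)]
        lam = np.array([s.lam for s in scores])
        unused = np.nonzero(lam.max(axis=0) < 1e-9)[0]
        if unused.size == 0:
            pytest.skip("every DMU is someone's peer in this draw")
        j = int(unused[0])
        keep = [i for i in range(10) if i != j]
        d_before = np.array([s.delta for s in scores])[keep]
        d_after = deltas_of(x[keep], Y[keep])
        np.testing.assert_allclose(d_before, d_after, atol=1e-8)

    def test_per_group_frontier_scores_weakly_below_pooled(self):
        from swdea.dea import score_within_groups
        rng = np.random.default_rng(600)
        x, Y = random_dea_instance(rng, n=30)
        years = np.repeat([2010, 2011, 2012], 10)
        pooled = deltas_of(x, Y)
        per_year = score_within_groups(x, Y, years)
        assert np.all(per_year <= pooled + 1e-8)

    @pytest.mark.parametrize("seed", range(5))
    def test_vrs_delta_le_crs_delta(self, seed):
        rng = np.random.default_rng(500 + seed)
        x, Y = random_dea_instance(rng, n=8)
        assert np.all(deltas_of(x, Y, "vrs") <= deltas_of(x, Y, "crs") + 1e-8)
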