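"""Optimal-transport solvers against brute-force oracles: exhaustive
permutation search for G-W, direct quadruple-sum objectives for FG-W, and
closed-form limits for Sinkhorn."""

import itertools

import numpy as np
import pytest

from fnirsalign import (
    entropic_gw,
    fgw_barycenter,
    fgw_distance,
    gw_objective,
    sinkhorn,
    uniform,
)
from fnirsalign.ot import fgw_objective


def random_geometry(rng, n, dim=3):
    """Distance matrix of random points: all pairwise distances distinct."""
    x = rng.random((n, dim))
    return np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1))


def gw_quadruple_sum(ca, cb, t):
    """O(n²m²) literal evaluation of the squared-loss G-W objective."""
    n, m = t.shape
    total = 0.0
    for i in range(n):
        for ip in range(n):
            for j in range(m):
                for jp in range(m):
                    total += (ca[i, ip] - cb[j, jp]) ** 2 * t[i, j] * t[ip, jp]
    return total


class TestSinkhorn:
    def test_zero_cost_gives_product_coupling(self):
        plan = sinkhorn(np.zeros((4, 4)), lam=0.1)
        np.testing.assert_allclose(plan.matrix, np.full((4, 4), 1 / 16),
                                   atol=1e-10)

    def test_small_lambda_recovers_exact_assignment(self):
        """2×2 cost [[0,1],[1,0]] with uniform marginals: the LP optimum over
        the one-parameter feasible set T = [[t, ½−t], [½−t, t]] is t = ½."""
        cost = np.array([[0.0, 1.0], [1.0, 0.0]])
        plan = sinkhorn(cost, lam=1e-3)
        np.testing.assert_allclose(plan.matrix, 0.5 * np.eye(2), atol=1e-3)

    @pytest.mark.parametrize("lam", [1e-3, 1e-2, 1.0])
    def test_marginal_feasibility(self, rng, lam):
        cost = rng.random((7, 5))
        a = rng.random(7)
        a /= a.sum()
        b = rng.random(5)
        b /= b.sum()
        plan = sinkhorn(cost, a, b, lam=lam, tol=1e-9)
        assert plan.marginal_error() < 1e-6
        assert plan.converged

    def test_log_domain_matches_standard(self, rng):
        cost = rng.random((5, 5))
        p1 = sinkhorn(cost, lam=0.05, log_domain=False)
        p2 = sinkhorn(cost, lam=0.05, log_domain=True)
        np.testing.assert_allclose(p1.matrix, p2.matrix, atol=1e-8)

    def test_invalid_inputs(self, rng):
        with pytest.raises(ValueError):
            sinkhorn(np.array([[np.inf, 1.0]]), lam=0.1)
        with pytest.raises(ValueError):
            sinkhorn(np.ones((2, 2)), lam=0.0)
        with pytest.raises(ValueError):
            sinkhorn(np.ones((2, 2)), a=np.array([0.9, 0.9]), lam=0.1)


class TestEntropicGW:
    @pytest.mark.parametrize("n", [4, 5, 6])
    def test_matches_exhaustive_permutation_search(self, n):
        """For identical spaces with distinct distances, the binarised plan
        must match the best permutation found by enumerating all n!."""
        rng = np.random.default_rng(n)
        ca = random_geometry(rng, n)
        perm = rng.permutation(n)
        cb = ca[np.ix_(perm, perm)]
        plan = entropic_gw(ca, cb)
        best_val, best_perm, second = np.inf, None, np.inf
        for p in itertools.permutations(range(n)):
            t = np.zeros((n, n))
            t[list(p), range(n)] = 1.0 / n
            val = gw_objective(ca, cb, t)
            if val < best_val:
                second, best_val, best_perm = best_val, val, p
            elif val < second:
                second = val
        assert second > best_val + 1e-12, "optimum not unique"
        cols = np.argmax(plan.matrix, axis=0)
        assert tuple(cols) == best_perm
        # the (rescaled) binarised plan cannot beat the best permutation
        t_bin = np.zeros((n, n))
        t_bin[cols, range(n)] = 1.0 / n
        assert gw_objective(ca, cb, t_bin) <= best_val + 1e-12

    def test_objective_matches_quadruple_sum(self, rng):
        ca = random_geometry(rng, 5)
        cb = random_geometry(rng, 4)
        plan = entropic_gw(ca, cb)
        assert gw_objective(ca, cb, plan.matrix) == pytest.approx(
            gw_quadruple_sum(ca, cb, plan.matrix), rel=1e-10
        )

    def test_zero_structures_give_product_coupling(self):
        a, b = uniform(4), uniform(5)
        plan = entropic_gw(np.zeros((4, 4)), np.zeros((5, 5)), a, b, lam=0.1)
        np.testing.assert_allclose(plan.matrix, np.outer(a, b), atol=1e-9)

    def test_objective_history_nonincreasing(self, rng):
        ca = random_geometry(rng, 12)
        cb = random_geometry(rng, 10)
        plan = entropic_gw(ca, cb)
        assert np.all(np.diff(plan.objective_history) <= 1e-12)
        assert plan.marginal_error() < 1e-6

    def test_symmetry_under_transposition(self, rng):
        ca = random_geometry(rng, 6)
        cb = random_geometry(rng, 6)
        p_ab = entropic_gw(ca, cb)
        p_ba = entropic_gw(cb, ca)
        assert gw_objective(ca, cb, p_ab.matrix) == pytest.approx(
            gw_objective(cb, ca, p_ba.matrix), rel=1e-4
        )


class TestFGW:
    def test_alpha_one_is_pure_gw(self, rng):
        ca = random_geometry(rng, 5)
        cb = random_geometry(rng, 5)
        fa = np.arange(5.0)
        fb = np.arange(5.0)[::-1].copy()
        val, plan = fgw_distance(ca, cb, fa, fb, alpha=1.0)
        ref = entropic_gw(ca, cb)
        assert val == pytest.approx(ref.objective_value, rel=1e-6, abs=1e-10)

    def test_alpha_zero_matches_labels(self, rng):
        ca = random_geometry(rng, 6)
        cb = random_geometry(rng, 6)
        fa = np.array([0.0, 0.0, 1.0, 1.0, 2.0, 2.0])
        fb = fa.copy()
        val, plan = fgw_distance(ca, cb, fa, fb, alpha=0.0, lam=1e-3)
        mass_on_matching = plan.matrix[fa[:, None] == fb[None, :]].sum()
        assert mass_on_matching > 0.99
        assert val < 1e-6

    def test_objective_matches_quadruple_sum(self, rng):
        n = 4
        ca = random_geometry(rng, n)
        cb = random_geometry(rng, n)
        fa = rng.integers(0, 4, n).astype(float)
        fb = rng.integers(0, 4, n).astype(float)
        alpha = 0.5
        val, plan = fgw_distance(ca, cb, fa, fb, alpha=alpha)
        t = plan.matrix
        direct = alpha * gw_quadruple_sum(ca, cb, t)
        for i in range(n):
            for j in range(n):
                direct += (1 - alpha) * (fa[i] - fb[j]) ** 2 * t[i, j]
        assert val == pytest.approx(direct, rel=1e-8)

    def test_alpha_validation(self, rng):
        ca = random_geometry(rng, 3)
        with pytest.raises(ValueError):
            fgw_distance(ca, ca, np.zeros(3), np.zeros(3), alpha=1.5)


class TestBarycenter:
    def _session(self, rng, n=12):
        c = random_geometry(rng, n)
        f = np.repeat(np.arange(4.0), n // 4)
        return c, f

    def test_single_input_reproduced_up_to_permutation(self, rng):
        c, f = self._session(rng)
        bary = fgw_barycenter([(c, f)], alpha=0.5)
        assert sorted(np.round(bary.features).astype(int)) == sorted(
            f.astype(int)
        )
        val, _ = fgw_distance(bary.distance_matrix, c, bary.features, f,
                              alpha=0.5)
        base = fgw_distance(c, c, f, f, alpha=0.5)[0]
        assert val <= base + 1e-4
        assert np.all(np.diff(bary.objective_history) <= 1e-12)

    def test_identical_inputs_track_self_distance(self, rng):
        """The Fréchet mean of K identical inputs achieves an objective no
        worse than the input's own entropic self-distance (the floor set by
        coupling blur), and reproduces the entry distribution."""
        c, f = self._session(rng)
        bary = fgw_barycenter([(c, f)] * 3, alpha=0.5)
        self_val, _ = fgw_distance(c, c, f, f, alpha=0.5)
        assert bary.objective_value <= 2.0 * self_val + 1e-12
        got = np.sort(bary.distance_matrix, axis=None)
        ref = np.sort(c, axis=None)
        assert np.quantile(np.abs(got - ref), 0.9) < 0.25 * c.max()

    def test_degenerate_weights_reduce_to_first_input(self, rng):
        c1, f1 = self._session(rng)
        c2, f2 = self._session(rng)
        zeta = np.array([1.0, 0.0])
        bary = fgw_barycenter([(c1, f1), (c2, f2)], zeta=zeta, alpha=0.5)
        ref = fgw_barycenter([(c1, f1)], alpha=0.5)
        assert bary.objective_value == pytest.approx(
            ref.objective_value, abs=1e-6
        )

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            fgw_barycenter([])

    def test_coupling_feasibility(self, rng):
        c1, f1 = self._session(rng)
        c2, f2 = self._session(rng)
        bary = fgw_barycenter([(c1, f1), (c2, f2)], alpha=0.5)
        for plan in bary.couplings:
            assert plan.marginal_error() < 1e-6
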