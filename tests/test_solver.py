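"""Pairwise LC solvers: oracle equivalence, feasibility, determinism."""

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from hmot.core import LatentRepresentation, transport_cost, assemble_plan
from hmot.solver import (
    GammaResult,
    SolverConfig,
    linear_ot,
    solve_gamma,
    solve_lc,
    solve_lc_fixed_left,
    solve_lc_fixed_right,
    solve_transition,
)

from conftest import lp_ot_reference, random_Q


def one_hot_Q(labels, a):
    r = int(np.max(labels)) + 1
    Q = np.zeros((len(labels), r))
    Q[np.arange(len(labels)), labels] = a
    return LatentRepresentation(Q)


def two_blocks(rng, n_per, sep=10.0, d=2):
    X = np.vstack(
        [rng.normal(0, 1, (n_per, d)), rng.normal(sep, 1, (n_per, d))]
    )
    labels = np.repeat([0, 1], n_per)
    return X, labels


class TestLinearOT:
    def test_matches_dense_lp_formulation(self, rng):
        for _ in range(20):
            r1, r2 = rng.integers(2, 8, size=2)
            M = rng.random((r1, r2))
            g1 = rng.dirichlet(np.ones(r1) * 3)
            g2 = rng.dirichlet(np.ones(r2) * 3)
            T = linear_ot(M, g1, g2)
            assert abs(float(np.sum(T * M)) - lp_ot_reference(M, g1, g2)) < 1e-9
            np.testing.assert_allclose(T.sum(axis=1), g1, atol=1e-12)
            np.testing.assert_allclose(T.sum(axis=0), g2, atol=1e-12)

    def test_assignment_oracle_uniform_square(self, rng):
        """On uniform square instances the optimum is an assignment / r."""
        for _ in range(10):
            r = int(rng.integers(3, 9))
            M = rng.random((r, r))
            g = np.full(r, 1.0 / r)
            T = linear_ot(M, g, g)
            ri, ci = linear_sum_assignment(M)
            assert abs(float(np.sum(T * M)) - M[ri, ci].sum() / r) < 1e-10

    def test_dual_certificate(self, rng):
        """Optimality certified by complementary slackness: potentials fit on
        the support must under-bid the cost everywhere."""
        for _ in range(10):
            r1, r2 = int(rng.integers(3, 7)), int(rng.integers(3, 7))
            M = rng.random((r1, r2))
            g1 = rng.dirichlet(np.ones(r1) * 4)
            g2 = rng.dirichlet(np.ones(r2) * 4)
            T = linear_ot(M, g1, g2)
            # solve f_i + h_j = M_ij on the support graph (least squares)
            idx = np.argwhere(T > 1e-10)
            A = np.zeros((len(idx), r1 + r2))
            A[np.arange(len(idx)), idx[:, 0]] = 1.0
            A[np.arange(len(idx)), r1 + idx[:, 1]] = 1.0
            sol, *_ = np.linalg.lstsq(A, M[idx[:, 0], idx[:, 1]], rcond=None)
            f, h = sol[:r1], sol[r1:]
            # support equations hold and duals are feasible
            assert np.max(np.abs(A @ sol - M[idx[:, 0], idx[:, 1]])) < 1e-8
            assert np.min(M - f[:, None] - h[None, :]) > -1e-8

    def test_rejects_zero_marginal(self):
        from hmot.core import DegenerateClusterError

        with pytest.raises(DegenerateClusterError):
            linear_ot(np.ones((2, 2)), np.array([1.0, 0.0]), np.array([0.5, 0.5]))


class TestSolveLC:
    def test_zero_cost(self, rng):
        a = rng.dirichlet(np.ones(6))
        b = rng.dirichlet(np.ones(7))
        res = solve_lc(np.zeros((6, 7)), a, b, 2, 3, SolverConfig(seed=0))
        assert res.objective == 0.0
        np.testing.assert_allclose(res.Q1.weights, a, atol=1e-12)
        np.testing.assert_allclose(res.T.T.sum(axis=1), res.Q1.g, atol=1e-8)

    def test_full_rank_reaches_lp(self, rng):
        for k in range(5):
            n = int(rng.integers(4, 9))
            C = rng.random((n, n))
            a = np.full(n, 1.0 / n)
            lp = lp_ot_reference(C, a, a)
            res = solve_lc(C, a, a, n, n, SolverConfig(seed=k))
            assert res.objective <= lp * 1.02 + 1e-12

    def test_block_structure_recovered(self, rng):
        X, labels = two_blocks(rng, 20)
        Y, _ = two_blocks(rng, 20)
        C = cdist(X, Y, "sqeuclidean")
        a = np.full(40, 1 / 40)
        res = solve_lc(C, a, a, 2, 2, SolverConfig(seed=0))
        S = res.Q1.Q / a[:, None]
        # each point's soft-cluster mass concentrates within its block
        purity = max(S[:20, 0].mean() + S[20:, 1].mean(),
                     S[:20, 1].mean() + S[20:, 0].mean()) / 2
        assert purity >= 0.95
        T = res.T.T
        diag_mass = max(T[0, 0] + T[1, 1], T[0, 1] + T[1, 0])
        assert diag_mass >= 0.95

    def test_trace_monotone_and_feasible(self, rng):
        C = rng.random((12, 15))
        a = rng.dirichlet(np.ones(12) * 4)
        b = rng.dirichlet(np.ones(15) * 4)
        res = solve_lc(C, a, b, 3, 4, SolverConfig(seed=1))
        assert np.all(np.diff(res.objective_trace) <= 1e-12)
        P = assemble_plan(res.Q1, res.Q2, res.T)
        np.testing.assert_allclose(P.sum(axis=1), a, atol=1e-7)
        np.testing.assert_allclose(P.sum(axis=0), b, atol=1e-7)

    def test_seeded_determinism_bitwise(self, rng):
        C = rng.random((10, 11))
        a = np.full(10, 0.1)
        b = np.full(11, 1 / 11)
        r1 = solve_lc(C, a, b, 3, 3, SolverConfig(seed=7))
        r2 = solve_lc(C, a, b, 3, 3, SolverConfig(seed=7))
        np.testing.assert_array_equal(r1.objective_trace, r2.objective_trace)
        np.testing.assert_array_equal(r1.Q1.Q, r2.Q1.Q)
        r3 = solve_lc(C, a, b, 3, 3, SolverConfig(seed=8))
        assert r3.objective <= r1.objective * 1.5 + 1e-9  # different seed still sane

    def test_invalid_ranks_rejected(self, rng):
        C = rng.random((4, 5))
        a, b = np.full(4, 0.25), np.full(5, 0.2)
        with pytest.raises(ValueError):
            solve_lc(C, a, b, 5, 2, SolverConfig(seed=0))
        with pytest.raises(ValueError):
            solve_lc(C, a, b, 0, 2, SolverConfig(seed=0))


class TestSolveFixed:
    def test_zero_cost_keeps_Q1(self, rng):
        Q1 = random_Q(rng, 6, 2)
        res = solve_lc_fixed_left(
            np.zeros((6, 7)), Q1, np.full(7, 1 / 7), 3, SolverConfig(seed=0)
        )
        assert res.objective == 0.0
        np.testing.assert_array_equal(res.Q1.Q, Q1.Q)

    def test_rank_one_matches_unrestricted(self, rng):
        C = rng.random((6, 8))
        a = np.full(6, 1 / 6)
        b = np.full(8, 1 / 8)
        Q1 = LatentRepresentation(a[:, None])
        fixed = solve_lc_fixed_left(C, Q1, b, 3, SolverConfig(seed=2))
        free = solve_lc(C, a, b, 1, 3, SolverConfig(seed=2))
        assert abs(fixed.objective - free.objective) <= 1e-6 * max(1, abs(free.objective))

    def test_blocks_recovered_given_truth_left(self, rng):
        X, labels = two_blocks(rng, 20)
        Y, _ = two_blocks(rng, 20)
        C = cdist(X, Y, "sqeuclidean")
        a = np.full(40, 1 / 40)
        Q1 = one_hot_Q(labels, a)
        res = solve_lc_fixed_left(C, Q1, a, 2, SolverConfig(seed=0))
        S = res.Q2.Q / a[:, None]
        purity = max(S[:20, 0].mean() + S[20:, 1].mean(),
                     S[:20, 1].mean() + S[20:, 0].mean()) / 2
        assert purity >= 0.95

    def test_fixed_right_mirrors_fixed_left(self, rng):
        C = rng.random((6, 7))
        a, b = np.full(6, 1 / 6), np.full(7, 1 / 7)
        Q2 = random_Q(rng, 7, 2, a=b)
        res = solve_lc_fixed_right(C, a, Q2, 3, SolverConfig(seed=3))
        mirrored = solve_lc_fixed_left(C.T, Q2, a, 3, SolverConfig(seed=3))
        assert abs(res.objective - mirrored.objective) <= 1e-9


class TestSolveTransition:
    def test_rank_one(self, rng):
        Q1 = LatentRepresentation(np.full((4, 1), 0.25))
        Q2 = LatentRepresentation(np.full((5, 1), 0.2))
        T = solve_transition(rng.random((4, 5)), Q1, Q2, SolverConfig(seed=0))
        np.testing.assert_allclose(T.T, [[1.0]])

    def test_matches_lp_on_one_hot(self, rng):
        labels1 = np.array([0, 0, 1, 1, 0, 1])
        labels2 = np.array([0, 1, 2, 0, 1, 2])
        a = np.full(6, 1 / 6)
        Q1, Q2 = one_hot_Q(labels1, a), one_hot_Q(labels2, a)
        C = rng.random((6, 6))
        T = solve_transition(C, Q1, Q2, SolverConfig(seed=0))
        L1 = Q1.Q / Q1.g
        L2 = Q2.Q / Q2.g
        M = L1.T @ C @ L2
        lp = lp_ot_reference(M, Q1.g, Q2.g)
        got = float(np.sum(T.T * M))
        assert abs(got - lp) <= 1e-8 * max(1, abs(lp))
        # objective consistent with the assembled plan
        assert abs(transport_cost(C, Q1, Q2, T) - got) < 1e-7

    def test_cheap_diagonal_wins(self):
        g = np.array([0.2, 0.3, 0.5])
        Q = LatentRepresentation(np.diag(g))
        M = np.full((3, 3), 10.0)
        np.fill_diagonal(M, 0.0)
        T = solve_transition(M, Q, Q, SolverConfig(seed=0))
        np.testing.assert_allclose(T.T, np.diag(g), atol=1e-9)


class TestSolveGamma:
    def _messages(self, rng, n_prev, n_next, r):
        Qa = random_Q(rng, n_prev, r)
        Qb = random_Q(rng, n_next, r)
        return Qa, Qb

    def test_zero_costs(self, rng):
        Qa, Qb = self._messages(rng, 5, 6, 2)
        res = solve_gamma(
            np.zeros((5, 4)),
            np.zeros((4, 6)),
            Qa.Q / Qa.g,
            Qb.Q / Qb.g,
            np.full(4, 0.25),
            2,
            SolverConfig(seed=0),
            g_alpha_prev=Qa.g,
            g_beta_next=Qb.g,
        )
        assert isinstance(res, GammaResult)
        assert res.objective == 0.0

    def test_consistent_blocks_agree(self, rng):
        """When past and future share a partition, the consensus matches it."""
        n = 30
        a = np.full(n, 1 / n)
        labels = np.repeat([0, 1], n // 2)
        Xs = [np.vstack([rng.normal(0, 1, (n // 2, 2)), rng.normal(12, 1, (n // 2, 2))])
              for _ in range(3)]
        C01 = cdist(Xs[0], Xs[1], "sqeuclidean")
        C12 = cdist(Xs[1], Xs[2], "sqeuclidean")
        Qtruth = one_hot_Q(labels, a)
        La = Qtruth.Q / Qtruth.g
        res = solve_gamma(
            C01, C12, La, La, a, 2, SolverConfig(seed=0),
            g_alpha_prev=Qtruth.g, g_beta_next=Qtruth.g,
        )
        S = res.Q.Q / a[:, None]
        half = n // 2
        purity = max(S[:half, 0].mean() + S[half:, 1].mean(),
                     S[:half, 1].mean() + S[half:, 0].mean()) / 2
        assert purity >= 0.95

    def test_consensus_beats_both_candidates(self, rng):
        """With conflicting messages the two-term loss of the consensus is no
        worse than either candidate scored under the same loss."""
        n = 20
        a = np.full(n, 1 / n)
        C01 = rng.random((15, n))
        C12 = rng.random((n, 18))
        Qa = random_Q(rng, 15, 2)
        Qb = random_Q(rng, 18, 2)
        cand_alpha = random_Q(rng, n, 2, a=a)
        cand_beta = random_Q(rng, n, 2, a=a)
        cfg = SolverConfig(seed=0)
        res = solve_gamma(
            C01, C12, Qa.Q / Qa.g, Qb.Q / Qb.g, a, 2, cfg,
            g_alpha_prev=Qa.g, g_beta_next=Qb.g,
            Q_candidates=(cand_alpha, cand_beta),
        )

        def two_term(Q):
            Tp = solve_transition(C01, Qa, Q, cfg)
            Tn = solve_transition(C12, Q, Qb, cfg)
            return transport_cost(C01, Qa, Q, Tp) + transport_cost(C12, Q, Qb, Tn)

        bound = min(two_term(cand_alpha), two_term(cand_beta))
        assert res.objective <= bound + cfg.inner_tol


class TestConfig:
    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            SolverConfig(max_outer_iters=0)
        with pytest.raises(ValueError):
            SolverConfig(inner_tol=0)
        with pytest.raises(ValueError):
            SolverConfig(init_mode="magic")
        with pytest.raises(ValueError):
            SolverConfig(on_degenerate="ignore")
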