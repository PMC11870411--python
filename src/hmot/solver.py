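"""Pairwise low-rank OT solvers in latent-coupling form.

The bilinear objective ``E(Q1, Q2, T) = <C, P(Q1, Q2, T)>_F`` is minimized
by block-coordinate descent.  For fixed representations the objective is
*linear* in the latent coupling — ``<C, P> = <T, Lambda1^T C Lambda2>`` —
so the ``T`` block is refreshed by an exact rank-scale linear program every
iteration (and the transition-only problem, :func:`solve_transition`, is a
single exact LP).  Each free representation takes a Frank-Wolfe step on its
row polytope ``Pi(a, .)``: the linearized objective is minimized at a
vertex (a hard reassignment of every point to its marginally cheapest
latent type) and a backtracking line search along the segment to that
vertex accepts only strict descent.  The objective trace is therefore
non-increasing by construction and every iterate is feasible.

The landscape is non-convex and flat around symmetric states (clusters that
are near-identical mixtures), so initialization does the heavy lifting.
Each solve evaluates a small menu of starts — a k-means assignment of the
embeddings when the cost is a factored (lazy) operator, a deterministic
balanced stride partition (which at full rank is ``Q = diag(a)``, making
the first ``T`` refresh the exact Wasserstein LP), and seeded Dirichlet
draws — and returns the best final objective.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .core import (
    CostOperator,
    CosineCost,
    DegenerateClusterError,
    LatentCoupling,
    LatentRepresentation,
    SquaredEuclideanCost,
    as_cost_operator,
    drop_empty_types,
)

__all__ = [
    "SolverConfig",
    "SolveResult",
    "GammaResult",
    "linear_ot",
    "solve_lc",
    "solve_lc_fixed_left",
    "solve_lc_fixed_right",
    "solve_transition",
    "solve_gamma",
]


@dataclass
class SolverConfig:
    """Hyperparameters for the LC solvers.

    Attributes
    ----------
    max_outer_iters
        Cap on outer (joint-update) iterations.
    inner_tol
        Convergence threshold on the relative objective change per outer
        iteration.
    entropic_eps
        Retained knob for entropic smoothing of coupling projections,
        relative to the mean cost.  The production updates use exact LP
        coupling refreshes, which correspond to the sharp limit; the value
        only matters for the Sinkhorn-based repair of near-feasible
        couplings and can normally be left alone.
    init_mode
        ``"random-dirichlet"`` or ``"kmeans-warmstart"``.  Both menus also
        include the deterministic stride partition; the warm start requires
        embeddings (a lazy cost operator) and falls back to Dirichlet rows
        when only a dense matrix is available.
    seed
        Mandatory RNG seed; all randomness flows from it.
    tau
        Temperature of the Boltzmann density over configurations.  The
        algorithm operates in the zero-temperature limit (point mass at the
        energy minimizer); the field is kept at 0.0 for documentation and
        is not read by the solver.
    min_latent_mass
        Floor below which a latent marginal entry counts as empty.
    n_restarts
        Number of Dirichlet starts added to the init menu.
    on_degenerate
        ``"error"`` raises :class:`DegenerateClusterError` when a returned
        representation has an empty type; ``"drop"`` removes the type.
    """

    max_outer_iters: int = 300
    inner_tol: float = 1e-6
    entropic_eps: float = 1e-2
    init_mode: str = "random-dirichlet"
    seed: int = 0
    tau: float = 0.0
    min_latent_mass: float = 1e-12
    n_restarts: int = 1
    on_degenerate: str = "error"

    def __post_init__(self):
        if self.max_outer_iters < 1:
            raise ValueError("max_outer_iters must be >= 1")
        if self.inner_tol <= 0:
            raise ValueError("inner_tol must be positive")
        if self.entropic_eps < 0:
            raise ValueError("entropic_eps must be nonnegative")
        if self.init_mode not in ("random-dirichlet", "kmeans-warmstart"):
            raise ValueError(f"unknown init_mode {self.init_mode!r}")
        if self.on_degenerate not in ("error", "drop"):
            raise ValueError("on_degenerate must be 'error' or 'drop'")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")


@dataclass
class SolveResult:
    """Solution of a pairwise LC problem."""

    Q1: LatentRepresentation
    Q2: LatentRepresentation
    T: LatentCoupling
    objective_trace: np.ndarray
    converged: bool

    @property
    def objective(self) -> float:
        return float(self.objective_trace[-1])


@dataclass
class GammaResult:
    """Solution of the consensus (smoothing) subproblem at one timepoint."""

    Q: LatentRepresentation
    T_prev: LatentCoupling
    T_next: LatentCoupling
    objective_trace: np.ndarray
    converged: bool

    @property
    def objective(self) -> float:
        return float(self.objective_trace[-1])


# ---------------------------------------------------------------------------
# Exact linear OT at rank scale
# ---------------------------------------------------------------------------


def linear_ot(M: np.ndarray, g1: np.ndarray, g2: np.ndarray) -> np.ndarray:
    """Exact solution of ``min_{T in Pi(g1, g2)} <T, M>`` by linear programming.

    Intended for rank-scale instances (``r`` up to a few hundred).  The
    returned matrix satisfies the marginal constraints to floating-point
    precision after a rounding correction of the LP solution.
    """
    M = np.asarray(M, dtype=float)
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    r1, r2 = M.shape
    if g1.shape != (r1,) or g2.shape != (r2,):
        raise ValueError("marginal lengths do not match the cost shape")
    if np.any(g1 <= 0) or np.any(g2 <= 0):
        raise DegenerateClusterError("linear OT needs strictly positive marginals")
    if r1 == 1 or r2 == 1:
        return np.outer(g1, g2)
    rows = sparse.kron(sparse.eye(r1), np.ones((1, r2)), format="csr")
    cols = sparse.kron(np.ones((1, r1)), sparse.eye(r2), format="csr")[:-1]
    A_eq = sparse.vstack([rows, cols], format="csr")
    b_eq = np.concatenate([g1, g2[:-1]])
    res = linprog(M.ravel(), A_eq=A_eq, b_eq=b_eq, bounds=(0, None), method="highs")
    if not res.success:  # pragma: no cover - HiGHS is reliable on feasible OT
        raise RuntimeError(f"linear OT solve failed: {res.message}")
    T = np.maximum(res.x.reshape(r1, r2), 0.0)
    return _round_to_marginals(T, g1, g2)


def _round_to_marginals(T: np.ndarray, g1: np.ndarray, g2: np.ndarray) -> np.ndarray:
    """Exact projection-by-rounding onto ``Pi(g1, g2)`` for a near-feasible plan.

    Rows and columns are scaled down where they overshoot their targets and
    the remaining deficit is filled by a rank-one nonnegative correction, so
    the output meets both marginals to floating-point rounding.
    """
    rs = T.sum(axis=1)
    T = T * np.where(rs > 0, np.minimum(1.0, g1 / np.where(rs > 0, rs, 1.0)), 1.0)[:, None]
    cs = T.sum(axis=0)
    T = T * np.where(cs > 0, np.minimum(1.0, g2 / np.where(cs > 0, cs, 1.0)), 1.0)[None, :]
    err_r = np.maximum(g1 - T.sum(axis=1), 0.0)
    err_c = np.maximum(g2 - T.sum(axis=0), 0.0)
    s = err_r.sum()
    if s > 0:
        T = T + np.outer(err_r, err_c) / s
    return T


def _sinkhorn_project(
    K: np.ndarray, g1: np.ndarray, g2: np.ndarray, tol: float = 1e-13, max_iter: int = 500
) -> np.ndarray:
    """Projection of a strictly positive matrix onto ``Pi(g1, g2)``:
    Sinkhorn scaling to tolerance, then the exact rounding correction."""
    T = np.maximum(K, 1e-300)
    for _ in range(max_iter):
        T *= (g1 / T.sum(axis=1))[:, None]
        T *= (g2 / T.sum(axis=0))[None, :]
        if np.max(np.abs(T.sum(axis=1) - g1)) < tol:
            break
    return _round_to_marginals(T, g1, g2)


# ---------------------------------------------------------------------------
# Initialization menu
# ---------------------------------------------------------------------------

#: per-entry mass floor (relative to the row weight) that keeps every latent
#: type marginally populated; perturbs objectives at the 1e-9 level
_FLOOR_FRAC = 1e-9

#: backtracking grid for Frank-Wolfe line searches
_LAMBDAS = (1.0, 0.5, 0.25, 0.1, 0.04, 0.015, 0.005, 0.001)


def _with_floor(Q: np.ndarray, a: np.ndarray) -> np.ndarray:
    r = Q.shape[1]
    Q = np.maximum(Q, (_FLOOR_FRAC / r) * a[:, None])
    return a[:, None] * (Q / Q.sum(axis=1, keepdims=True))


def _dirichlet_Q(rng: np.random.Generator, a: np.ndarray, r: int) -> np.ndarray:
    G = rng.gamma(1.0, size=(a.shape[0], r))
    return _with_floor(a[:, None] * (G / G.sum(axis=1, keepdims=True)), a)


def _stride_Q(a: np.ndarray, r: int) -> np.ndarray:
    """Deterministic balanced partition by index; ``diag(a)`` at full rank."""
    n = a.shape[0]
    Q = np.zeros((n, r))
    Q[np.arange(n), (np.arange(n) * r) // n] = a
    return _with_floor(Q, a)


def _kmeans_Q(points: np.ndarray, a: np.ndarray, r: int, seed: int) -> np.ndarray:
    from sklearn.cluster import KMeans

    labels = KMeans(n_clusters=r, n_init=2, random_state=seed % (2**31)).fit_predict(
        points
    )
    n = a.shape[0]
    Q = np.zeros((n, r))
    Q[np.arange(n), labels] = a
    return _with_floor(Q, a)


def _init_menu(
    rng: np.random.Generator,
    cfg: SolverConfig,
    a: np.ndarray,
    r: int,
    points: Optional[np.ndarray],
) -> list:
    menu = []
    if cfg.init_mode == "kmeans-warmstart" and points is not None and r <= len(a):
        menu.append(_kmeans_Q(points, a, r, cfg.seed))
    menu.append(_stride_Q(a, r))
    for _ in range(cfg.n_restarts):
        menu.append(_dirichlet_Q(rng, a, r))
    return menu


def _points_of(op: CostOperator, side: int) -> Optional[np.ndarray]:
    if isinstance(op, (SquaredEuclideanCost, CosineCost)):
        return op.X if side == 0 else op.Y
    return None


def _finalize_Q(Q: np.ndarray, cfg: SolverConfig) -> LatentRepresentation:
    rep = LatentRepresentation(Q)
    if np.any(rep.g < cfg.min_latent_mass):
        if cfg.on_degenerate == "drop":
            return drop_empty_types(rep, cfg.min_latent_mass)
        raise DegenerateClusterError(
            "solver produced an empty latent type; set on_degenerate='drop' "
            "or lower the rank"
        )
    return rep


def _fw_step(
    Q: np.ndarray, G: np.ndarray, a: np.ndarray, eval_obj, E: float
) -> tuple[np.ndarray, float, bool]:
    """One Frank-Wolfe step on ``Pi(a, .)``: line search toward the vertex
    minimizing the linearized objective; accepts only strict descent."""
    S = np.zeros_like(Q)
    S[np.arange(Q.shape[0]), np.argmin(G, axis=1)] = a
    S = _with_floor(S, a)
    for lam in _LAMBDAS:
        Qt = (1.0 - lam) * Q + lam * S
        Et = eval_obj(Qt)
        if Et < E:
            return Qt, Et, True
    return Q, E, False


# ---------------------------------------------------------------------------
# Pairwise LC solve (both / one representation free)
# ---------------------------------------------------------------------------


def _solve_pair(
    op: CostOperator,
    a: np.ndarray,
    b: np.ndarray,
    r1: int,
    r2: int,
    cfg: SolverConfig,
    Q1_fixed: Optional[np.ndarray],
    Q2_fixed: Optional[np.ndarray],
):
    floor = cfg.min_latent_mass
    rng = np.random.default_rng(cfg.seed)
    menu1 = [Q1_fixed] if Q1_fixed is not None else _init_menu(rng, cfg, a, r1, _points_of(op, 0))
    menu2 = [Q2_fixed] if Q2_fixed is not None else _init_menu(rng, cfg, b, r2, _points_of(op, 1))
    n_starts = max(len(menu1), len(menu2))

    def g_of(Q):
        return np.maximum(Q.sum(axis=0), floor)

    best = None
    for s in range(n_starts):
        Q1 = menu1[min(s, len(menu1) - 1)].copy()
        Q2 = menu2[min(s, len(menu2) - 1)].copy()
        L2 = Q2 / g_of(Q2)[None, :]
        CL2 = op.dot(L2)  # (n, r2), refreshed when Q2 moves
        M = (Q1 / g_of(Q1)[None, :]).T @ CL2
        T = linear_ot(M, g_of(Q1), g_of(Q2))
        E = float(np.sum(T * M))
        trace = [E]
        converged = False
        for _ in range(cfg.max_outer_iters):
            E_prev = E
            # Q1 block: Frank-Wolfe against the exact gradient.  Candidates
            # are scored with the coupling re-rounded onto their own
            # marginals, so every evaluation is of a feasible triple and
            # the exact LP refresh afterwards can only descend further.
            if Q1_fixed is None:
                g1 = g_of(Q1)
                G1 = (CL2 @ T.T) / g1[None, :] - ((T * M).sum(axis=1) / g1)[None, :]
                g2c = g_of(Q2)

                def eval1(Qt):
                    Tt = _round_to_marginals(T, g_of(Qt), g2c)
                    return float(np.sum(Tt * ((Qt / g_of(Qt)[None, :]).T @ CL2)))

                Q1, E, moved = _fw_step(Q1, G1, a, eval1, E)
                if moved:
                    M = (Q1 / g_of(Q1)[None, :]).T @ CL2
                    T = linear_ot(M, g_of(Q1), g_of(Q2))
                    E = float(np.sum(T * M))
            # Q2 block
            if Q2_fixed is None:
                L1 = Q1 / g_of(Q1)[None, :]
                CtL1 = op.tdot(L1)  # (m, r1)
                g2 = g_of(Q2)
                G2 = (CtL1 @ T) / g2[None, :] - ((T * M).sum(axis=0) / g2)[None, :]
                g1c = g_of(Q1)

                def eval2(Qt):
                    Tt = _round_to_marginals(T, g1c, g_of(Qt))
                    return float(np.sum(Tt * (((Qt / g_of(Qt)[None, :]).T @ CtL1).T)))

                Q2, E, moved = _fw_step(Q2, G2, b, eval2, E)
                if moved:
                    L2 = Q2 / g_of(Q2)[None, :]
                    CL2 = op.dot(L2)
                    M = (Q1 / g_of(Q1)[None, :]).T @ CL2
                    T = linear_ot(M, g_of(Q1), g_of(Q2))
                    E = float(np.sum(T * M))
            trace.append(E)
            if abs(E_prev - E) <= cfg.inner_tol * max(1.0, abs(E_prev)):
                converged = True
                break
        if best is None or E < best[3]:
            best = (Q1, Q2, T, E, np.asarray(trace), converged)
    Q1, Q2, T, _, trace, converged = best
    return Q1, Q2, T, trace, converged


def _pair_result(Q1, Q2, T, trace, converged, cfg) -> SolveResult:
    rep1 = _finalize_Q(Q1, cfg)
    rep2 = _finalize_Q(Q2, cfg)
    if rep1.rank != Q1.shape[1] or rep2.rank != Q2.shape[1]:
        keep1 = Q1.sum(axis=0) >= cfg.min_latent_mass
        keep2 = Q2.sum(axis=0) >= cfg.min_latent_mass
        T = _round_to_marginals(T[np.ix_(keep1, keep2)], rep1.g, rep2.g)
    else:
        T = _round_to_marginals(T, rep1.g, rep2.g)
    coupling = LatentCoupling(T, rep1.g, rep2.g)
    return SolveResult(rep1, rep2, coupling, trace, converged)


def solve_lc(C, a, b, r1: int, r2: int, cfg: SolverConfig) -> SolveResult:
    """Low-rank balanced Wasserstein solve with both representations free.

    Minimizes ``<C, P(Q1, Q2, T)>_F`` over LC factorizations of plans in
    ``Pi(a, b)`` with ranks ``(r1, r2)``.  Deterministic given ``cfg.seed``;
    non-convergence is reported via ``converged=False``, never silently.
    """
    op = as_cost_operator(C)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n, m = op.shape
    if not (1 <= r1 <= n and 1 <= r2 <= m):
        raise ValueError(f"ranks (r1={r1}, r2={r2}) must satisfy 1 <= r <= n")
    if a.shape != (n,) or b.shape != (m,):
        raise ValueError("marginal lengths do not match the cost shape")
    out = _solve_pair(op, a, b, r1, r2, cfg, None, None)
    return _pair_result(*out, cfg)


def solve_lc_fixed_left(C, Q1_fixed: LatentRepresentation, b, r2: int, cfg) -> SolveResult:
    """LC solve conditioning on a frozen left representation (Q2, T free)."""
    op = as_cost_operator(C)
    b = np.asarray(b, dtype=float)
    n, m = op.shape
    if Q1_fixed.n != n:
        raise ValueError("Q1_fixed does not match the cost shape")
    if np.any(Q1_fixed.g < cfg.min_latent_mass):
        raise DegenerateClusterError("Q1_fixed has an empty latent type")
    if not (1 <= r2 <= m):
        raise ValueError("invalid rank r2")
    Q1, Q2, T, trace, conv = _solve_pair(
        op, Q1_fixed.weights, b, Q1_fixed.rank, r2, cfg, Q1_fixed.Q, None
    )
    res = _pair_result(Q1, Q2, T, trace, conv, cfg)
    return SolveResult(Q1_fixed, res.Q2, res.T, res.objective_trace, res.converged)


def solve_lc_fixed_right(C, a, Q2_fixed: LatentRepresentation, r1: int, cfg) -> SolveResult:
    """Mirror image of :func:`solve_lc_fixed_left` (Q1, T free)."""
    op = as_cost_operator(C)
    a = np.asarray(a, dtype=float)
    n, m = op.shape
    if Q2_fixed.n != m:
        raise ValueError("Q2_fixed does not match the cost shape")
    if np.any(Q2_fixed.g < cfg.min_latent_mass):
        raise DegenerateClusterError("Q2_fixed has an empty latent type")
    if not (1 <= r1 <= n):
        raise ValueError("invalid rank r1")
    Q1, Q2, T, trace, conv = _solve_pair(
        op, a, Q2_fixed.weights, r1, Q2_fixed.rank, cfg, None, Q2_fixed.Q
    )
    res = _pair_result(Q1, Q2, T, trace, conv, cfg)
    return SolveResult(res.Q1, Q2_fixed, res.T, res.objective_trace, res.converged)


def solve_transition(
    C, Q1_fixed: LatentRepresentation, Q2_fixed: LatentRepresentation, cfg: SolverConfig
) -> LatentCoupling:
    """Optimal latent coupling between two frozen representations.

    With both representations fixed the objective is linear in ``T``:
    ``<C, P> = <T, Lambda1^T C Lambda2>``, an ``r1 x r2`` linear OT problem
    with marginals ``(g1, g2)``, solved exactly.
    """
    op = as_cost_operator(C)
    if op.shape != (Q1_fixed.n, Q2_fixed.n):
        raise ValueError("cost shape does not match the representations")
    g1, g2 = Q1_fixed.g, Q2_fixed.g
    if np.any(g1 < cfg.min_latent_mass) or np.any(g2 < cfg.min_latent_mass):
        raise DegenerateClusterError("transition solve needs positive latent mass")
    L2 = Q2_fixed.Q / g2[None, :]
    M = (Q1_fixed.Q / g1[None, :]).T @ op.dot(L2)
    T = linear_ot(M, g1, g2)
    return LatentCoupling(T, g1, g2)


# ---------------------------------------------------------------------------
# Consensus (smoothing) subproblem
# ---------------------------------------------------------------------------


def solve_gamma(
    C_prev,
    C_next,
    Lambda_alpha_prev: np.ndarray,
    Lambda_beta_next: np.ndarray,
    a_t: np.ndarray,
    r_t: int,
    cfg: SolverConfig,
    g_alpha_prev: Optional[np.ndarray] = None,
    g_beta_next: Optional[np.ndarray] = None,
    Q_candidates: Optional[Sequence] = None,
) -> GammaResult:
    """Smoothed representation at one timepoint given frozen messages.

    Minimizes the local two-term loss

        <C_prev, Lambda_alpha T_prev Lambda^T> + <C_next, Lambda T_next Lambda_beta^T>

    over the middle representation ``Q`` (emission normalization
    ``Lambda``) and both local transitions, which are treated as free
    variables of the subproblem.  The transitions live in
    ``Pi(g_alpha_prev, g)`` and ``Pi(g, g_beta_next)``; emission matrices
    do not determine their own marginals, so the message marginals are
    passed alongside (uniform when omitted).  ``Q_candidates`` may supply
    warm starts (typically the forward and backward estimates at this
    timepoint); every candidate is scored under the two-term loss with its
    exactly-optimal transitions and refined, so the returned objective
    never exceeds the best candidate's.
    """
    op_p = as_cost_operator(C_prev)
    op_n = as_cost_operator(C_next)
    a_t = np.asarray(a_t, dtype=float)
    La = np.asarray(Lambda_alpha_prev, dtype=float)
    Lb = np.asarray(Lambda_beta_next, dtype=float)
    n = a_t.shape[0]
    if op_p.shape[1] != n or op_n.shape[0] != n:
        raise ValueError("cost shapes do not chain through the middle timepoint")
    if La.shape[0] != op_p.shape[0] or Lb.shape[0] != op_n.shape[1]:
        raise ValueError("message shapes do not match the costs")
    floor = cfg.min_latent_mass
    g_prev = (
        np.full(La.shape[1], 1.0 / La.shape[1])
        if g_alpha_prev is None
        else np.asarray(g_alpha_prev, dtype=float)
    )
    g_next = (
        np.full(Lb.shape[1], 1.0 / Lb.shape[1])
        if g_beta_next is None
        else np.asarray(g_beta_next, dtype=float)
    )

    CtLa = op_p.tdot(La)  # (n, r_prev)
    CLb = op_n.dot(Lb)  # (n, r_next)

    def g_of(Q):
        return np.maximum(Q.sum(axis=0), floor)

    def two_term(Q, Tp, Tn):
        L = Q / g_of(Q)[None, :]
        M1 = CtLa.T @ L
        M2 = L.T @ CLb
        return float(np.sum(Tp * M1) + np.sum(Tn * M2)), M1, M2

    def optimal_transitions(Q):
        g = g_of(Q)
        L = Q / g[None, :]
        Tp = linear_ot(CtLa.T @ L, g_prev, g)
        Tn = linear_ot(L.T @ CLb, g, g_next)
        return Tp, Tn

    rng = np.random.default_rng(cfg.seed)
    starts: list[np.ndarray] = []
    if Q_candidates:
        for cand in Q_candidates:
            Qc = cand.Q if isinstance(cand, LatentRepresentation) else np.asarray(cand)
            if Qc.shape == (n, r_t):
                starts.append(
                    _with_floor(
                        a_t[:, None]
                        * (Qc / np.maximum(Qc.sum(axis=1, keepdims=True), 1e-300)),
                        a_t,
                    )
                )
    if not starts:
        starts.append(_stride_Q(a_t, r_t))
        starts.append(_dirichlet_Q(rng, a_t, r_t))

    best = None
    for Q0 in starts:
        Q = Q0
        Tp, Tn = optimal_transitions(Q)
        E, M1, M2 = two_term(Q, Tp, Tn)
        trace = [E]
        converged = False
        for _ in range(cfg.max_outer_iters):
            E_prev = E
            g = g_of(Q)
            G = (CtLa @ Tp) / g[None, :] - ((Tp * M1).sum(axis=0) / g)[None, :]
            G = G + (CLb @ Tn.T) / g[None, :] - ((Tn * M2).sum(axis=1) / g)[None, :]

            def eval_q(Qt):
                gt = g_of(Qt)
                E_t, _, _ = two_term(
                    Qt,
                    _round_to_marginals(Tp, g_prev, gt),
                    _round_to_marginals(Tn, gt, g_next),
                )
                return E_t

            Q, E, moved = _fw_step(Q, G, a_t, eval_q, E)
            if moved:
                Tp, Tn = optimal_transitions(Q)
                E, M1, M2 = two_term(Q, Tp, Tn)
            trace.append(E)
            if abs(E_prev - E) <= cfg.inner_tol * max(1.0, abs(E_prev)):
                converged = True
                break
        if best is None or E < best[3]:
            best = (Q, Tp, Tn, E, np.asarray(trace), converged)

    Q, Tp, Tn, _, trace, converged = best
    rep = _finalize_Q(Q, cfg)
    if rep.rank != Q.shape[1]:
        keep = Q.sum(axis=0) >= cfg.min_latent_mass
        Tp, Tn = Tp[:, keep], Tn[keep]
    g = rep.g
    Tp = _round_to_marginals(Tp, g_prev, g)
    Tn = _round_to_marginals(Tn, g, g_next)
    return GammaResult(
        rep,
        LatentCoupling(Tp, g_prev, g),
        LatentCoupling(Tn, g, g_next),
        trace,
        converged,
    )
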