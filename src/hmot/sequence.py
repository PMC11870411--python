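"""Sequence-level inference: forward/backward passes, consensus smoothing,
and the transition-completion step.

Given pairwise costs ``C^(t,t+1)`` between ``N`` timepoints, the global
objective is the total transport cost of the chain,

    sum_t <C^(t,t+1), P(Q_t, Q_{t+1}, T^(t,t+1))>_F,

over per-timepoint latent representations ``Q_t`` (rank ``r_t``) and latent
couplings ``T^(t,t+1)``.  Exact dynamic programming over these continuous,
constrained variables is infeasible, so the per-timepoint representations
are estimated as approximate MAP states of the Boltzmann density over
configurations in the zero-temperature limit: a greedy forward pass
conditions each ``Q_{t+1}`` on ``Q_t`` (alpha), a greedy backward pass runs
the mirror image (beta), and a consensus pass re-estimates each interior
``Q_t`` from the frozen forward message at ``t - 1`` and backward message at
``t + 1`` (gamma).  A final completion pass solves the decoupled pairwise
linear OT problems between the smoothed representations, yielding the
differentiation map.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Optional, Sequence

import numpy as np

from .core import (
    DifferentiationMap,
    LatentRepresentation,
    as_cost_operator,
    emission_matrix,
    transport_cost,
)
from .solver import (
    SolverConfig,
    solve_gamma,
    solve_lc,
    solve_lc_fixed_left,
    solve_lc_fixed_right,
    solve_transition,
)

__all__ = ["FitResult", "alpha_pass", "beta_pass", "fit", "total_cost"]


@dataclass
class FitResult:
    """Output of :func:`fit`: smoothed representations plus the differentiation map."""

    Qs: list
    dmap: DifferentiationMap
    total_cost: float
    converged: bool
    stage_converged: dict

    def __iter__(self):
        # allows ``Qs, dmap = fit(...)``
        return iter((self.Qs, self.dmap))


def _stage_cfg(cfg: SolverConfig, stage: int) -> SolverConfig:
    """Derive a deterministic per-stage seed; stage 0 keeps cfg verbatim."""
    if stage == 0:
        return cfg
    return replace(cfg, seed=int((cfg.seed + 7919 * stage) % (2**31)))


def _check_chain(costs: Sequence, marginals: Sequence, ranks: Optional[Sequence]):
    ops = [as_cost_operator(C) for C in costs]
    margs = [np.asarray(a, dtype=float) for a in marginals]
    N = len(margs)
    if N < 2:
        raise ValueError("a time series needs at least two timepoints")
    if len(ops) != N - 1:
        raise ValueError(f"need {N - 1} cost matrices for {N} timepoints")
    for t, op in enumerate(ops):
        if op.shape != (margs[t].shape[0], margs[t + 1].shape[0]):
            raise ValueError(
                f"cost {t} has shape {op.shape}, expected "
                f"({margs[t].shape[0]}, {margs[t + 1].shape[0]})"
            )
    if ranks is not None and len(ranks) != N:
        raise ValueError(f"need {N} ranks for {N} timepoints")
    return ops, margs


def alpha_pass(
    costs: Sequence,
    marginals: Sequence,
    ranks: Sequence[int],
    cfg: SolverConfig,
    fixed: Optional[Mapping[int, LatentRepresentation]] = None,
) -> list:
    """Greedy forward estimates ``Q_t^alpha`` for every timepoint.

    The first pair is solved jointly; every subsequent representation is
    solved conditioning on the previous one (frozen).  ``fixed`` may pin a
    subset of timepoints to given representations (partial supervision);
    pinned timepoints are taken verbatim and condition their neighbors.
    """
    ops, margs = _check_chain(costs, marginals, ranks)
    fixed = dict(fixed or {})
    N = len(margs)
    out: list = [None] * N

    if 0 in fixed and 1 in fixed:
        out[0], out[1] = fixed[0], fixed[1]
    elif 0 in fixed:
        res = solve_lc_fixed_left(ops[0], fixed[0], margs[1], ranks[1], _stage_cfg(cfg, 0))
        out[0], out[1] = fixed[0], res.Q2
    elif 1 in fixed:
        res = solve_lc_fixed_right(ops[0], margs[0], fixed[1], ranks[0], _stage_cfg(cfg, 0))
        out[0], out[1] = res.Q1, fixed[1]
    else:
        res = solve_lc(ops[0], margs[0], margs[1], ranks[0], ranks[1], _stage_cfg(cfg, 0))
        out[0], out[1] = res.Q1, res.Q2

    for t in range(1, N - 1):
        if t + 1 in fixed:
            out[t + 1] = fixed[t + 1]
        else:
            res = solve_lc_fixed_left(
                ops[t], out[t], margs[t + 1], ranks[t + 1], _stage_cfg(cfg, t)
            )
            out[t + 1] = res.Q2
    return out


def _transposed_chain(costs, marginals, ranks, fixed):
    ops = [as_cost_operator(C).transpose() for C in reversed(costs)]
    margs = list(reversed(marginals))
    rks = list(reversed(ranks)) if ranks is not None else None
    N = len(margs)
    fx = {N - 1 - t: Q for t, Q in (fixed or {}).items()}
    return ops, margs, rks, fx


def beta_pass(
    costs: Sequence,
    marginals: Sequence,
    ranks: Sequence[int],
    cfg: SolverConfig,
    fixed: Optional[Mapping[int, LatentRepresentation]] = None,
) -> list:
    """Greedy backward estimates ``Q_t^beta``: the forward pass on the
    reversed series with transposed costs."""
    ops, margs, rks, fx = _transposed_chain(costs, marginals, ranks, fixed)
    return list(reversed(alpha_pass(ops, margs, rks, cfg, fixed=fx)))


def total_cost(costs: Sequence, Qs: Sequence[LatentRepresentation], dmap: DifferentiationMap) -> float:
    """Global chain objective, evaluated plan-free (no ``n x m`` products)."""
    if len(Qs) != dmap.n_timepoints or len(costs) != len(Qs) - 1:
        raise ValueError("costs, representations and map lengths do not chain")
    return float(
        sum(
            transport_cost(costs[t], Qs[t], Qs[t + 1], dmap.couplings[t])
            for t in range(len(costs))
        )
    )


def fit(
    costs: Sequence,
    marginals: Sequence,
    ranks: Sequence[int],
    cfg: SolverConfig,
    fixed: Optional[Mapping[int, LatentRepresentation]] = None,
) -> FitResult:
    """Full sequence solve: alpha and beta passes, consensus smoothing of the
    interior timepoints, endpoint assignment, and transition completion.

    With ``N = 2`` the machinery degenerates to the single pairwise low-rank
    solve.  Endpoints keep their single informative direction
    (``Q_1 = Q_1^alpha``, ``Q_N = Q_N^beta``).  ``fixed`` pins a subset of
    timepoints (partial supervision); pinned representations are frozen in
    every pass.
    """
    ops, margs = _check_chain(costs, marginals, ranks)
    fixed = dict(fixed or {})
    N = len(margs)
    stage_conv: dict = {}

    if N == 2 and not fixed:
        res = solve_lc(ops[0], margs[0], margs[1], ranks[0], ranks[1], _stage_cfg(cfg, 0))
        Qs = [res.Q1, res.Q2]
        dmap = DifferentiationMap((res.T,), (res.Q1.g, res.Q2.g))
        stage_conv["pair"] = res.converged
        return FitResult(Qs, dmap, res.objective, res.converged, stage_conv)

    alpha = alpha_pass(ops, margs, ranks, cfg, fixed=fixed)
    beta = beta_pass(ops, margs, ranks, cfg, fixed=fixed)

    gamma: list = [None] * N
    gamma[0] = fixed.get(0, alpha[0])
    gamma[N - 1] = fixed.get(N - 1, beta[N - 1])
    for t in range(N - 2, 0, -1):
        if t in fixed:
            gamma[t] = fixed[t]
            continue
        res = solve_gamma(
            ops[t - 1],
            ops[t],
            emission_matrix(alpha[t - 1]),
            emission_matrix(beta[t + 1]),
            margs[t],
            ranks[t],
            _stage_cfg(cfg, N + t),
            g_alpha_prev=alpha[t - 1].g,
            g_beta_next=beta[t + 1].g,
            Q_candidates=(alpha[t], beta[t]),
        )
        gamma[t] = res.Q
        stage_conv[f"gamma_{t}"] = res.converged

    # The local smoothing recursion is not guaranteed to lower the *global*
    # chain cost relative to the greedy passes it consumed, so the smoothed
    # sequence competes with both of them under the completed objective and
    # the cheapest sequence wins (the smoothed one on ties).
    def _complete(Qseq):
        cps = tuple(
            solve_transition(ops[t], Qseq[t], Qseq[t + 1], cfg) for t in range(N - 1)
        )
        dm = DifferentiationMap(cps, tuple(Q.g for Q in Qseq))
        return dm, total_cost(ops, Qseq, dm)

    candidates = [("gamma", gamma), ("alpha", alpha), ("beta", beta)]
    if fixed:
        candidates = [
            (name, [fixed.get(t, Q) for t, Q in enumerate(seq)])
            for name, seq in candidates
        ]
    best = None
    for name, Qseq in candidates:
        dm, tot = _complete(Qseq)
        if best is None or tot < best[3] - 1e-12:
            best = (name, Qseq, dm, tot)
    stage_conv["selected"] = best[0]
    converged = all(v for k, v in stage_conv.items() if k != "selected") or not stage_conv
    return FitResult(list(best[1]), best[2], best[3], converged, stage_conv)
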