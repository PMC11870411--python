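"""Supervised and partially supervised differentiation-map inference.

When cell-type annotations are available, each labeling determines a unique
latent representation (``Q_{i,k} = a_i`` iff cell ``i`` carries label ``k``),
so the chain objective decouples in time and reduces to ``N - 1``
independent rank-scale linear OT problems for the transitions.  With only a
subset of timepoints annotated, the fixed representations are frozen inside
the forward/backward/consensus passes and the free timepoints are smoothed
as usual.
"""

from __future__ import annotations

import logging
from typing import Mapping, Optional, Sequence

import numpy as np

from .core import DifferentiationMap, LatentRepresentation
from .sequence import FitResult, fit as _fit
from .solver import SolverConfig, solve_transition

__all__ = ["labels_to_Q", "fit_supervised", "fit_partial"]

logger = logging.getLogger("hmot")


def labels_to_Q(
    labels: Sequence,
    a: np.ndarray,
    type_order: Optional[Sequence] = None,
) -> LatentRepresentation:
    """The unique latent representation induced by a hard labeling.

    ``Q_{i,k} = a_i`` if ``labels[i]`` is type ``k`` and 0 otherwise; the
    latent marginal ``g_k`` is the total weight of type ``k``.  The latent
    axis is ordered by ``type_order`` when given (unseen labels are an
    error), else lexicographically.  Types with zero mass at this timepoint
    are dropped with a warning, since ``diag(1/g)`` is undefined for them.
    """
    labels = list(labels)
    if len(labels) == 0:
        raise ValueError("empty label vector")
    if any(l is None or (isinstance(l, float) and np.isnan(l)) for l in labels):
        raise ValueError("labels must be non-missing")
    a = np.asarray(a, dtype=float)
    if a.shape[0] != len(labels):
        raise ValueError("labels and weights have different lengths")
    if type_order is None:
        order = sorted(set(str(l) for l in labels))
    else:
        order = [str(t) for t in type_order]
        unseen = set(str(l) for l in labels) - set(order)
        if unseen:
            raise ValueError(f"labels not in type_order: {sorted(unseen)}")
    index = {t: k for k, t in enumerate(order)}
    Q = np.zeros((len(labels), len(order)))
    Q[np.arange(len(labels)), [index[str(l)] for l in labels]] = a
    present = Q.sum(axis=0) > 0
    if not present.all():
        dropped = [t for t, p in zip(order, present) if not p]
        logger.warning(
            "dropping %d zero-mass annotated type(s) at this timepoint: %s",
            len(dropped),
            dropped,
        )
        Q = Q[:, present]
        order = [t for t, p in zip(order, present) if p]
    return LatentRepresentation(Q, type_names=tuple(order))


def fit_supervised(
    costs: Sequence,
    Q_fixed: Sequence[LatentRepresentation],
    cfg: SolverConfig,
) -> DifferentiationMap:
    """Differentiation map between fully annotated timepoints.

    Solves the ``N - 1`` decoupled pairwise linear OT problems
    ``min_{T in Pi(g_t, g_{t+1})} <T, Lambda_t^T C^(t,t+1) Lambda_{t+1}>``
    exactly; the problems are independent, so solve order is irrelevant.
    """
    if len(Q_fixed) != len(costs) + 1:
        raise ValueError("need one representation per timepoint")
    couplings = tuple(
        solve_transition(costs[t], Q_fixed[t], Q_fixed[t + 1], cfg)
        for t in range(len(costs))
    )
    names = (
        tuple(Q.type_names for Q in Q_fixed)
        if all(Q.type_names is not None for Q in Q_fixed)
        else None
    )
    return DifferentiationMap(couplings, tuple(Q.g for Q in Q_fixed), type_names=names)


def fit_partial(
    costs: Sequence,
    fixed: Mapping[int, LatentRepresentation],
    marginals: Sequence,
    ranks: Sequence[int],
    cfg: SolverConfig,
) -> FitResult:
    """Chain solve with an arbitrary subset of timepoints pinned to annotations.

    The pinned representations act as frozen messages in the forward,
    backward and consensus passes; free timepoints receive smoothed
    estimates.  With every timepoint pinned this routes to
    :func:`fit_supervised` and the outputs coincide exactly.
    """
    fixed = dict(fixed)
    if not fixed:
        raise ValueError("fixed must pin at least one timepoint")
    N = len(marginals)
    if any(not (0 <= t < N) for t in fixed):
        raise IndexError("fixed timepoint index out of range")
    if len(fixed) == N:
        Qs = [fixed[t] for t in range(N)]
        dmap = fit_supervised(costs, Qs, cfg)
        from .sequence import total_cost

        return FitResult(Qs, dmap, total_cost(costs, Qs, dmap), True, {})
    return _fit(costs, marginals, ranks, cfg, fixed=fixed)
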