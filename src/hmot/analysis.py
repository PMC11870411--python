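"""Co-clustering readouts and differentiation-map quality metrics.

Maximum-likelihood clustering reads hard labels off a latent
representation; ancestral co-clustering pulls each descendant cell back to
its most likely ancestor type, giving labels that are consistent across the
whole series (phylogenetic view).  Map quality is scored by pointwise
mutual information — the log-ratio of a transition's joint probability to
its independence prediction — and its normalization NPMI in ``[-1, 1]``
(+1 perfect correspondence, 0 independence, -1 never co-occur).  Clustering
agreement against ground truth uses adjusted mutual information (AMI).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import adjusted_mutual_info_score

from .core import DifferentiationMap, LatentCoupling, LatentRepresentation, compose_transitions

__all__ = [
    "ml_cluster",
    "ancestral_cocluster",
    "ancestral_labels_series",
    "pmi",
    "npmi",
    "ami",
    "match_clusters",
    "kernel_tv",
    "benchmark_vs_kmeans",
]


def ml_cluster(Q: LatentRepresentation) -> np.ndarray:
    """Maximum-likelihood cluster labels: row-wise argmax of ``Q``.

    Ties break to the lowest column index (deterministic).
    """
    return np.argmax(Q.Q, axis=1)


def ancestral_cocluster(
    Q_s: LatentRepresentation, T: LatentCoupling, Q_t: LatentRepresentation
) -> np.ndarray:
    """Labels at the descendant timepoint expressed in ancestor-cluster identities.

    Each point at time ``t`` is ML-assigned to its descendant cluster, whose
    mass is pulled back through ``T`` to the most likely ancestor cluster at
    time ``s`` (column argmax of ``T``); that ancestor index is returned.
    Composite couplings from :func:`~hmot.core.compose_transitions` trace
    ancestry across non-consecutive timepoints the same way.
    """
    Tm = T.T if isinstance(T, LatentCoupling) else np.asarray(T, dtype=float)
    if Tm.shape != (Q_s.rank, Q_t.rank):
        raise ValueError("coupling shape does not match the representations")
    if np.any(Tm.sum(axis=0) <= 0):
        raise ValueError("coupling has a zero-mass descendant column")
    desc = ml_cluster(Q_t)
    ancestor_of = np.argmax(Tm, axis=0)
    return ancestor_of[desc]


def ancestral_labels_series(
    Qs: Sequence[LatentRepresentation],
    dmap: DifferentiationMap,
    reference: int = 0,
) -> list:
    """Per-timepoint labels, all expressed in the reference timepoint's clusters.

    Timepoints at or before ``reference`` keep / trace their own identities
    forward is not defined; this helper labels every ``t >= reference`` in
    the reference clusters (``t == reference`` is plain ML clustering).
    """
    out = []
    for t in range(reference, dmap.n_timepoints):
        if t == reference:
            out.append(ml_cluster(Qs[t]))
        else:
            Tst = compose_transitions(dmap, reference, t)
            fake = LatentCoupling(
                Tst, dmap.marginals[reference], dmap.marginals[t]
            )
            out.append(ancestral_cocluster(Qs[reference], fake, Qs[t]))
    return out


def pmi(T: LatentCoupling) -> np.ndarray:
    """Pointwise mutual information ``log T_ab / (g_s,a g_t,b)`` per cell.

    Zero-probability transitions give ``-inf`` (they never co-occur).
    """
    Tm, gs, gt = T.T, T.source_marginal, T.target_marginal
    if np.any(gs <= 0) or np.any(gt <= 0):
        raise ValueError("PMI undefined for zero latent marginals")
    indep = np.outer(gs, gt)
    with np.errstate(divide="ignore"):
        return np.log(Tm) - np.log(indep)


def npmi(T: LatentCoupling) -> np.ndarray:
    """Normalized PMI, ``PMI(a,b) / (-log T_ab)``, in ``[-1, 1]``.

    +1 marks perfect correspondence (a diagonal coupling scores +1 on the
    diagonal), 0 independence, and exactly -1 where ``T_ab = 0``.  Cells
    with ``T_ab = 1`` (a single full-mass transition) are 0 by the
    independence convention.
    """
    Tm = T.T
    P = pmi(T)
    denom = -np.log(np.where(Tm > 0, Tm, 0.5))  # placeholder where T == 0
    out = np.where(
        Tm > 0,
        np.divide(P, denom, out=np.zeros_like(denom), where=denom > 0),
        -1.0,
    )
    return np.clip(out, -1.0, 1.0)


def ami(labels_a: Sequence, labels_b: Sequence) -> float:
    """Adjusted mutual information between two labelings (chance-corrected)."""
    labels_a = np.asarray(labels_a)
    labels_b = np.asarray(labels_b)
    if labels_a.shape != labels_b.shape:
        raise ValueError("label vectors have different lengths")
    return float(adjusted_mutual_info_score(labels_a, labels_b))


def match_clusters(pred: np.ndarray, true: np.ndarray) -> np.ndarray:
    """Permutation mapping predicted cluster ids onto ground-truth ids.

    Maximizes contingency overlap by the Hungarian algorithm; returns an
    array ``perm`` with ``perm[pred_label] = matched_true_label``.  Extra
    predicted clusters map to distinct unused ids.
    """
    pred = np.asarray(pred)
    true = np.asarray(true)
    kp, kt = pred.max() + 1, true.max() + 1
    k = max(kp, kt)
    cont = np.zeros((k, k))
    np.add.at(cont, (pred, true), 1)
    rows, cols = linear_sum_assignment(-cont)
    perm = np.empty(k, dtype=int)
    perm[rows] = cols
    return perm


def kernel_tv(K_hat: np.ndarray, K_true: np.ndarray) -> float:
    """Maximum per-row total-variation distance between two transition kernels."""
    K_hat = np.asarray(K_hat, dtype=float)
    K_true = np.asarray(K_true, dtype=float)
    if K_hat.shape != K_true.shape:
        raise ValueError("kernel shapes differ")
    return float(0.5 * np.max(np.abs(K_hat - K_true).sum(axis=1)))


def benchmark_vs_kmeans(
    measures: Sequence,
    true_labels: Sequence[np.ndarray],
    ranks: Sequence[int],
    cfg,
) -> dict:
    """Pooled-AMI comparison of chain-coupled clustering vs per-timepoint k-means.

    Both competitors label every cell of every timepoint; labels are pooled
    across the series and scored once against the pooled ground-truth type
    identities.  The chain model reports ancestral co-cluster labels, which
    carry one consistent identity space across time; independent k-means has
    no cross-time identity, so its per-timepoint clusters enter the pool
    with unrelated ids.  Returns the two AMIs plus per-timepoint ML-label
    AMIs for the chain model.
    """
    from sklearn.cluster import KMeans

    from .data import build_cost
    from .sequence import fit

    costs = [
        build_cost(measures[t], measures[t + 1], metric="sqeuclidean", lazy=True)
        for t in range(len(measures) - 1)
    ]
    res = fit(costs, [m.weights for m in measures], ranks, cfg)
    chain_labels = ancestral_labels_series(res.Qs, res.dmap)
    km_labels = [
        KMeans(n_clusters=ranks[t], n_init=4, random_state=cfg.seed + t).fit_predict(
            measures[t].points
        )
        for t in range(len(measures))
    ]
    pooled_true = np.concatenate([np.asarray(l) for l in true_labels])
    pooled_chain = np.concatenate(chain_labels)
    pooled_km = np.concatenate(km_labels)
    return {
        "ami_hmot": ami(pooled_chain, pooled_true),
        "ami_kmeans": ami(pooled_km, pooled_true),
        "per_timepoint_ami_hmot": [
            ami(ml_cluster(res.Qs[t]), true_labels[t]) for t in range(len(measures))
        ],
        "fit": res,
    }
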