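"""Domain containers and latent-coupling (LC) algebra for low-rank transport.

A transport plan ``P`` between two weighted point clouds ``(X, a)`` and
``(Y, b)`` with nonnegative rank at most ``min(r1, r2)`` admits a latent
coupling factorization

    P = Q1 diag(1/g1) T diag(1/g2) Q2^T,

where ``Q1`` (n x r1) and ``Q2`` (m x r2) are joint distributions between
points and abstract latent types ("latent representations"), ``g = Q^T 1``
are the latent marginals, and ``T`` is an r1 x r2 coupling of ``g1`` and
``g2`` (the "latent coupling").  Row-normalizing a latent representation
gives a soft clustering, column-normalizing gives an emission matrix
``Lambda = Q diag(1/g)``, and ``T diag(1/g2)``-style normalizations give
cluster-to-cluster transition kernels.

Everything in this module is plain in-memory algebra on these factors.  The
point of the factored form is that an ``n x m`` plan never has to be stored:
costs are contracted against the factors (:func:`transport_cost`), and plans
are only assembled densely for small instances and tests
(:func:`assemble_plan`).  Cost matrices may be dense arrays or lazy
evaluators over embeddings (:class:`SquaredEuclideanCost`,
:class:`CosineCost`) which support the same factor contractions in
``O((n+m)(d+r))`` memory.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = [
    "ATOL_PROB",
    "ATOL_COUPLING",
    "ATOL_PLAN",
    "RTOL_COST",
    "EPS_MASS",
    "MarginalError",
    "DegenerateClusterError",
    "DiscreteMeasure",
    "LatentRepresentation",
    "LatentCoupling",
    "DifferentiationMap",
    "CostOperator",
    "DenseCost",
    "SquaredEuclideanCost",
    "CosineCost",
    "as_cost_operator",
    "latent_marginal",
    "emission_matrix",
    "soft_clustering",
    "assemble_plan",
    "compose_transitions",
    "joint_between",
    "transport_cost",
]

# ---------------------------------------------------------------------------
# Package-wide tolerance table.  Probability vectors are tightest, assembled
# or composed plans loosest (they accumulate a few matrix products of
# rounding error).
# ---------------------------------------------------------------------------

#: probability vectors (a, b, g) must sum to one within this
ATOL_PROB = 1e-9
#: marginal agreement required of Q and T at construction time
ATOL_COUPLING = 1e-8
#: marginal agreement required of assembled / composed plans
ATOL_PLAN = 1e-7
#: relative agreement of plan-free and dense cost evaluation
RTOL_COST = 1e-9
#: floor on latent marginal entries below which diag(1/g) is refused
EPS_MASS = 1e-12


class MarginalError(ValueError):
    """A coupling's marginals do not match the prescribed distributions."""


class DegenerateClusterError(ValueError):
    """A latent type carries (numerically) zero mass and diag(1/g) is undefined."""


def _check_prob_vector(v: np.ndarray, name: str, atol: float = ATOL_PROB) -> None:
    if v.ndim != 1:
        raise ValueError(f"{name} must be a vector, got shape {v.shape}")
    if np.any(v < 0):
        raise ValueError(f"{name} has negative entries")
    s = float(v.sum())
    if abs(s - 1.0) > atol:
        raise ValueError(f"{name} sums to {s!r}, not 1 within {atol}")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DiscreteMeasure:
    """A dataset at one timepoint: an embedded point cloud with probability weights.

    Parameters
    ----------
    points
        ``(n, d)`` array of feature vectors (e.g. PCA coordinates of
        expression profiles).  Unitless.
    weights
        Probability vector ``a`` of length ``n`` (nonnegative, sums to 1).
    timepoint_id
        Ordinal index of the timepoint within its series (0-based).
    point_ids
        Optional ``n`` string identifiers (cell barcodes).
    """

    points: np.ndarray
    weights: np.ndarray
    timepoint_id: int = 0
    point_ids: Optional[tuple] = None

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim == 1:
            pts = pts[:, None]
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "weights", w)
        if pts.shape[0] < 1:
            raise ValueError("a measure needs at least one point")
        if pts.shape[0] != w.shape[0]:
            raise ValueError(
                f"points ({pts.shape[0]}) and weights ({w.shape[0]}) disagree"
            )
        _check_prob_vector(w, "weights")
        if self.point_ids is not None:
            ids = tuple(str(s) for s in self.point_ids)
            if len(ids) != pts.shape[0]:
                raise ValueError("point_ids length mismatch")
            object.__setattr__(self, "point_ids", ids)

    @property
    def n(self) -> int:
        return self.points.shape[0]

    @property
    def dim(self) -> int:
        return self.points.shape[1]


@dataclass(frozen=True)
class LatentRepresentation:
    """Joint distribution ``Q`` between ``n`` points and ``r`` latent types.

    ``Q`` is an ``n x r`` nonnegative matrix whose row sums equal the point
    weights ``a`` of the underlying measure (``Q`` is a coupling in
    ``Pi(a, .)``) and whose column sums are the latent marginals ``g``.
    """

    Q: np.ndarray
    type_names: Optional[tuple] = None

    def __post_init__(self):
        Q = np.asarray(self.Q, dtype=float)
        if Q.ndim != 2:
            raise ValueError("Q must be a matrix")
        if np.any(Q < 0):
            raise ValueError("Q has negative entries")
        n, r = Q.shape
        if not (1 <= r <= n):
            raise ValueError(f"rank must satisfy 1 <= r <= n, got r={r}, n={n}")
        total = float(Q.sum())
        if abs(total - 1.0) > ATOL_COUPLING:
            raise ValueError(f"Q must have total mass 1, got {total!r}")
        object.__setattr__(self, "Q", Q)
        if self.type_names is not None:
            names = tuple(str(s) for s in self.type_names)
            if len(names) != r:
                raise ValueError("type_names length mismatch")
            object.__setattr__(self, "type_names", names)

    @property
    def n(self) -> int:
        return self.Q.shape[0]

    @property
    def rank(self) -> int:
        return self.Q.shape[1]

    @property
    def weights(self) -> np.ndarray:
        """Row sums of Q — the point weights ``a`` it represents."""
        return self.Q.sum(axis=1)

    @property
    def g(self) -> np.ndarray:
        """Latent marginals ``g = Q^T 1``."""
        return self.Q.sum(axis=0)


@dataclass(frozen=True)
class LatentCoupling:
    """Transition mass matrix ``T`` in ``Pi(g_s, g_t)`` between latent marginals."""

    T: np.ndarray
    source_marginal: np.ndarray
    target_marginal: np.ndarray

    def __post_init__(self):
        T = np.asarray(self.T, dtype=float)
        gs = np.asarray(self.source_marginal, dtype=float)
        gt = np.asarray(self.target_marginal, dtype=float)
        object.__setattr__(self, "T", T)
        object.__setattr__(self, "source_marginal", gs)
        object.__setattr__(self, "target_marginal", gt)
        if T.ndim != 2:
            raise ValueError("T must be a matrix")
        if np.any(T < 0):
            raise ValueError("T has negative entries")
        _check_prob_vector(gs, "source_marginal")
        _check_prob_vector(gt, "target_marginal")
        if T.shape != (gs.shape[0], gt.shape[0]):
            raise ValueError("T shape does not match marginal lengths")
        if np.max(np.abs(T.sum(axis=1) - gs)) > ATOL_COUPLING:
            raise MarginalError("row sums of T do not equal source marginal")
        if np.max(np.abs(T.sum(axis=0) - gt)) > ATOL_COUPLING:
            raise MarginalError("column sums of T do not equal target marginal")

    @property
    def shape(self):
        return self.T.shape


@dataclass(frozen=True)
class DifferentiationMap:
    """An ordered chain of ``N - 1`` latent couplings linking ``N`` timepoints.

    ``marginals[t]`` is the latent marginal at timepoint ``t``; coupling ``t``
    links timepoints ``t`` and ``t + 1`` and its target marginal must equal
    the source marginal of coupling ``t + 1``.
    """

    couplings: tuple
    marginals: tuple
    type_names: Optional[tuple] = None

    def __post_init__(self):
        cps = tuple(self.couplings)
        margs = tuple(np.asarray(g, dtype=float) for g in self.marginals)
        object.__setattr__(self, "couplings", cps)
        object.__setattr__(self, "marginals", margs)
        if len(margs) != len(cps) + 1:
            raise ValueError("need exactly one more marginal than couplings")
        for t, c in enumerate(cps):
            if not isinstance(c, LatentCoupling):
                raise TypeError("couplings must be LatentCoupling instances")
            if np.max(np.abs(c.source_marginal - margs[t])) > ATOL_COUPLING:
                raise MarginalError(f"coupling {t} source marginal mismatch")
            if np.max(np.abs(c.target_marginal - margs[t + 1])) > ATOL_COUPLING:
                raise MarginalError(f"coupling {t} target marginal mismatch")
        if self.type_names is not None:
            object.__setattr__(self, "type_names", tuple(self.type_names))

    @property
    def n_timepoints(self) -> int:
        return len(self.marginals)


# ---------------------------------------------------------------------------
# Cost operators: dense matrices and lazy factored evaluators share one
# interface so the solver path never needs an n x m allocation.
# ---------------------------------------------------------------------------


class CostOperator:
    """Abstract pairwise cost ``C`` exposed through factor contractions.

    Subclasses implement ``dot`` (``C @ V``), ``tdot`` (``C.T @ U``) and
    ``mean`` (a scale estimate used to normalize solver step sizes).
    """

    shape: tuple

    def dot(self, V: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def tdot(self, U: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def mean(self) -> float:  # pragma: no cover - interface
        raise NotImplementedError

    def transpose(self) -> "CostOperator":  # pragma: no cover - interface
        raise NotImplementedError

    def dense(self) -> np.ndarray:
        """Materialize the full matrix (tests / small instances only)."""
        n, m = self.shape
        return self.dot(np.eye(m))


class DenseCost(CostOperator):
    """Wrapper giving a dense ``n x m`` array the :class:`CostOperator` interface."""

    def __init__(self, C: np.ndarray):
        C = np.asarray(C, dtype=float)
        if C.ndim != 2:
            raise ValueError("cost matrix must be 2-D")
        if not np.all(np.isfinite(C)):
            raise ValueError("cost matrix must be finite")
        self.C = C
        self.shape = C.shape

    def dot(self, V):
        return self.C @ V

    def tdot(self, U):
        return self.C.T @ U

    def mean(self):
        return float(self.C.mean())

    def transpose(self):
        return DenseCost(self.C.T)

    def dense(self):
        return self.C


class SquaredEuclideanCost(CostOperator):
    """Lazy squared-Euclidean cost ``C_ij = ||x_i - y_j||^2`` over embeddings.

    Contractions use ``C @ V = |x|^2 (1^T V) + 1 (|y|^2)^T V - 2 X (Y^T V)``
    so peak auxiliary storage is ``O((n + m)(d + r))``.
    """

    def __init__(self, X: np.ndarray, Y: np.ndarray):
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if Y.ndim == 1:
            Y = Y[:, None]
        if X.shape[1] != Y.shape[1]:
            raise ValueError("embedding dimensions differ")
        self.X, self.Y = X, Y
        self.sqx = np.einsum("ij,ij->i", X, X)
        self.sqy = np.einsum("ij,ij->j", Y.T, Y.T)
        self.shape = (X.shape[0], Y.shape[0])

    def dot(self, V):
        V = np.asarray(V, dtype=float)
        colsum = V.sum(axis=0)
        return (
            np.outer(self.sqx, colsum)
            + (self.sqy @ V)[None, :]
            - 2.0 * (self.X @ (self.Y.T @ V))
        )

    def tdot(self, U):
        U = np.asarray(U, dtype=float)
        colsum = U.sum(axis=0)
        return (
            np.outer(self.sqy, colsum)
            + (self.sqx @ U)[None, :]
            - 2.0 * (self.Y @ (self.X.T @ U))
        )

    def mean(self):
        mx, my = self.X.mean(axis=0), self.Y.mean(axis=0)
        return float(self.sqx.mean() + self.sqy.mean() - 2.0 * mx @ my)

    def transpose(self):
        return SquaredEuclideanCost(self.Y, self.X)


class CosineCost(CostOperator):
    """Lazy cosine-distance cost ``C_ij = 1 - <x_i, y_j> / (|x_i| |y_j|)``."""

    def __init__(self, X: np.ndarray, Y: np.ndarray):
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if Y.ndim == 1:
            Y = Y[:, None]
        if X.shape[1] != Y.shape[1]:
            raise ValueError("embedding dimensions differ")
        nx = np.linalg.norm(X, axis=1)
        ny = np.linalg.norm(Y, axis=1)
        if np.any(nx == 0) or np.any(ny == 0):
            raise ValueError("cosine cost undefined for zero vectors")
        self.X, self.Y = X, Y
        self.Xn = X / nx[:, None]
        self.Yn = Y / ny[:, None]
        self.shape = (X.shape[0], Y.shape[0])

    def dot(self, V):
        V = np.asarray(V, dtype=float)
        return V.sum(axis=0)[None, :] - self.Xn @ (self.Yn.T @ V)

    def tdot(self, U):
        U = np.asarray(U, dtype=float)
        return U.sum(axis=0)[None, :] - self.Yn @ (self.Xn.T @ U)

    def mean(self):
        return float(1.0 - self.Xn.mean(axis=0) @ self.Yn.mean(axis=0))

    def transpose(self):
        return CosineCost(self.Y, self.X)


def as_cost_operator(C) -> CostOperator:
    """Coerce a dense array or cost operator to the :class:`CostOperator` interface."""
    if isinstance(C, CostOperator):
        return C
    return DenseCost(np.asarray(C))


# ---------------------------------------------------------------------------
# LC algebra
# ---------------------------------------------------------------------------


def latent_marginal(Q: LatentRepresentation) -> np.ndarray:
    """Latent marginal ``g = Q^T 1`` — the probability mass per latent type."""
    return Q.g


def _safe_inv(g: np.ndarray, eps: float = EPS_MASS) -> np.ndarray:
    if np.any(g < eps):
        raise DegenerateClusterError(
            f"latent marginal has entries below {eps}; drop or merge empty types"
        )
    return 1.0 / g


def emission_matrix(Q: LatentRepresentation, eps: float = EPS_MASS) -> np.ndarray:
    """Column-stochastic emission matrix ``Lambda = Q diag(1/g)``.

    ``Lambda[:, k]`` is the distribution of points conditional on latent
    type ``k``.  Raises :class:`DegenerateClusterError` if some type carries
    less mass than ``eps``.
    """
    g = Q.g
    return Q.Q * _safe_inv(g, eps)[None, :]


def soft_clustering(Q: LatentRepresentation) -> np.ndarray:
    """Row-stochastic soft clustering ``diag(1/a) Q``.

    Row ``i`` is the distribution of latent types conditional on point ``i``.
    """
    a = Q.weights
    if np.any(a <= 0):
        raise ValueError("soft clustering undefined for zero-weight points")
    return Q.Q / a[:, None]


def drop_empty_types(
    Q: LatentRepresentation, eps: float = EPS_MASS
) -> LatentRepresentation:
    """Remove latent types with marginal mass below ``eps``.

    The configurable alternative to raising :class:`DegenerateClusterError`:
    empty columns are deleted (with their type names) and the remaining mass
    is untouched, so the result still couples the same point weights.
    """
    g = Q.g
    keep = g >= eps
    if keep.all():
        return Q
    if not keep.any():
        raise DegenerateClusterError("all latent types are empty")
    names = None
    if Q.type_names is not None:
        names = tuple(n for n, k in zip(Q.type_names, keep) if k)
    return LatentRepresentation(Q.Q[:, keep], type_names=names)


def assemble_plan(
    Q1: LatentRepresentation, Q2: LatentRepresentation, T: LatentCoupling
) -> np.ndarray:
    """Dense transport plan ``P = Q1 diag(1/g1) T diag(1/g2) Q2^T``.

    Materializes the full ``n x m`` matrix — intended for small instances and
    tests only; the solver path always works with the factors
    (see :func:`transport_cost`).
    """
    g1, g2 = Q1.g, Q2.g
    if np.max(np.abs(T.source_marginal - g1)) > ATOL_COUPLING:
        raise MarginalError("T source marginal does not match g1 of Q1")
    if np.max(np.abs(T.target_marginal - g2)) > ATOL_COUPLING:
        raise MarginalError("T target marginal does not match g2 of Q2")
    L1 = Q1.Q * _safe_inv(g1)[None, :]
    L2 = Q2.Q * _safe_inv(g2)[None, :]
    return L1 @ T.T @ L2.T


def compose_transitions(dmap: DifferentiationMap, s: int, t: int) -> np.ndarray:
    """Composite latent coupling ``T^(s,t)`` between non-consecutive timepoints.

    Alternating product ``T^(s,s+1) diag(1/g_{s+1}) T^(s+1,s+2) ... T^(t-1,t)``
    — up to the left factor, a composition of Markov transition kernels on the
    latent types.  Indices are 0-based with ``0 <= s < t <= N - 1``.
    """
    N = dmap.n_timepoints
    if not (0 <= s < t <= N - 1):
        raise IndexError(f"need 0 <= s < t <= {N - 1}, got s={s}, t={t}")
    out = dmap.couplings[s].T
    for u in range(s + 1, t):
        g = dmap.marginals[u]
        out = (out * _safe_inv(g)[None, :]) @ dmap.couplings[u].T
    return out


def joint_between(
    Qs: LatentRepresentation,
    Qt: LatentRepresentation,
    dmap: DifferentiationMap,
    s: int,
    t: int,
) -> np.ndarray:
    """Dense joint distribution ``P^(s,t) = Lambda_s T^(s,t) Lambda_t^T``.

    The implied coupling of timepoints ``s`` and ``t`` under the latent
    Markov chain.  Small-instance / test use only.
    """
    if np.max(np.abs(Qs.g - dmap.marginals[s])) > ATOL_COUPLING:
        raise MarginalError("Qs latent marginal does not match map marginal at s")
    if np.max(np.abs(Qt.g - dmap.marginals[t])) > ATOL_COUPLING:
        raise MarginalError("Qt latent marginal does not match map marginal at t")
    Tst = compose_transitions(dmap, s, t)
    Ls = Qs.Q * _safe_inv(Qs.g)[None, :]
    Lt = Qt.Q * _safe_inv(Qt.g)[None, :]
    return Ls @ Tst @ Lt.T


def transport_cost(C, Q1: LatentRepresentation, Q2: LatentRepresentation, T) -> float:
    """Plan-free transport cost ``<C, P(Q1, Q2, T)>_F``.

    Contracts the cost against the LC factors:
    ``<C, Lambda1 T Lambda2^T> = <T, Lambda1^T (C Lambda2)>`` so the full
    ``n x m`` plan is never materialized; peak auxiliary storage is
    ``O((n + m) max(r1, r2))``.  ``C`` may be dense or a lazy
    :class:`CostOperator`; ``T`` may be a :class:`LatentCoupling` or a bare
    matrix.
    """
    op = as_cost_operator(C)
    Tm = T.T if isinstance(T, LatentCoupling) else np.asarray(T, dtype=float)
    if op.shape != (Q1.n, Q2.n):
        raise ValueError(
            f"cost shape {op.shape} does not match point counts ({Q1.n}, {Q2.n})"
        )
    if Tm.shape != (Q1.rank, Q2.rank):
        raise ValueError("T shape does not match the ranks of Q1, Q2")
    L2 = Q2.Q * _safe_inv(Q2.g)[None, :]
    CL2 = op.dot(L2)  # (n, r2)
    L1 = Q1.Q * _safe_inv(Q1.g)[None, :]
    M = L1.T @ CL2  # (r1, r2)
    return float(np.sum(Tm * M))
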