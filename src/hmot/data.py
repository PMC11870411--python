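"""Synthetic generators, cost construction, and file I/O.

The generators emulate the hidden-Markov view of a developmental time
series: a latent cell-type trajectory is a Markov chain ``z_1 -> ... -> z_N``
under per-step transition kernels, and at each timepoint cells are emitted
independently from an isotropic Gaussian around their type's mean.  The
drift variant moves the type means coherently under a shared external
displacement field (types also keep fixed spatial offsets), so that
consecutive snapshots overlap in absolute position and per-timepoint
clustering carries no cross-time identity.  Both return complete ground
truth (labels, kernels, latent trajectories) so recovery can be scored with
no external data.

Readers accept H5AD (one file with a timepoint field, or one file per
timepoint), dense CSV/TSV (cells x genes), and MatrixMarket triplets
(matrix.mtx + barcodes + features); expression is harmonized to the common
gene set, library-size normalized, log1p-transformed and embedded by a PCA
fit on the concatenated series so all timepoints share one space.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .core import (
    CosineCost,
    DiscreteMeasure,
    DifferentiationMap,
    LatentCoupling,
    LatentRepresentation,
    SquaredEuclideanCost,
)

__all__ = [
    "HmmSimSpec",
    "DriftSimSpec",
    "SimResult",
    "simulate_hmm_series",
    "simulate_gradient_drift",
    "build_cost",
    "read_timeseries",
    "write_results",
    "load_results",
]

logger = logging.getLogger("hmot")


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------


def _default_kernels():
    K = np.array([[0.8, 0.2, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
    return [K.copy() for _ in range(3)]


def _default_means():
    M = np.array([[0.0, 0.0], [10.0, 0.0], [20.0, 0.0]])
    return [M.copy() for _ in range(4)]


@dataclass
class HmmSimSpec:
    """Study conditions for the hidden-Markov generator.

    Defaults describe a 4-timepoint series of 300 cells with three cell
    types whose means are collinear and separated by ten emission standard
    deviations, a partially differentiating type-1 population (kernel row
    ``[0.8, 0.2, 0]``), and an initial type distribution ``[0.5, 0.3, 0.2]``.
    The kernels move mass only between geometrically adjacent types, i.e.
    they are the least-action couplings of their own marginals — the regime
    in which transition structure is identifiable from independent
    snapshots.
    """

    N: int = 4
    ranks: Sequence[int] = (3, 3, 3, 3)
    transition_kernels: Sequence[np.ndarray] = field(default_factory=_default_kernels)
    emission_means: Sequence[np.ndarray] = field(default_factory=_default_means)
    emission_scale: float = 1.0
    cells_per_timepoint: int = 300
    initial_distribution: Optional[np.ndarray] = None
    seed: int = 0

    def __post_init__(self):
        self.ranks = tuple(int(r) for r in self.ranks)
        if len(self.ranks) != self.N:
            raise ValueError("need one rank per timepoint")
        self.transition_kernels = [
            np.asarray(K, dtype=float) for K in self.transition_kernels
        ]
        if len(self.transition_kernels) != self.N - 1:
            raise ValueError(f"need {self.N - 1} transition kernels")
        for t, K in enumerate(self.transition_kernels):
            if K.shape != (self.ranks[t], self.ranks[t + 1]):
                raise ValueError(f"kernel {t} shape {K.shape} does not chain")
            if np.any(K < 0) or np.max(np.abs(K.sum(axis=1) - 1.0)) > 1e-9:
                raise ValueError(f"kernel {t} rows must be stochastic")
        self.emission_means = [np.asarray(M, dtype=float) for M in self.emission_means]
        if len(self.emission_means) != self.N:
            raise ValueError("need one mean matrix per timepoint")
        for t, M in enumerate(self.emission_means):
            if M.shape[0] != self.ranks[t]:
                raise ValueError(f"means at timepoint {t} do not match rank")
        if self.initial_distribution is None:
            self.initial_distribution = np.array([0.5, 0.3, 0.2])[: self.ranks[0]]
            self.initial_distribution = (
                self.initial_distribution / self.initial_distribution.sum()
            )
        else:
            self.initial_distribution = np.asarray(self.initial_distribution, dtype=float)
        if self.initial_distribution.shape != (self.ranks[0],):
            raise ValueError("initial distribution length must equal ranks[0]")


@dataclass
class SimResult:
    """Generator output: data plus complete ground truth."""

    measures: list
    labels: list
    kernels: list
    trajectories: np.ndarray  # (n_cells, N) latent type per cell and timepoint
    type_means: list


def simulate_hmm_series(spec: HmmSimSpec) -> SimResult:
    """Sample a time series from the latent-Markov generative model.

    Latent trajectories are sampled as a Markov chain (initial law, then the
    per-step kernels); each cell's features at timepoint ``t`` are drawn
    independently from an isotropic Gaussian at its type's mean.  Weights
    are uniform.  Fully deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n, N = spec.cells_per_timepoint, spec.N
    traj = np.empty((n, N), dtype=int)
    traj[:, 0] = rng.choice(spec.ranks[0], size=n, p=spec.initial_distribution)
    for t in range(N - 1):
        K = spec.transition_kernels[t]
        u = rng.random(n)
        cum = np.cumsum(K, axis=1)
        traj[:, t + 1] = (u[:, None] > cum[traj[:, t]]).sum(axis=1)
    measures, labels = [], []
    for t in range(N):
        z = traj[:, t]
        mu = spec.emission_means[t][z]
        pts = mu + spec.emission_scale * rng.standard_normal(mu.shape)
        measures.append(
            DiscreteMeasure(
                pts,
                np.full(n, 1.0 / n),
                timepoint_id=t,
                point_ids=tuple(f"t{t}_c{i}" for i in range(n)),
            )
        )
        labels.append(z.copy())
    return SimResult(measures, labels, list(spec.transition_kernels), traj, list(spec.emission_means))


@dataclass
class DriftSimSpec:
    """Study conditions for the drifting-cluster (external field) variant.

    Types persist (identity kernels) while every type mean is displaced by a
    shared per-step drift; types additionally keep fixed offsets along the
    drift axis.  With the default spacing equal to the per-step drift, the
    position occupied by type ``k`` at time ``t + 1`` is the position type
    ``k + 1`` held at time ``t``, so snapshots overlap in absolute position
    and nothing at a single timepoint identifies which cluster is which
    across time.
    """

    N: int = 4
    n_cells: int = 200
    n_types: int = 3
    type_spacing: float = 4.0
    drift: Sequence[float] = (4.0, 0.0)
    emission_scale: float = 1.0
    dim: int = 2
    seed: int = 0


def simulate_gradient_drift(spec: DriftSimSpec) -> SimResult:
    """Sample the drifting-cluster series (see :class:`DriftSimSpec`).

    With zero drift this reduces exactly to :func:`simulate_hmm_series`
    with identity kernels and time-constant means.
    """
    drift = np.zeros(spec.dim)
    drift[: len(spec.drift)] = np.asarray(spec.drift, dtype=float)[: spec.dim]
    base = np.zeros((spec.n_types, spec.dim))
    base[:, 0] = spec.type_spacing * np.arange(spec.n_types)
    means = [base + t * drift[None, :] for t in range(spec.N)]
    hspec = HmmSimSpec(
        N=spec.N,
        ranks=(spec.n_types,) * spec.N,
        transition_kernels=[np.eye(spec.n_types) for _ in range(spec.N - 1)],
        emission_means=means,
        emission_scale=spec.emission_scale,
        cells_per_timepoint=spec.n_cells,
        initial_distribution=np.full(spec.n_types, 1.0 / spec.n_types),
        seed=spec.seed,
    )
    return simulate_hmm_series(hspec)


# ---------------------------------------------------------------------------
# Cost construction
# ---------------------------------------------------------------------------


def build_cost(
    X_s: DiscreteMeasure,
    X_t: DiscreteMeasure,
    metric: str = "sqeuclidean",
    lazy: bool = False,
):
    """Pairwise cost between two timepoints' embeddings.

    ``lazy=True`` returns a factored evaluator that contracts against
    rank-scale matrices without ever materializing the ``n x m`` cost
    (supported for ``sqeuclidean`` and ``cosine``); otherwise a dense matrix.
    """
    if X_s.dim != X_t.dim:
        raise ValueError("feature dimensions differ between timepoints")
    if metric == "sqeuclidean":
        if lazy:
            return SquaredEuclideanCost(X_s.points, X_t.points)
        return cdist(X_s.points, X_t.points, metric="sqeuclidean")
    if metric == "cosine":
        if lazy:
            return CosineCost(X_s.points, X_t.points)
        return cdist(X_s.points, X_t.points, metric="cosine")
    if metric == "euclidean":
        if lazy:
            raise ValueError("euclidean cost has no factored form; use lazy=False")
        return cdist(X_s.points, X_t.points, metric="euclidean")
    raise ValueError(f"unknown metric {metric!r}")


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def _read_one(path: Path, labels_field: Optional[str]):
    """Read one timepoint file -> (DataFrame cells x genes, labels or None)."""
    path = Path(path)
    if path.is_dir():  # MatrixMarket triplet directory
        from scipy.io import mmread

        mat = mmread(str(path / "matrix.mtx"))
        barcodes = pd.read_csv(path / "barcodes.tsv", header=None, sep="\t")[0].astype(str)
        features = pd.read_csv(path / "features.tsv", header=None, sep="\t")[0].astype(str)
        M = np.asarray(mat.todense() if hasattr(mat, "todense") else mat, dtype=float)
        if M.shape == (len(features), len(barcodes)):
            M = M.T  # features x barcodes orientation
        elif M.shape != (len(barcodes), len(features)):
            raise ValueError(f"{path}: matrix shape matches neither orientation")
        return pd.DataFrame(M, index=barcodes, columns=features), None
    suffix = path.suffix.lower()
    if suffix == ".h5ad":
        import anndata

        ad = anndata.read_h5ad(str(path))
        X = ad.X
        if hasattr(X, "todense"):
            X = np.asarray(X.todense())
        df = pd.DataFrame(
            np.asarray(X, dtype=float),
            index=ad.obs_names.astype(str),
            columns=ad.var_names.astype(str),
        )
        labels = None
        if labels_field is not None:
            if labels_field not in ad.obs:
                raise KeyError(f"{path}: obs field {labels_field!r} missing")
            labels = ad.obs[labels_field].astype(str).to_numpy()
        return df, labels
    if suffix in (".csv", ".tsv", ".txt"):
        sep = "," if suffix == ".csv" else "\t"
        df = pd.read_csv(path, sep=sep, index_col=0)
        labels = None
        if labels_field is not None:
            if labels_field not in df.columns:
                raise KeyError(f"{path}: column {labels_field!r} missing")
            labels = df[labels_field].astype(str).to_numpy()
            df = df.drop(columns=[labels_field])
        return df.astype(float), labels
    raise ValueError(f"cannot detect format of {path}")


def _split_h5ad_by_time(path: Path, time_field: str, labels_field: Optional[str]):
    import anndata

    ad = anndata.read_h5ad(str(path))
    if time_field not in ad.obs:
        raise KeyError(f"{path}: timepoint field {time_field!r} missing")
    tvals = ad.obs[time_field]
    try:
        order = sorted(tvals.unique(), key=float)
    except (TypeError, ValueError):
        order = sorted(tvals.unique())
    frames, labels = [], []
    X = ad.X
    if hasattr(X, "todense"):
        X = np.asarray(X.todense())
    X = np.asarray(X, dtype=float)
    for tv in order:
        mask = (tvals == tv).to_numpy()
        frames.append(
            pd.DataFrame(
                X[mask],
                index=ad.obs_names[mask].astype(str),
                columns=ad.var_names.astype(str),
            )
        )
        if labels_field is not None:
            labels.append(ad.obs.loc[mask, labels_field].astype(str).to_numpy())
    return frames, (labels if labels_field is not None else None)


def _embed(frames: Sequence[pd.DataFrame], pca_dims: int, normalize: bool):
    """Harmonize genes by intersection, normalize, and fit one shared PCA."""
    common = frames[0].columns
    for df in frames[1:]:
        common = common.intersection(df.columns)
    if len(common) == 0:
        raise ValueError("timepoints share no genes")
    dropped = sum(df.shape[1] - len(common) for df in frames)
    if dropped:
        logger.info("gene intersection: %d columns kept, %d dropped", len(common), dropped)
    mats = [df[common].to_numpy(dtype=float) for df in frames]
    if normalize:
        out = []
        for M in mats:
            lib = M.sum(axis=1, keepdims=True)
            lib[lib == 0] = 1.0
            out.append(np.log1p(1e4 * M / lib))
        mats = out
    if pca_dims and pca_dims > 0:
        from sklearn.decomposition import PCA

        stacked = np.vstack(mats)
        d = min(pca_dims, stacked.shape[1], stacked.shape[0] - 1)
        pca = PCA(n_components=d, svd_solver="full", random_state=0)
        pca.fit(stacked)
        mats = [pca.transform(M) for M in mats]
    return mats


def read_timeseries(
    paths,
    *,
    time_field: Optional[str] = None,
    labels_field: Optional[str] = None,
    pca_dims: int = 50,
    normalize: bool = True,
):
    """Load a developmental time series into :class:`DiscreteMeasure` objects.

    ``paths`` is either one H5AD path (with ``time_field`` naming the obs
    column that partitions cells into ordered timepoints) or a list of
    per-timepoint paths (H5AD, CSV/TSV, or a MatrixMarket directory).  All
    timepoints are restricted to their common genes, library-size
    normalized, log1p-transformed and projected into one shared PCA space
    of ``pca_dims`` dimensions (set ``pca_dims=0`` together with
    ``normalize=False`` to use the stored matrix as coordinates).  Weights
    are uniform per timepoint.

    Returns ``(measures, labels)`` where ``labels`` is ``None`` unless
    ``labels_field`` was given.
    """
    if isinstance(paths, (str, Path)):
        if time_field is None:
            paths = [paths]
        else:
            frames, labels = _split_h5ad_by_time(Path(paths), time_field, labels_field)
            return _frames_to_measures(frames, labels, pca_dims, normalize)
    frames, labels = [], []
    any_labels = False
    for p in paths:
        df, lab = _read_one(Path(p), labels_field)
        frames.append(df)
        labels.append(lab)
        any_labels = any_labels or lab is not None
    return _frames_to_measures(frames, labels if any_labels else None, pca_dims, normalize)


def _frames_to_measures(frames, labels, pca_dims, normalize):
    mats = _embed(frames, pca_dims, normalize)
    measures = [
        DiscreteMeasure(
            M,
            np.full(M.shape[0], 1.0 / M.shape[0]),
            timepoint_id=t,
            point_ids=tuple(frames[t].index),
        )
        for t, M in enumerate(mats)
    ]
    return measures, labels


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------


def write_results(
    Qs: Sequence[LatentRepresentation],
    dmap: DifferentiationMap,
    metrics: Optional[dict],
    out_dir,
    measures: Optional[Sequence[DiscreteMeasure]] = None,
    config: Optional[dict] = None,
) -> dict:
    """Persist a run: factor matrices, labeled transition/NPMI tables,
    co-cluster labels, a Sankey-ready edge list, and a JSON manifest.

    The exact arrays (``Q_t``, ``T``, marginals) go into one compressed
    ``.npz`` container so :func:`load_results` round-trips them bitwise;
    the CSVs are human-readable views.  Returns the paths written.
    """
    from . import __version__
    from .analysis import ancestral_labels_series, ml_cluster, npmi

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    N = len(Qs)
    names = [
        list(Qs[t].type_names)
        if Qs[t].type_names is not None
        else [f"t{t}_c{k}" for k in range(Qs[t].rank)]
        for t in range(N)
    ]

    arrays = {f"Q_{t}": Qs[t].Q for t in range(N)}
    arrays.update({f"g_{t}": dmap.marginals[t] for t in range(N)})
    arrays.update({f"T_{t}": dmap.couplings[t].T for t in range(N - 1)})
    npz_path = out / "factors.npz"
    np.savez_compressed(npz_path, **arrays)

    edge_rows = []
    for t in range(N - 1):
        T = dmap.couplings[t]
        pd.DataFrame(T.T, index=names[t], columns=names[t + 1]).to_csv(
            out / f"transitions_{t}_{t + 1}.csv"
        )
        npmi_t = npmi(T)
        pd.DataFrame(npmi_t, index=names[t], columns=names[t + 1]).to_csv(
            out / f"npmi_{t}_{t + 1}.csv"
        )
        for i, src in enumerate(names[t]):
            for j, dst in enumerate(names[t + 1]):
                if T.T[i, j] > 0:
                    edge_rows.append(
                        {
                            "timepoint": t,
                            "source_type": src,
                            "target_type": dst,
                            "mass": T.T[i, j],
                            "npmi": npmi_t[i, j],
                        }
                    )
    pd.DataFrame(
        edge_rows, columns=["timepoint", "source_type", "target_type", "mass", "npmi"]
    ).to_csv(out / "edges.csv", index=False)

    label_rows = []
    ml = [ml_cluster(Q) for Q in Qs]
    anc = ancestral_labels_series(Qs, dmap) if N >= 2 else [ml[0]]
    for t in range(N):
        ids = (
            measures[t].point_ids
            if measures is not None and measures[t].point_ids is not None
            else [f"t{t}_c{i}" for i in range(Qs[t].n)]
        )
        for i, pid in enumerate(ids):
            label_rows.append(
                {
                    "point_id": pid,
                    "timepoint": t,
                    "ml_label": int(ml[t][i]),
                    "ancestral_label": int(anc[t][i]),
                }
            )
    pd.DataFrame(
        label_rows, columns=["point_id", "timepoint", "ml_label", "ancestral_label"]
    ).to_csv(out / "labels.csv", index=False)

    import scipy
    import sklearn

    manifest = {
        "config": config or {},
        "metrics": metrics or {},
        "n_timepoints": N,
        "ranks": [Q.rank for Q in Qs],
        "index_base": 0,
        "versions": {
            "hmot": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "sklearn": sklearn.__version__,
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=float)
    return {"npz": npz_path, "out_dir": out}


def load_results(out_dir):
    """Reload the exact factor arrays written by :func:`write_results`."""
    out = Path(out_dir)
    with np.load(out / "factors.npz") as z:
        arrays = {k: z[k] for k in z.files}
    N = sum(1 for k in arrays if k.startswith("Q_"))
    Qs = [LatentRepresentation(arrays[f"Q_{t}"]) for t in range(N)]
    couplings = tuple(
        LatentCoupling(arrays[f"T_{t}"], arrays[f"g_{t}"], arrays[f"g_{t + 1}"])
        for t in range(N - 1)
    )
    dmap = DifferentiationMap(couplings, tuple(arrays[f"g_{t}"] for t in range(N)))
    with open(out / "manifest.json") as fh:
        manifest = json.load(fh)
    return {"Qs": Qs, "dmap": dmap, "manifest": manifest}
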