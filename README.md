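# hmot

Joint clustering and differentiation-map inference for developmental
time series, via low-rank optimal transport with latent-coupling
factorization.

## The problem

Single-cell and spatial transcriptomics experiments sample a developing
tissue at a handful of timepoints. Because sequencing is destructive, no
cell is observed twice: each timepoint is an independent snapshot, and the
two questions a developmental biologist asks — *what cell types are present
at each stage?* and *which types turn into which?* — have to be answered by
linking the snapshots computationally. Pairwise alignment methods couple
individual cells between adjacent timepoints and leave cell types and their
transitions to post-processing; `hmot` instead infers both at once, for a
series of any length, as the solution of one transport problem.

## The model

Each timepoint *t* is a discrete measure: points `X_t` (embedding
coordinates of `n_t` cells) with weights `a_t`. A **latent representation**
`Q_t ∈ Π(a_t, ·) ⊂ R₊^{n_t×r_t}` is a joint distribution between cells and
`r_t` abstract cell types; its row normalization is a soft clustering, its
column normalization `Λ_t = Q_t diag(1/g_t)` an emission matrix, where
`g_t = Q_tᵀ1` are the latent marginals (type abundances). A transport plan
between timepoints factors as

```
P(t,t+1) = Q_t diag(1/g_t) T(t,t+1) diag(1/g_{t+1}) Q_{t+1}ᵀ ,
```

with the **latent coupling** `T(t,t+1) ∈ Π(g_t, g_{t+1})` carrying the
type-to-type mass flow. The sequence `(T(t,t+1))` is the **differentiation
map**. The fit minimizes the total transport cost

```
Σ_t ⟨C(t,t+1), P(t,t+1)⟩_F        over all Q_t, T(t,t+1),
```

which couples the latent trajectories to a Markov chain on types: the
joint law of any two timepoints is `Λ_s T(s,t) Λ_tᵀ` with `T(s,t)` the
alternating product of the stepwise couplings. Inference approximates the
MAP state of each `Q_t` by message passing in the zero-temperature limit —
a greedy forward pass, a greedy backward pass, and a consensus pass that
re-estimates each interior timepoint from its frozen forward and backward
messages — followed by a completion pass that solves the now-decoupled
transitions as exact rank-scale linear OT problems. With cell-type
annotations supplied, the representations are pinned and only the
transitions are solved (supervised mode); any subset of timepoints can be
pinned (partial mode).

Everything is computed from the factors: the `n×m` plan is never stored,
so a pair of 50,000-cell timepoints fits in a few hundred MB.

Map quality is read out with normalized pointwise mutual information,
`NPMI(a,b) = log[T_ab/(g_s)_a(g_t)_b] / (−log T_ab) ∈ [−1, 1]` (+1 perfect
correspondence, 0 independence, −1 never co-occur), and clusterings are
scored against references by adjusted mutual information (AMI).

## Worked example

Simulate a 4-timepoint series from the built-in hidden-Markov generator
(three Gaussian cell types, means 10 standard deviations apart, one type
partially differentiating into another) and fit it unsupervised:

```python
import numpy as np
from hmot import (HmmSimSpec, simulate_hmm_series, build_cost, SolverConfig,
                  fit, ml_cluster, ami, npmi)

sim = simulate_hmm_series(HmmSimSpec(seed=0))
costs = [build_cost(sim.measures[t], sim.measures[t + 1], lazy=True)
         for t in range(3)]
cfg = SolverConfig(seed=0, init_mode="kmeans-warmstart")
res = fit(costs, [m.weights for m in sim.measures], ranks=[3, 3, 3, 3], cfg=cfg)

print(f"total transport cost: {res.total_cost:.4f}")
for t in range(4):
    print(f"AMI at timepoint {t}: {ami(ml_cluster(res.Qs[t]), sim.labels[t]):.3f}")
print(np.round(npmi(res.dmap.couplings[0]), 3))
T = res.dmap.couplings[0].T
print(np.round(T / T.sum(axis=1, keepdims=True), 3))
```

prints

```
total transport cost: 34.2633
AMI at timepoint 0: 1.000
AMI at timepoint 1: 1.000
AMI at timepoint 2: 1.000
AMI at timepoint 3: 1.000
[[ 0.825 -1.    -1.   ]
 [-0.312  0.825 -1.   ]
 [-1.    -1.     1.   ]]
[[1.    0.    0.   ]
 [0.156 0.844 0.   ]
 [0.    0.    1.   ]]
```

The clusterings match the generating types exactly at every timepoint
(AMI 1.0; cluster *ids* are arbitrary). The NPMI table shows strong
self-correspondence on the matched diagonal, −1 for type pairs that never
co-occur, and a negative but finite score for the one genuine
differentiation edge. The row-normalized coupling recovers the generating
kernel: one type sends ≈ 0.16 of its mass to a neighbor (truth: 0.2 before
sampling noise at 300 cells), the others self-transition.

The same pipeline runs from the shell on H5AD / CSV / MTX inputs:

```sh
hmot simulate --kind hmm -N 4 --cells 300 -o sim/
hmot fit -i sim/timepoint_0.csv -i sim/timepoint_1.csv \
         -i sim/timepoint_2.csv -i sim/timepoint_3.csv \
         --no-preprocess -r 3 --seed 0 -o run/
hmot score --results run/
```

`hmot fit-supervised` (with `--labels-field`) and `hmot fit-partial`
(with `--fixed 0,2`) expose the annotated modes.

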