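# Methods

## Model

A developmental time series is `N` discrete measures `(X_t, a_t)`,
`t = 0..N−1`, in a common embedding space. The latent-coupling (LC)
factorization writes a transport plan of nonnegative rank ≤ min(r₁, r₂)
between two timepoints as `P = Q₁ diag(1/g₁) T diag(1/g₂) Q₂ᵀ`, where the
latent representations `Q_t ∈ Π(a_t, ·)` are joint distributions between
cells and abstract types, `g_t = Q_tᵀ1` the type abundances, and
`T ∈ Π(g₁, g₂)` the type-to-type coupling. The chain objective is the sum
of pairwise transport costs `⟨C(t,t+1), P(t,t+1)⟩_F`; its minimizers define
per-timepoint clusterings that are *consistent* across the series plus a
differentiation map `(T(t,t+1))`. Composite couplings between
non-consecutive timepoints are alternating products
`T(s,t) = T(s,s+1) diag(1/g_{s+1}) ⋯ T(t−1,t)`, i.e. (up to the left
factor) compositions of Markov kernels on the types; the implied joint law
of two timepoints is `Λ_s T(s,t) Λ_tᵀ` with emission matrices
`Λ = Q diag(1/g)`.

The statistical reading: cells are emitted independently at each timepoint
conditional on a latent type trajectory that evolves as a Markov chain.
The fitted `Q_t` play the role of (unnormalized) emission posteriors and
the fitted couplings the role of transition kernels weighted by abundance.

## Inference

Exact minimization over the sequence is a continuous, constrained,
non-convex program; discretizing it for a Viterbi-style dynamic program is
infeasible. Instead each `Q_t` is estimated as an approximate MAP state of
the Boltzmann density over configurations in the zero-temperature limit,
by message passing:

1. **Forward (α) pass** — solve the first pair jointly, then solve each
   `Q_{t+1}` conditioning on the frozen `Q_t`.
2. **Backward (β) pass** — the identical procedure on the reversed series
   with transposed costs (implemented literally that way, so the
   reversal-equivalence property is structural).
3. **Consensus (γ) pass** — for each interior `t`, re-estimate `Q_t` and
   its two local transitions from the frozen messages `Λ_{t−1}^α` and
   `Λ_{t+1}^β`, minimizing the local two-term loss. Both local transitions
   are treated as free variables of the subproblem. Endpoints keep their
   single informative direction (`Q_0 = Q_0^α`, `Q_{N−1} = Q_{N−1}^β`).
4. **Completion** — with all representations fixed, the transitions
   decouple; each `T(t,t+1)` is an `r_t×r_{t+1}` linear OT problem with
   cost `Λ_tᵀ C Λ_{t+1}`, solved exactly. This is also precisely the fully
   supervised mode.
5. **Selection** — the γ recursion optimizes local objectives and is not
   guaranteed to improve the *global* chain cost over the greedy passes it
   consumed (we observed it losing by 1–4% on random instances). The three
   candidate sequences (α, β, γ) are therefore each completed and scored
   under the global objective, and the cheapest is returned (γ on ties).
   This makes "smoothing never hurts" a structural property rather than a
   hope.

With `N = 2` the machinery reduces exactly to the single pairwise solve.
Partial supervision pins any subset of timepoints; pinned representations
are frozen inside all passes, and pinning everything routes to the
supervised path bitwise.

## The pairwise solver

For fixed representations the objective is linear in `T`
(`⟨C, P⟩ = ⟨T, Λ₁ᵀCΛ₂⟩`), so the `T`-block is refreshed by an exact
rank-scale LP (HiGHS via `scipy.optimize.linprog`) every outer iteration;
LP outputs are rounded back onto `Π(g₁, g₂)` by a scale-then-rank-one
correction, giving machine-precision marginals. Each free representation
takes a Frank–Wolfe step on its row polytope `Π(a, ·)`: the linearized
objective is minimized at a vertex (a hard reassignment of every cell to
its marginally cheapest type) and a backtracking line search over
`λ ∈ {1, 0.5, …, 0.001}` along the segment accepts only strict descent,
with candidates always scored as *feasible* triples (the coupling is
re-rounded onto the candidate's marginals before evaluation). The
objective trace is hence non-increasing by construction, every iterate is
feasible, and convergence is declared when the relative change per outer
iteration falls below `inner_tol` (default 1e-6) or after
`max_outer_iters` (default 300; non-convergence is flagged, never
silent).

**Initialization.** The landscape is flat around symmetric states —
clusters that are near-identical mixtures receive near-identical
gradients — so cold random starts stall badly. (An entropic
mirror-descent scheme with Sinkhorn projections was prototyped first and
plateaued 40–300% above the LP optimum at full rank for exactly this
reason.) Every solve therefore evaluates a small menu of starts and keeps
the best final objective:

- a k-means assignment of the embeddings (when the cost is a factored
  operator carrying coordinates; `init_mode="kmeans-warmstart"`),
- a deterministic balanced *stride* partition by index — at full rank this
  is `Q = diag(a)`, whose first `T`-refresh is the exact Wasserstein LP,
- `n_restarts` seeded Dirichlet draws.

A per-entry floor of `1e-9 · a_i / r` keeps every latent type marginally
populated (an exactly empty type can never be revived and would silently
shrink the rank); it perturbs objectives at the 1e-9 level. Types that end
below `min_latent_mass = 1e-12` anyway trigger an error or are dropped,
per `on_degenerate`.

All randomness flows from `SolverConfig.seed`; identical inputs and seed
give bitwise-identical traces. The `tau` field documents the temperature
of the Boltzmann density; the algorithm operates at the `τ → 0` limit and
never reads it. The partition function of that density is never computed —
only the ground states matter.

## Memory contract

Dense matrices live at point scale (`n × r`, `n × d`) and rank scale
(`r × r`) only. Costs may be passed as lazy operators over embeddings
(squared Euclidean and cosine have factored contractions
`C·V` / `Cᵀ·U` in `O((n+m)(d+r))` memory); plan-level quantities are
contracted against the factors (`transport_cost`), so no `n×m` array is
ever allocated in the solver path. Dense plans are assembled only by the
explicitly small-instance helpers (`assemble_plan`, `joint_between`).
Measured: two 50,000-cell timepoints at rank 20 fit in ≈ 3 s / 160 MB of
traced allocations on one CPU, where a single dense plan would need 20 GB.

## Tolerances

One package-wide table (`hmot.core`): probability vectors sum to 1 within
1e-9; `Q`/`T` marginal agreement at construction 1e-8; assembled or
composed plans 1e-7; plan-free vs dense cost agreement 1e-9 relative;
`diag(1/g)` floor 1e-12. Argmax ties (ML clustering, ancestral pull-back)
break to the lowest index. Indices are 0-based everywhere, including output
files.

## Synthetic generators — study conditions

**Hidden-Markov series** (`HmmSimSpec`): `n` latent trajectories sampled
as a Markov chain (initial law, per-step kernels); cells emitted
independently per timepoint from isotropic Gaussians at their type's mean.
Defaults: `N = 4`, 3 types, 300 cells per timepoint, unit emission scale,
collinear means at 0/10/20 (adjacent separation 10 standard deviations),
initial law `[0.5, 0.3, 0.2]`, kernel rows `[0.8, 0.2, 0]`, `[0, 1, 0]`,
`[0, 0, 1]` at every step.

The kernels are deliberately *least-action*: mass moves only between
geometrically adjacent types and only as required by the marginal flow.
This is an identifiability condition, not a convenience. Snapshots are
independent, so the data determine type abundances and positions but not
per-cell linkages; a transport-based method recovers the cost-minimal
coupling of the abundances, and a generative kernel that shuffled mass
without a cost incentive (e.g. symmetric exchange between distant types)
would be unrecoverable *by any method* from this data. Recovery tests
(AMI ≥ 0.9 per timepoint, per-row total variation ≤ 0.1 against the true
kernels, 8+/10 seeds) should be read accordingly: they validate the
estimator in the regime where the estimand is identifiable. Residual TV
(~0.05) is multinomial sampling noise at 300 cells.

**Drifting clusters** (`DriftSimSpec`): types persist (identity kernels)
while all type means translate by a shared per-step drift — an external
gradient field — and types keep fixed offsets along the drift axis equal
to the per-step drift (defaults: 3 types, spacing 4, drift (4, 0), unit
noise, 200 cells, `N = 4`). Type `k` at time `t+1` therefore occupies the
position type `k+1` held at time `t`: snapshots overlap in absolute
position and nothing in a single snapshot identifies which cluster is
which across time. The comparison harness scores labels pooled over all
timepoints against the pooled true type identities: independent
per-timepoint k-means clusters each snapshot well but contributes
arbitrary, unlinked ids (its pooled labeling is a refinement of the truth),
while the chain model's ancestral co-clustering carries one identity space
through the couplings. Observed pooled AMIs ≈ 0.88 (chain) vs ≈ 0.30
(k-means). Squared-Euclidean geometry is what resolves the conveyor
ambiguity: translating all mass uniformly is strictly cheaper than any
stay-in-place matching, because the cost is strictly convex in
displacement.

**What the generators do not emulate:** count noise (emissions are
Gaussian, not negative binomial), library-size variation, batch effects,
doublets, growth and death (the balanced case fixes both marginals),
spatial coordinates, and continuous differentiation fronts (types are
well-separated modes). Passing these tests therefore demonstrates correct
inference under the model's own assumptions, not robustness to real-data
pathologies.

## Real-data input path

`read_timeseries` accepts one H5AD with a timepoint field, or one file per
timepoint (H5AD, CSV/TSV cells×genes, MatrixMarket triplet directories).
Gene spaces are harmonized by intersection (union-with-zeros would inject
spurious zero-distance structure); counts are library-size normalized to
1e4, log1p-transformed, and embedded by a single PCA (default 50
components) fit on the concatenated series so all timepoints share one
space. Default cost: squared Euclidean on that embedding, lazily. Weights
default to uniform, matching the balanced-transport setting. These
preprocessing choices are defaults, not claims; all are overridable.

## Design choices made where the design was open

- **Endpoint convention:** the consensus recursion only produces interior
  estimates; endpoints take their single informative direction.
- **γ subproblem scope:** both local transitions are optimized jointly
  with the middle representation (the alternative — inheriting the
  forward transition — conditions the middle estimate on a quantity the
  completion pass recomputes anyway).
- **Messages are frozen α/β estimates**, not chained γ estimates, and the
  three passes run once; the final selection step (above) guards the
  global objective.
- **NPMI normalization:** `PMI/(−log T_ab)`, which gives exactly the
  advertised endpoints (+1 diagonal of a diagonal coupling, 0 at
  independence, −1 for never-co-occurring pairs); zero cells are −1 by
  continuity and PMI reports −inf there. The degenerate single-cell case
  `T_ab = 1` is scored 0.
- **Ancestral co-clustering** pulls each descendant cell's ML cluster back
  through the column argmax of the (possibly composed) coupling; across
  multiple steps the composition is taken first, then the argmax.
- **Supervised type ordering** follows `type_order` when given, else
  lexicographic; annotated types with zero mass at a timepoint are dropped
  from that timepoint's axis with a logged warning (the coupling polytope
  is undefined at zero marginals).
- **Ranks are user inputs.** No automated rank/model selection.

## Known limitations

- The objective is non-convex; the solver guarantees feasibility,
  monotone descent and the full-rank/supervised exactness properties, but
  not global optimality at intermediate ranks. The init menu is the
  practical mitigation.
- Costs are linear (Wasserstein) only: no Gromov–Wasserstein or fused
  terms, so purely spatial structure cannot drive the alignment.
- Marginals are balanced: growth and death are not modeled.
- Exact LP transition solves scale comfortably to a few hundred types;
  they are not intended for thousands.
- The problem sizes used by the test suite and the acceptance script
  (≤ 50,000 cells, ≤ 20 types, 10 seeds per experiment) were chosen to
  make the full pipeline conveniently re-runnable; all are parameters,
  not limits of the implementation.
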