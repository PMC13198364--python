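# Methods

## Problem setting

Two single-cell datasets `X ∈ R^{nx×dx}` and `Y ∈ R^{ny×dy}` (cells as rows)
measure different modalities on different cells with no shared features and
no known cell correspondence.  The package estimates a sample coupling
`P ∈ R₊^{nx×ny}` — and, when the co-optimal-transport term is active, a
feature coupling `Q ∈ R₊^{dx×dy}` — by minimizing an entropic, optionally
unbalanced optimal-transport objective.  The working assumptions are the
standard ones for diagonal integration: the two modalities are driven by a
shared underlying cell-state structure, so either their intra-domain
geometries are near-isometric (the Gromov–Wasserstein view) or their raw
measurements are comparable up to feature-level transport (the
co-optimal-transport view).

## The local problem and its solver

Every block update reduces to one generalized linear OT problem

```
min_P  ⟨C + βD, P⟩ + ε KL(P | μ₁⊗μ₂) + ρ₁ KL(P#1 | μ₁) + ρ₂ KL(P#2 | μ₂)
```

with the generalized KL divergence `KL(p|r) = Σ p log(p/r) − Σ p + Σ r`
(convention `0·log 0 = 0` throughout).  `ρ = ∞` encodes a hard marginal
constraint; `ρ = 0` removes the marginal term, giving the closed form
`P = (μ₁⊗μ₂) ∘ exp(−(C+βD)/ε)`.

Numerics:

* **Log-domain Sinkhorn.**  Dual potentials `f, g` are iterated as
  `f = −τ₁ ε LSE_j(log μ₂ + (g − C)/ε)` (and symmetrically for `g`) with
  the unbalanced damping factor `τ = ρ/(ρ+ε)` (1 for a hard constraint).
  All quantities stay in the log domain, so there is no overflow for ε down
  to 1e−4 on costs scaled to [0, 1].
* **ε-scaling.**  Cold starts anneal ε from 5% of the cost range down to the
  target in factor-5 stages (≤100 iterations each), warm-starting the duals
  at every stage.  Warm-started calls (successive BCD sweeps) skip the
  anneal.  This is purely an accelerator: it changes iteration counts, not
  fixed points.
* **Convergence criterion.**  Hard-constraint sides converge when the
  total-variation marginal violation falls below `tol`; relaxed sides when
  the sup-norm dual change does.  Checks run every 5 iterations.  Defaults:
  `tol = 1e−9`, `max_iter = 1000`.  Non-convergence is flagged and logged,
  never silent.
* **Costs are used as given** — no internal rescaling — so ε is
  interpretable against user-scaled costs.  The geodesic pipeline normalizes
  distance matrices to max 1 by default (toggleable), which makes one ε
  meaningful across domains.

A caveat worth recording: for *finite* ρ the damped update is an exact
alternating minimization of the primal objective, so the objective is
non-increasing along Sinkhorn iterates; for hard constraints the iteration
is dual ascent and the primal need not decrease monotonically (only the
outer BCD trace is monotone there).  The monotonicity property test
therefore targets finite-ρ instances.

## Block-coordinate descent and the unbalanced decomposition

The full objective couples blocks through product-measure KL terms.  Using
the identity

```
KL(a⊗b | u⊗v) = m(b)·KL(a|u) + m(a)·KL(b|v) + (m(a)−m(u))(m(b)−m(v))
```

(`m(·)` = total mass), holding block `T` fixed turns each KL term into (i) a
KL in the moving block scaled by `m(T)` and (ii) a term linear in the moving
block's mass.  Consequently the update of each block is an *exact* local
problem with `ε_eff = ε·m(T)`, `ρ_eff = ρ·m(T)` and a scalar cost offset
`ε(KL(T|ref) + m(T) − 1) + Σᵢ ρᵢ(KL(T#i|μᵢ) + m(T) − 1)` (finite-ρ sides
only).  Because every block update exactly minimizes the restricted
objective, the traced total objective is non-increasing — the property the
fuzz suite asserts.

Sweep structure (`P, P′` initialized at `μs₁⊗μs₂`, `Q` at `μf₁⊗μf₂`):

1. **P** — blended cost `α·C_gw(P′) + (1−α)·C_coot(Q) + β_s D_s`, with
   `ε_eff = α ε_gw m(P′) + (1−α) ε_coot m(Q)` and the analogous convex
   blend of mass-scaled ρ per side (an infinite contribution makes the side
   balanced).
2. **P′** — pure GW block against `P` (α factors out; skipped at α = 0).
3. **Q** — pure COOT block on the feature axis against `P`, plus
   `β_f D_f` (skipped at α = 1).

Local costs use the squared-loss factorization
`C = A² r 1ᵀ + 1 cᵀ (B²)ᵀ − 2 A T Bᵀ` (`r, c` = marginals of the fixed
block), never materializing the 4-index tensor.

Stopping: after `n_outer` sweeps (default 50) or when the objective changes
by less than `inner_tol`.  The solver is deterministic — product-measure
initialization, no randomness anywhere.

Conventions chosen where the formulation leaves freedom (each is a design
decision of this package):

* The returned primary coupling is `P`; the symmetrized `(P+P′)/2` is
  available as `AlignmentResult.P_symmetrized`.
* The blended ε and ρ for the shared P-update use the convex combination
  weighted by α.
* Feature supervision enters the Q-update cost as `β_f D_f` (unscaled); the
  traced global objective accordingly carries `(1−α)·β_f⟨D_f, Q⟩`, keeping
  block updates exact.
* Supervision matrices follow the `D_ij = 0` for known pairs, `1` otherwise
  convention, with any real-valued `D` accepted.
* `align(mode, ...)` fixes α and the ρ sentinels per mode and treats a
  finite ρ supplied together with a balanced mode as an explicit parameter
  error.  `ugw`/`ucoot` with unset ρ fall back to 0.1, the midpoint of the
  usual {0.01, 0.1, 1} search grid.

## Geometry

Intra-domain distances are all-pairs shortest paths on the union-symmetrized
Euclidean kNN graph (an edge exists if either endpoint lists the other among
its k nearest neighbors; union keeps graphs connected longer than mutual
kNN).  Edges are weighted by Euclidean length by default; unweighted hop
counts are an option.  Disconnected graphs are repaired rather than
rejected: components are joined along a minimum-spanning-tree over
components whose weights are the shortest Euclidean inter-component links,
adding exactly one bridging edge per MST edge, with a logged warning —
grid searches over k should not crash.  Duplicate points yield zero-weight
edges and are allowed.  `k` is a tuning parameter; neighborhood sizes around
100 suit datasets of a few thousand cells, and the package clips `k` to
`n−1` for small data.

PCA reduction (centered, full SVD, components ordered by explained
variance, sign fixed so each component's largest-magnitude loading is
positive) and per-cell L2 / per-feature z-score normalization are provided
as generic preprocessing; modality-specific pipelines (count normalization,
topic models) are intentionally out of scope — users supply embeddings.

## Evaluation

* **FOSCTTM** uses Euclidean distances, strict inequality (ties never count
  as "closer"), and averages the two directions; the one-directional variant
  is a flag.  0 is perfect, 0.5 is random.
* **Label-transfer accuracy** trains a kNN classifier on the original
  domain with k = number of distinct training labels, evaluates on the
  projected domain, majority vote with ties broken by the nearest
  neighbor's label; test labels unseen in training count as errors.
* **Barycentric projection** normalizes each row of `P`; rows annihilated by
  an unbalanced solve become NaN with a warning and are excluded from LTA.
* **Feature mass on pairs** is invariant to positive rescaling of `Q`; a
  uniform coupling gives `|pairs|/(dx·dy)` — the random baseline (4% for 20
  pairs in a 25×20 coupling).
* **Cell-type matching** aggregates `P` by label into a type×type matrix,
  predicts each row type's counterpart by argmax, and scores against a truth
  map; types absent from the truth map or carrying no mass are excluded.
  Percentages are conventionally reported at two decimals.
* **Coupling density** (grid-search diagnostic): the fraction of rows whose
  top entry holds more than half the row's mass — near 1 means
  near-deterministic matching, near 0 an over-smoothed coupling.

## Synthetic co-assay generator

`make_multiomic` draws a latent Gaussian-mixture cell-state space (optional
1-D trajectory mode) and observes it through two feature maps:
`X = s_x·Z A^T + noise`, `Y = g(s_y·Z B^T) + noise` with `g` ∈ {identity,
tanh, quadratic}.  `A` and `B` are rows of one tall matrix with orthonormal
columns whose first `min(dx, dy)` rows are shared, so paired features load
on identical latent directions — the ground-truth feature pairs.  When
`dx = dy` both maps are exact scaled isometries of the latent space, making
noiseless geodesic matrices equal up to scale (the regime used for
geometry-preservation tests); for `dx ≠ dy` they are near-isometries.

Cell types are deliberately *not* exchangeable: proportions follow
`1 : 2 : … : n_types`, per-type dispersion factors span 0.7–1.3, and center
draws are rejected until all pairwise gaps exceed 6 within-cluster standard
deviations.  Perfectly symmetric equal clusters are unidentifiable for
purely geometric alignment (any cluster permutation is a near-isometry),
and overlapping centers merge types; real cell-type structure has neither
degeneracy.  Defaults: 100 cells, 3 types, 10 features per modality,
`noise_sd = 0.05`, `center_scale = 4`, `within_sd = 0.6`, `s_x = 1`,
`s_y = 1.5`.

`downsample_by_type` implements the unbalanced protocol: per type, a
fraction `f ~ Uniform(0, max_fraction)` of cells is removed (round-half-even
count, uniform choice), independently per modality with different seeds, so
the surviving type proportions differ across domains.

What the generator does **not** emulate: count sparsity and overdispersion
of real scATAC/scRNA data, sequencing-depth effects, batch effects, doublets
or continuous differentiation mixtures (beyond the simple trajectory mode).
Passing tests therefore demonstrate correctness of the optimization and
evaluation machinery and recoverability under clean geometric assumptions —
not performance on raw sequencing data, which additionally depends on the
user's preprocessing/embedding choices.

## Validation experiment sizes and settings

The acceptance experiments (also run by `scripts/acceptance.py`) use: 5×5
instances against the exact LP oracle (20 draws, ε = 1e−3); 10×10 fixed
instances for the reduction identities and the ρ = 1e6 balanced-limit check;
GW self-alignment on 100 noiseless cells, 3 types, `ε_gw = 1.5e−4`,
`inner_tol = 1e−6`, k = 20; the unbalanced LTA comparison on 250-cell
simulations (5 seeds, `max_fraction = 0.5`, `ε_gw = 3e−4`, UGW ρ = 0.1 from
the standard {0.01, 0.1, 1} grid, k = 30); and a 50-instance monotonicity
fuzz with sizes 5–8 and mixed balanced/unbalanced settings.  The ε values
were selected with the package's own density diagnostic (at ε = 1e−3 the
self-alignment coupling is visibly over-smoothed: density ≈ 0.5 and
row-argmax errors within clusters; exact 1-1 recovery wants the sharper
ε = 1.5e−4, cluster-level label transfer is already stable at 3e−4).

## Known limitations

* No convergence theory is claimed for the unbalanced augmented objective;
  the BCD trace is provably non-increasing, but limit points are not
  characterized.
* Entropic bias: couplings are blurred at the ε scale; transport costs lie
  within O(ε log n) of the exact optimum, which the LP-oracle check
  quantifies.
* The two GW sample couplings `P, P′` are initialized equal and usually stay
  close but are not constrained to coincide.
* Geodesic repair of disconnected kNN graphs inserts single bridging edges;
  inter-component distances are then tree-path approximations.
* Dense algebra throughout: memory is O(nx·ny + dx·dy), appropriate for the
  desk-scale problems (≤ a few thousand cells) the package targets.
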