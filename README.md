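# otalign

Optimal-transport alignment of separately assayed single-cell multi-omic
datasets.

Single-cell experiments usually measure one modality at a time — gene
expression in one run, chromatin accessibility or surface proteins in
another — on *different* cells with *different* feature sets.  Diagonal
integration asks for a pairing of cells (and, when possible, features)
across such datasets without any known correspondence.  `otalign` solves
this with entropic, optionally unbalanced optimal transport: it computes a
nonnegative coupling matrix `P ∈ R₊^{nx×ny}` whose entry `P_ij` is the
probabilistic match strength between cell `i` of modality `X` and cell `j`
of modality `Y`.

## The model

All formulations in the package are partial functions of one objective over
three couplings — two sample couplings `P, P′` and a feature coupling `Q`:

```
  α  · [ ⟨L(D_X, D_Y), P ⊗ P′⟩ + ε_gw KL(P ⊗ P′ | μ⊗μ′⊗ν⊗ν′)
         + ρ_gw1 KL(P#1 ⊗ P′#1 | μ⊗μ′) + ρ_gw2 KL(P#2 ⊗ P′#2 | ν⊗ν′) ]     (GW)
+ (1−α)· [ ⟨L(X, Y), P ⊗ Q⟩ + ε_coot KL(P ⊗ Q | μs⊗μf⊗νs⊗νf)
         + ρ_coot1 KL(P#1 ⊗ Q#1 | μs⊗μf) + ρ_coot2 KL(P#2 ⊗ Q#2 | νs⊗νf) ]  (COOT)
+ supervision terms β ⟨D, ·⟩
```

with squared loss `L(a,b)_ijkl = (a_ij − b_kl)²`, `P#1`/`P#2` the row/column
marginals of `P`, and `D_X`, `D_Y` intra-domain geodesic distance matrices
(shortest paths on a symmetrized Euclidean kNN graph).  Setting `α = 1`
gives Gromov–Wasserstein (geometry matching, no feature map), `α = 0` gives
co-optimal transport (joint sample + feature couplings), intermediate `α`
the augmented combination; `ρ = ∞` are hard marginal constraints (balanced),
finite `ρ` tolerates disproportionate cell-type representation by creating
or destroying mass (unbalanced: UGW, UCOOT, UAGW).

A block-coordinate-descent driver holds two couplings fixed and solves an
exact entropic (un)balanced linear OT problem for the third with log-domain,
damped Sinkhorn iterations; the traced objective is non-increasing by
construction.  Alignments are consumed through the barycentric projection
`Ŷ_i = Σ_j (P_ij / P#1_i) Y_j` and scored by FOSCTTM (fraction of samples
closer than the true match), kNN label-transfer accuracy, feature mass on
known pairs, and cell-type-level matching accuracy.

## Worked example

Generate a synthetic co-assay (one latent cell-type structure observed
through two different feature maps, cell `i` of `X` truly matching cell `i`
of `Y`) and align it with balanced GW:

```python
import numpy as np
from otalign import make_multiomic, MultiOmicAlignment, SolverConfig

sim = make_multiomic(n_cells=100, n_types=3, dx=10, dy=10,
                     noise_sd=0.0, seed=1)
model = MultiOmicAlignment(
    sim.X, sim.Y, mode="gw",
    config=SolverConfig(eps_gw=1.5e-4, inner_tol=1e-6),
    k_neighbors=20,
)
res = model.fit()
print(res.summary())
print(f"pair recovery: {np.mean(res.P.plan.argmax(1) == np.arange(100)):.2%}")
print(f"FOSCTTM:       {res.foscttm():.4f}")
print(f"LTA:           {res.label_transfer_accuracy():.2%}")
```

prints

```
Multi-omic OT alignment results
===============================================
formulation                                  gw
cells (X, Y)                         (100, 100)
alpha                                         1
eps (gw, coot)                   0.00015, 0.001
rho_gw                                 inf, inf
rho_coot                               inf, inf
BCD sweeps                                    8
converged                                  True
final objective                       0.0012974
coupling mass (P)                             1
coupling density (P)                       0.85
===============================================
pair recovery: 100.00%
FOSCTTM:       0.0002
LTA:           100.00%
```

The coupling's row-argmax recovers every true cell pair; FOSCTTM 0.0002
means that, on average, almost no cell is closer to a projected cell than
its true match (0.5 would be random); label-transfer accuracy 100% means a
kNN classifier trained on `Y` labels every projected `X` cell correctly.

The same analysis is available from the shell:

```sh
otalign simulate --n-cells 100 --n-types 3 --noise-sd 0 --seed 1 --out-dir sim/
otalign align --x sim/X.tsv --y sim/Y.tsv \
        --x-labels sim/X_labels.tsv --y-labels sim/Y_labels.tsv \
        --mode gw --out-dir run/
```

which writes the coupling (`coupling_P.tsv`), the projected data, the loss
trace and a JSON metrics report.  `otalign tune` grid-searches `ε`, `ρ` and
`α` and ranks configurations by a chosen metric together with a
coupling-density diagnostic.

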