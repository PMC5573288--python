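# spanmf

SPA-initialized non-negative matrix factorization for brain-tumor tissue
segmentation from multi-parametric MRI features.

## The problem

Multi-parametric MRI assigns each voxel a vector of non-negative features
(structural intensities, perfusion, diffusion and metabolite levels).
Stacking the voxels column-wise gives a matrix `X ∈ R₊^{m×n}` that NMF
decomposes as

```
X ≈ W H,   W ∈ R₊^{m×r},  H ∈ R₊^{r×n},
```

where the columns of `W` are tissue-specific signatures (normal tissue,
edema, active tumor, necrosis) and the rows of `H` their per-voxel
abundances, by minimizing `½‖X − WH‖²_F`.  NMF is non-convex, so the result
depends on the starting point `(W₀, H₀)`.  This package is about that
starting point: it implements the **successive projection algorithm (SPA)**
as an NMF initializer and benchmarks it against the common alternatives.

SPA rests on convex geometry.  If every tissue is represented purely in at
least one voxel and abundances sum to (at most) one, the data columns span
a convex hull whose vertices are the pure voxels.  SPA finds them greedily:
pick the column with the largest ℓ₂ norm, project all columns onto its
orthogonal complement, repeat `r` times — `O(mnr)` work, fully
deterministic.  The selected columns become `W₀`; `H₀` follows by
per-voxel non-negative least squares.

## What's in the box

- `spanmf.spa` — SPA column selection, NNLS abundances, and the Convex-NMF
  weight initialization `A₀ = A⁺ + 0.2·E·⟨A⁺⟩` with `A ≈ H₀ᵀ(H₀H₀ᵀ)⁻¹`.
- `spanmf.initializers` — the baselines: repetitive random, NNDSVD with a
  1%-of-mean zero fix, and fuzzy c-means.
- `spanmf.solvers` — four solvers under one stopping contract (relative
  residual change < 1e-5, ≤ 10000 iterations): accelerated HALS,
  Gauss–Newton/dogleg on squared variables (GD), projected gradient with
  Armijo line search (PG), and Convex NMF (`X ≈ XAH`) by multiplicative
  updates; plus best-of-30 restart orchestration for the non-deterministic
  initializers.
- `spanmf.hnmf` — two-level hierarchical NMF: rank-2 split, per-branch
  factorization, NNLS recombination.
- `spanmf.segmentation` — k-means segmentation of abundances (one-hot
  centroid initialization), Dice scoring over the nested BraTS classes
  (active ⊂ core ⊂ whole tumor), and a one-tailed Wilcoxon signed-rank
  test with exact small-sample p-values.
- `spanmf.phantom` — synthetic phantoms with concentric tumor geometry,
  sum-to-one Dirichlet mixing, controllable pure-pixel violations and SNR.
- `spanmf.io` / `spanmf.pipeline` / `spanmf.cli` — delimited-text I/O, the
  benchmark grid driver, and the `spanmf` command
  (`phantom` / `factorize` / `benchmark` / `validate`).

## Worked example

```python
import spanmf as sp
from spanmf.segmentation import relabel

ph  = sp.make_phantom(sp.PhantomConfig(seed=3, snr_db=30.0))   # 64x64, 4 tissues
fac = sp.solve(ph.X, 4, "ahals", "spa")                        # SPA-initialized aHALS

perm = sp.match_sources(fac.W, ph.W_true)
seg  = sp.segment_abundances(fac.H, grid_shape=ph.config.grid_shape)
seg.labels = relabel(seg.labels, perm)
seg.class_of_source = ph.class_of_source
print(sp.dice_report(seg, ph.label_map_true).as_dict())
```

prints

```
{'active': 0.928, 'core': 0.965, 'whole': 0.974}
```

the Dice overlap between the recovered and true segmentations for active
tumor, tumor core (active + necrosis) and whole tumor (core + edema): at
SNR 30 dB all three classes are recovered with Dice well above 0.85, with
disagreements confined to region boundaries where voxels are genuine
tissue mixtures.  The scripts in `examples/` walk through each capability
(SPA selection, solver comparison, segmentation, the full initializer
benchmark, hNMF) with printed, annotated output.

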