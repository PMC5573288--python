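# Methods

## Model

All components operate on the NMF model `X ≈ WH` with `X` an `m×n`
non-negative feature matrix (rows: MRI-derived features, columns: voxels),
`W` the `m×r` tissue signatures and `H` the `r×n` abundances, fit under the
Frobenius objective `½‖X − WH‖²_F`.  The geometric assumption exploited by
SPA is near-separability: every source appears (approximately) pure in at
least one column, and abundances sum to at most one, so the columns of `X`
live in the convex hull whose vertices are the pure voxels.

## SPA initialization

`spa_select_columns` implements the greedy projection recursion literally:
working matrix `S ← X`; at step `j` select `i* = argmax_i ‖S(:,i)‖²₂`
(ties broken by smallest index, for determinism), record the *original*
column `X(:, i*)`, and update `S ← (I − s sᵀ/‖s‖²) S` with `s = S(:, i*)`.
Selection stops with a rank-deficiency error, naming the failing step, if
the maximal projected squared norm drops below `1e-12·‖X‖²_F` (configurable);
the data then has fewer than `r` usable directions.  `W₀` stores the
unprojected selected columns; `H₀` is computed per voxel by Lawson–Hanson
active-set NNLS (an exact KKT point per column — the quality of `H₀` drives
the initializer comparison, so an iterative approximation is not used here).

For Convex NMF an auxiliary weight matrix is needed:
`A = H₀ᵀ(H₀H₀ᵀ)⁻¹`, made non-negative as `A₀ = A⁺ + 0.2·E·⟨A⁺⟩` where `A⁺`
is the element-wise positive part and `⟨A⁺⟩` the mean absolute value of its
nonzero entries.  The Gram solve assumes `H₀H₀ᵀ` invertible; a caller who
requests the fallback mode gets a tiny ridge (`1e-10·trace/r`) instead of
an error when it is numerically singular.  Note that for non-negative `H₀`
with overlapping row supports the unconstrained `A` necessarily carries
negative entries (the inverse of a positive Gram matrix has mixed signs),
which is exactly why the positive-part-plus-offset construction exists.

## Baseline initializers

*Repetitive random*: `W₀, H₀ ~ Uniform(0,1)` i.i.d. from a seeded
generator; meant to be used under best-of-`n_restarts` orchestration.

*NNDSVD*: truncated SVD of `X`; the leading triplet of a non-negative
matrix is non-negative up to sign and is used directly; every later
component is split into positive/negative parts of its singular vectors
and the candidate rank-1 term with the larger product of factor norms (the
dominant triplet of `C_i⁺`) is kept.  Signs are fixed by orienting each
left singular vector so its largest-magnitude entry is positive, making
repeated runs bit-identical.  Because several solvers leave exact zeros
untouched forever (multiplicative updates; the squared-variable GD
solver), all remaining zeros are replaced by 1% of the mean of the
positive entries of the corresponding factor.

*Fuzzy c-means*: classical alternating updates with Euclidean distance,
fuzzifier 2.0, tolerance 1e-5 on the largest membership change, at most
300 iterations, random initial memberships (all exposed in the function
signature).  A point coincident with a centroid receives an indicator
membership.  Centroids become columns of `W₀`, membership rows become `H₀`.

## Solvers and the common stopping contract

Every solver records `‖X − WH‖_F` per outer iteration, starting with the
initialization (index 0) so head-start comparisons are possible, and stops
when the relative change between successive residuals falls below `tol`
(default 1e-5) or at `max_iter` (default 10000).  A residual below
`1e-13·‖X‖_F` also counts as converged: at an exact factorization the
relative change of machine-noise residuals never settles, and without the
floor a solver started at the answer would spin to `max_iter`.

*aHALS*: exact cyclic rank-one updates
`H(k,:) ← max(ε, H(k,:) + (W(:,k)ᵀX − W(:,k)ᵀWH)/‖W(:,k)‖²)` and the
symmetric update for `W` columns, with `ε = 1e-16` as a division-safety
floor.  The acceleration repeats the cheap inner sweeps
`1 + ⌊α·ρ⌋` times (`α = 0.5`), where `ρ` is the flop ratio between the
one-off Gram/cross products and one sweep, with an early stop once a sweep
changes less than 1e-4 of the first sweep's change.  Collapsed factor
columns are reset to small seeded random values and logged.

*GD*: change of variables `W = U∘U`, `H = V∘V` removes the constraints;
Gauss–Newton steps on the resulting nonlinear least squares, the
linearized step solved by conjugate gradients from Jacobian-vector
products (the Jacobian is never formed; CG relative tolerance
`min(0.1, √‖g‖)`, at most 100 CG iterations), globalized by a dogleg trust
region (initial radius 1.0, acceptance thresholds 0.25/0.75, radius ×0.25
on failure, ×2 on strong success).  The radius is shrunk until a step is
accepted within each outer iteration, so the trace is non-increasing;
radius collapse below 1e-14 terminates with the converged flag set.

*PG*: alternating non-negative least-squares subproblems solved by
projected gradient with the Armijo rule along the projection arc
(sufficient decrease σ = 0.01, backtracking ratio β = 0.1, step-size
memory across iterations).  Subproblem tolerances start at
`1e-3·‖∇f(W₀,H₀)‖` and shrink ×0.1 whenever a subproblem returns
immediately.

*Convex NMF*: `X ≈ XAH` with `K = XᵀX` split as `K± = (|K| ± K)/2`;
monotone multiplicative square-root updates of `H` and `A` with
denominator floor 1e-16; `W = XA` on output.  Forming `K` costs `O(n²)`
memory, which bounds the practical voxel count (the benchmark driver uses
32×32 grids for this solver's iteration measurements for that reason).

`run_with_restarts` runs a solver with seeds `base_seed … base_seed +
n_restarts − 1` (default 30), keeps the run with the lowest final
residual (ties: smallest seed) and records all final residuals.  FCM is
re-clustered with a fresh seed at every restart rather than reusing one
clustering — the closest reading of "repetitively run the randomly
initialized pipeline".

## Hierarchical NMF

Level 1 is a rank-2 aHALS factorization; each voxel follows its dominant
level-1 abundance (ties to branch 1).  Branch ranks are `(r1, r − r1)`
with default `r1 = ⌈r/2⌉`.  Level 2 runs aHALS per branch at those ranks,
the chosen initializer applied to each submatrix.  The pooled sources are
re-fit to all voxels by exact NNLS.  A branch receiving fewer voxels than
its rank is an error naming the branch.  The dominant-abundance assignment
is the simplest quantitative reading of "grouping similar tissues after
the rank-2 split"; semantic source-to-tissue heuristics are out of scope.

## Segmentation and validation

Abundance columns are sum-normalized (so mixed voxels live on the same
simplex as the centroids — raw-scale clustering would let bright voxels
dominate) and clustered by k-means with centroids initialized at the
one-hot vectors `e₁ … e_r`; cluster `k` inherits source identity `k`.
The k-means step is scikit-learn's Lloyd implementation with `n_init=1`
and the fixed centroid array.  All-zero columns are labeled unassigned.

Because NMF output ordering is arbitrary, estimated sources are anchored
before scoring: against ground-truth signatures (phantoms) by the exact
cosine-similarity assignment (Hungarian algorithm), or, for file input
with only a reference label map, by majority overlap.  Dice is
`2|A∩B|/(|A|+|B|)` per BraTS class (active; core = active ∪ necrosis;
whole = core ∪ edema); two empty masks score 1 (agreement on absence),
empty vs non-empty scores 0.

The one-tailed Wilcoxon signed-rank test drops zero differences, midranks
ties, and computes `P(W⁺ ≥ w)` exactly for up to 25 nonzero pairs by
dynamic programming over the (possibly half-integer) rank lattice — this
remains exact under ties, unlike textbook tables — switching to a
tie-corrected normal approximation with continuity correction beyond 25.

## Phantom generator

The generator reproduces the data structure the method assumes, not MR
physics.  Defaults: 64×64 grid, m = 24 features, r = 4 tissues.  Source
signatures are log-uniform over one decade, redrawn until all pairwise
cosines are ≤ 0.97 (tissue signatures are distinct but correlated).
Geometry is concentric — necrotic center ⊂ active rim ⊂ edema halo ⊂
normal background — which makes the three nested BraTS classes
non-trivial.  Interior voxels are pure with probability
`purity_fraction = 0.5`, otherwise Dirichlet mixtures with concentration
`mixing_sharpness = 10` on their own tissue and 0.3 elsewhere; boundary
voxels are two-tissue mixtures favoring their own region (expected share
2/3).  Columns always sum to one.  Noise is additive Gaussian scaled to
the target SNR (power ratio, dB) and truncated at zero to keep `X`
non-negative; at the default SNRs the truncation is negligible and the
realized SNR stays within ±0.5 dB.  Setting a source's pure-pixel flag to
false demotes its one-hot columns to 0.9/0.1 mixtures, emulating the
partial-volume violation of the pure-pixel assumption in low-resolution
modalities.

What the phantom does *not* emulate: feature-to-feature noise
correlations, intensity non-uniformity, irregular tumor shapes, multiple
lesions, and inter-subject variability.  Passing the end-to-end gates
therefore shows the pipeline is correct and robust under the model's own
assumptions, not that clinical Dice levels are guaranteed.

## Numerical choices and limitations

- Ties in SPA's argmax go to the smallest column index; duplicated pure
  voxels are all eligible.
- Dense SVD (LAPACK) is used for NNDSVD; feature counts are small, so a
  truncated iterative SVD would not pay off.
- Per-column NNLS is Lawson–Hanson active set; exact for the small `r`
  used here, `O(n)` independent solves.
- The end-to-end property gates (Dice ≥ 0.90 whole / 0.85 core and active
  at SNR 30 dB in ≥ 45/50 seeds) were fixed from a calibration run of the
  generator at its default conditions; they are regression gates for this
  pipeline, not clinical performance claims.
- With boundary mixing present, hNMF's rank-1 branch fits blend sources
  slightly, so its recombination residual on a two-source phantom is a few
  percent rather than exact; exactness holds (and is tested) when every
  voxel is purely one source.
- The benchmark driver sizes its problems (64×64 grids generally; 32×32
  where Convex NMF's `n×n` Gram matrix is involved) so a full grid runs in
  minutes on one CPU core.
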