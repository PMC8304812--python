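# Methods

## Pipeline

1. **Windowing.** HU values are clipped to an absolute window
   `[ct_min, ct_max]`. The default (−583, 137) HU corresponds to window
   level −223 HU and width 720 HU; `derive_window` recomputes it from any
   cohort as μ_d ± 2σ_d, where μ_d and σ_d are the sample mean and sample
   (n−1) standard deviation of the per-nodule mean density. The estimator
   choice is recorded in the provenance fields (`mu_d`, `sigma_d`) so
   either convention can be reconstructed. Per-nodule mean density is
   measured over the 50% consensus mask, which is the natural
   rater-independent choice.
2. **Quantisation.** Fixed bin count: `level(x) = floor((x − ct_min)/bw) + 1`
   with `bw = width/Ng`. Levels are 1-based (1..Ng), matching the
   conventional grey-level matrix indexing; the top bin is closed so
   `ct_max` maps to Ng rather than overflowing. Monotonicity, surjectivity
   on dense input, idempotence w.r.t. clipping and the floor-halving
   refinement between Ng and 2·Ng are asserted by property tests.
3. **Feature extraction.** 88 features; δ = 1, 26-connectivity, voxel-unit
   distances (no spatial resampling anywhere, so no spacing correction).
4. **Stability.** Average pairwise sMAPE per nodule, averaged over the
   cohort, graded on the four-level scale (≤5 / ≤10 / ≤20 / ≤100 %).

## Feature conventions

All matrix builders are vectorised (shift-and-mask, `bincount`,
`scipy.ndimage.label` for zones) and validated cell-by-cell against naive
nested-loop enumerators on hundreds of random ≤4×4×4 masked volumes.

* **First-order**: Entropy and Uniformity come from the quantised level
  histogram and so depend on Ng (Entropy ∈ [0, log2 Ng], Uniformity ∈
  [1/Ng, 1]); the other 11 are computed from the clipped continuous HU
  values and are bit-identical across Ng — scenario B exercises exactly
  this split. Std/Skewness/Kurtosis use population (biased) moments;
  Kurtosis is non-excess (Gaussian → 3); RMAD averages absolute deviation
  within the P10–P90 range.
* **GLCM / GLRLM** are built per direction over the 13 unique positive
  offsets of the 26-neighbourhood; features are computed on each non-empty
  direction matrix and averaged over directions (not merged), matching the
  aggregation of the widely used extraction tooling this package's numbers
  are meant to be comparable with. GLCM matrices are symmetrised.
* **GLDM**: a neighbour is dependent when its level differs by ≤ α
  (default 0). The matrix column stores the raw dependent-neighbour count
  j ∈ {0..26}; features that weight by dependence size use j + 1, so an
  isolated voxel has small-dependence emphasis exactly 1.
* **Degenerate denominators** (deterministic by fiat): GLCM Correlation
  and MCC on zero marginal variance → 1; IMC1 with zero marginal entropy
  → 0; NGTDM Coarseness on a constant region → sentinel 10⁶; NGTDM
  Busyness/Strength with zero denominator → 0; any feature on an empty
  matrix (e.g. all GLCM/NGTDM features of a single-voxel mask) → NaN, the
  explicit "undefined" flag. Undefined readings are excluded from a
  feature's stability average (with exclusion counts reported), never
  imputed.
* **Naming**: canonical output names are class-prefixed abbreviations
  (`glcm_Contr`, `glrlm_GLN`, …) because several abbreviations recur
  across classes; every CSV also carries a `class` column.

## The sMAPE statistic

The summand is implemented as 100·|x̂ − x| / (|x̂| + |x|): with absolute
values in the denominator the [0, 100] bound holds for negative-valued
features too (cluster shade, skewness, minimum, IMC1). Because the
absolute-value form is symmetric, the mean over ordered pairs equals the
mean over unordered pairs — the tests assert this identity numerically.
A 0/0 pair counts as perfect agreement (0). The ratio is clamped at 1
before scaling so floating-point rounding cannot exceed the bound by one
ulp. Grade boundaries are closed on the upper end (S = 5 is excellent,
S = 10 is good).

## Synthetic phantoms

The generator emulates what the stability analysis needs from real CT
nodules, not their full appearance:

* a spherical nodule with a **radially graded density** (dense core,
  lighter rim — the profile that makes Max the delineation-stable
  first-order feature, since every plausible contour keeps the core);
* **spatially correlated Gaussian noise** (white noise smoothed at the
  `noise_correlation_length`, rescaled to `noise_sigma`) providing
  non-trivial texture at every Ng;
* **cohort-level density variation**: the default sampler draws each
  nodule's mean density from N(−223, 180) HU, radii from 4.5–7.5 voxels
  on 28³ grids and noise σ from 40–80 HU, so the μ_d ± 2σ_d window
  derivation is exercised with realistic spread;
* **rater simulation**: each observer's mask is the base contour displaced
  along its signed-distance normal by a smooth random field (Gaussian,
  std = `boundary_jitter_sigma` voxels, correlation length fixed at 3
  voxels) plus an optional uniform dilation/erosion bias. Smooth radial
  displacement keeps masks connected and contour-like, unlike independent
  voxel flips; draws failing the `min_dice` floor are resampled up to 10
  times. Background voxels sit at −1000 HU, below any plausible window
  floor, so mask-leak bugs clamp to CTmin and show up in feature values.

What the phantoms do **not** model: scanner reconstruction kernels, slice
thickness/anisotropic spacing effects, lesion shape irregularity,
spiculation, or calibrated inter-observer statistics of any real
annotation corpus (no quantitative disagreement model is available to
calibrate against — jitter parameters are free knobs). Passing pipeline
tests therefore demonstrates correctness of the statistics and their
analytic invariances (zero disagreement ⇒ S = 0; Ng-invariance of
continuous first-order features), not clinical-scale stability rankings,
which depend on real lesion morphology.

## Determinism and problem sizes

Every generator output is a pure function of (parameters, seed); one
master seed spawns per-nodule child seeds recorded in the manifest so any
single nodule can be regenerated. The study-scale configuration used by
`scripts/acceptance.py` is 20 nodules × 4 raters at 28³ voxels — small
enough that a full two-scenario run (160 feature extractions, Ng up to
256) completes in well under a minute on one core, while still giving
every feature family non-degenerate matrices. CSV floats are written with
6 significant digits; in-memory values keep full precision.

## Known limitations

* Scenario rankings on phantoms are family-plausible but not transferable
  to clinical cohorts (see above).
* GLDM with α = 0 at high Ng makes nearly every voxel its own dependence
  class on noisy data, inflating instability of that family — inherent to
  the α = 0 convention, not a defect.
* The MCC eigen-solve on near-singular co-occurrence tables can be
  sensitive at the last few ulps; values are clamped at 0 before the
  square root.
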