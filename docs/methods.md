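# Methods

## Data model

All spectra in a study live on one uniform wavenumber grid described by
`(start, step, n_points)`; the abscissa at index *i* is `start + i·step`
(cm⁻¹). The instrument convention bundled as `CANONICAL_GRID` covers
4000 cm⁻¹ upward at 8 cm⁻¹ resolution; because the nominal upper end of
12500 cm⁻¹ is not an integer number of steps from 4000, the canonical grid
keeps the inclusive start and an integer point count (1063 points, last
point 12496 cm⁻¹). Any other uniform grid is accepted; grid uniformity is
enforced once at ingestion and never re-checked downstream. Spectra are
stored ascending in wavenumber regardless of file order.

Absorbance values are treated as arbitrary-unit absorbance throughout; no
log(1/R) or Kubelka–Munk transform is applied, and none of the statistics
below depend on the absolute unit. Each file row is taken to be an
already-averaged instrument scan; raw interferograms are out of scope.

## Preprocessing chain

1. **Savitzky–Golay smoothing** (derivative order 0). Each point is
   replaced by the value at the window centre of the least-squares
   polynomial fit over the window. Boundary points are fit on the window
   truncated at the array edge (grown inward if truncation leaves fewer
   than `polyorder + 1` points), so output length equals input length and
   grids stay aligned. Interior points are computed with
   `scipy.signal.savgol_filter`; edges by explicit local fits.
2. **Multiplicative scatter correction.** Each spectrum is regressed (OLS,
   over all wavenumbers) on a reference spectrum; the correction is
   `(x − a) / b`. The reference defaults to the mean of the set being
   corrected, computed *after* smoothing. When scoring products against a
   saved reference model the reference is instead fixed to the standard
   set's smoothed mean (explicit mode), so one spectrum's score never
   depends on which other spectra share its file. A constant reference or
   a fitted |b| < 1e−12 raises a numerical error rather than producing
   garbage.
3. **Savitzky–Golay first derivative** with a second-order polynomial,
   same boundary policy.

Defaults: both windows 17 points (a 128 cm⁻¹ span at 8 cm⁻¹ resolution),
polynomial order 2 — common chemometrics practice; all overridable. The
derivative is per index point by default (`per_point`): the downstream
Mahalanobis metric is equivariant to any fixed rescaling because the
covariance is estimated on the same scale. `per_wavenumber` (divide by
`step^deriv`) is offered for interpretability of the derivative itself.

Whether scatter correction should be applied per batch or over a whole
study is a genuinely open choice; the pipeline corrects whole sets by
default, and per-group correction can be assembled from `msc_fit` /
`msc_apply` directly.

## Reference model and stability statistic

The stability statistic is the quadratic form
`D = (x − μ) C⁻¹ (x − μ)ᵀ` — the **squared** Mahalanobis distance. It is
reported exactly in this squared form (matching the magnitude conventions
of distance-match chemometrics reports); callers wanting "number of
standard deviations" can take the square root.

`μ` and `C` come from the preprocessed standard spectra of one brand
(minimum 3, all sharing the brand and `role=standard`). With `n_ref` in
the tens and `d ≈ 1063`, the sample covariance is singular; three
treatments are provided:

- **`pca_subspace`** (default): eigendecomposition of the sample
  covariance (divisor `n_ref − 1`, computed via SVD of the centered data).
  The smallest `k` leading components whose eigenvalue sum reaches
  `variance_retained` (default 0.99) of the total are kept; eigenvalues
  below 1e−12 of the largest are always dropped.
  `D = Σⱼ (vⱼ·(x−μ))² / λⱼ` over the retained components. Components are
  ordered by descending eigenvalue; each eigenvector's sign is fixed so
  its largest-magnitude element is positive (determinism). The number of
  retained components is recorded in every result.
- **`shrinkage`**: `C_λ = (1−λ)S + λ(tr S / d)I` with λ the Ledoit–Wolf
  closed-form intensity; λ and the rule name are recorded in the model.
- **`classical`**: plain sample covariance, only when `n_ref − 1 ≥ d`;
  requesting it otherwise raises an error pointing at the alternatives.

Distances in the full-matrix modes are computed by Cholesky solve; an
explicit inverse is formed only for `d ≤ 50`. Useful identities that the
test suite verifies: `D(μ) = 0`; in classical mode the sum of `D` over the
training standards equals `d·(n_ref − 1)` exactly; subspace mode with
`variance_retained = 1` coincides with classical mode on full-rank data;
`D` is invariant under invertible linear maps applied jointly to the data
and the standards.

Batch stability is summarized two ways: per-sample distances, and the
distance of each batch's **averaged preprocessed spectrum** (averaging
after preprocessing, so the batch mean lives in the same space as the
model; this is configurable in principle by averaging before calling the
pipeline). Results are ordered by `date_index`, the batch's integer
position on the production timeline.

PCA score plots (for brand/cup cluster inspection) use centered PCA with
the same largest-element-positive sign convention.

## Cup-equivalence comparison

Paired measurements (one sample source scanned in both cups, linked by an
explicit `pair_id` — the pairing policy is the user's statement, not
inferred) give the paired distance
`D = (x_old − x_new) C⁻¹ (x_old − x_new)ᵀ` in the reference model's
metric; the reference mean cancels. The comparison report contains both
populations (paired and sample-to-standard), shared equal-width histogram
bins spanning the pooled range, medians, ranges, and the separation ratio
`median_sample / median_paired`. A two-sided Wilcoxon rank-sum p-value for
the location difference is attached; it is an addition for decision
convenience, not part of the distance methodology itself.

## Synthetic study generator

The generator produces the statistical structure the analysis assumes, at
configurable scale:

- Each brand is a sum of Gaussian bands plus a polynomial baseline. The
  two default brands share most bands and differ in three band amplitudes
  and one band position — enough for clean PCA separation without
  pretending chemical realism.
- Each product batch draws a smooth batch-level random effect shared by
  its pads; each pad adds its own smooth effect. Smooth effects are random
  coefficients (sd `between_batch_sd` = 0.004 and `within_batch_sd` =
  0.002 absorbance) on a fixed basis of 12 broad Gaussian bumps spanning
  the grid.
- Every measurement receives the shared empty-pad background, then a
  multiplicative scatter transform `b·x + a`
  (`b ~ N(1, 0.02)`, `a ~ N(0, 0.01)`), then white noise
  (`noise_sd` = 2e−4).
- Half of each batch's pads are "scanned" in each cup: the two members of
  a pair share the same underlying pad signal; the self-made-cup member
  additionally gets a fixed spectral offset band (amplitude 1e−3 at
  6200 cm⁻¹) and a 0.2 % gain. These cup terms are the **only**
  cup-dependent quantities in the generator.
- Standard batches are generated the same way (classical cup only, no
  pairing): 11 batches × 4 pads = 44 standards for one brand and
  11 × 5 = 55 for the other at full scale.
- Empty-pad spectra are background plus noise only. The background's
  default amplitude (bands of 0.008/0.005 plus a 0.010 baseline) is set so
  its first derivative is slight relative to the tobacco bands, which is
  what makes similarity scoring insensitive to it.
- An optional anomaly term (off by default) adds an exponentially decaying
  drift to the earliest batches, mimicking early-campaign storage effects.

Randomness is one global stream split deterministically by
(role, brand, batch, pad) via `SeedSequence` spawn keys: the same seed
reproduces a study bit for bit, and adding a batch never changes earlier
batches' spectra.

Default sizes mirror a two-year campaign (62 and 66 batches of 24 pads,
44/55 standards). Tests and the acceptance script use
`scaled_study_config()` — 20 batches × 8 pads and 20 standards per brand —
which preserves the design while keeping a full analysis under a few
seconds; all reported problem sizes state this scale.

Effect sizes were chosen once so that the three distance populations
reproduce the qualitative structure of real campaigns — inter-brand ≫
intra-brand sample-to-standard > paired-cup, with roughly two or more
orders of magnitude between paired and inter-brand medians — and are
frozen. Absolute D values are not meaningful to compare against any
particular instrument: they depend on the grid length and covariance
treatment.

What the simulation does **not** emulate: real band shapes and
chemistry-driven covariance between bands, instrument drift over days,
humidity/temperature effects, pad-to-pad thickness structure beyond the
smooth effects, and non-Gaussian outliers. Passing tests therefore
demonstrate correctness of the computations and the qualitative behavior
of the method under its own assumptions, not quantitative performance on
any real instrument's data.

## Numerical and degenerate-input choices

- Grid spacing uniformity tolerance on CSV ingestion: 1e−9 of the step.
- CSV floats are written with shortest round-trip repr: write→read is the
  identity, bit-exact.
- JCAMP-DX support is a strict subset: `(X++(Y..Y))`, AFFN numerals,
  uniform `DELTAX` (negative `DELTAX` is reversed to ascending). Anything
  else — SQZ/DIF/DUP compression, peak tables — raises an explicit
  "unsupported variant" error instead of misparsing.
- Eigenvalue ties in the subspace model keep the decomposition's
  first-occurrence order; signs fixed as above.
- Histogram bins: `n_bins` equal-width bins over the pooled min–max; if
  all distances coincide the range is widened by 1 to avoid zero-width
  bins.
- The end-to-end run manifest records the config snapshot, seed, stage
  parameters and SHA-256 digests of every artifact; its wall-clock
  timestamps are the only non-deterministic bytes in a report bundle.

## Known limitations

- The MSC reference in explicit mode must come from the same preprocessing
  (smoothed scale); the model JSON stores it to make scoring of new
  spectra self-contained.
- Shrinkage-mode models hold a `d × d` matrix in memory (~9 MB at
  d = 1063); serialization of shrinkage models stores the full matrix and
  is correspondingly large. The subspace model is compact and is the
  default.
- No control-chart limits are defined on D; the package reports distances
  and comparisons, and leaves accept/reject thresholds to the user's QC
  policy.
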