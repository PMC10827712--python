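# Methods

## The model

A 3D binary segmentation drawn axial slice by axial slice can be
inconsistent between adjacent slices even when every individual slice is
plausible. The package quantifies this by looking at the segmentation's
silhouettes: the mask is collapsed along the anterior–posterior axis
(coronal view) and along the left–right axis (sagittal view), and each
projection is binarized — a pixel is foreground iff any voxel along the
collapsed axis is foreground. Binarization is deliberate: only the
support of the silhouette carries the staircase signal, and using counts
instead would mix in organ thickness.

Each projection σ(u, z) ∈ {0, 1} is then treated as a height field and
its local mean curvature H is evaluated at every pixel (formula in the
README). For a binary field H vanishes wherever the 3×3 stencil sees a
constant patch, so |H| concentrates in a band around the silhouette
edges. A smooth edge contributes a fixed small amount of |H| per unit
edge length; a staircase edge contributes several times more because
every step corner is a curvature event. Summing |H| over both views and
dividing by the combined foreground areas yields a dimensionless,
size-normalized scalar: edge roughness. On straight tubular phantoms the
baseline (curved smooth outline) is ≈ 0.08–0.15 depending on radius and
centerline drift; per-slice jitter raises it steeply and monotonically
(the acceptance suite checks strict monotonicity over jitter amplitudes
0/1/2/4 px with rank-sum separation at p < 0.01).

## Numerical choices

* **Derivatives.** Central finite differences with replicate
  (edge-clamp) padding; second derivatives by the standard three-point
  stencil; the mixed term σ_xy as the central difference of the σ_x
  field. Grid spacing is 1 (pixel units on the 1 mm resampled grid), so
  σ and H are dimensionless. These choices are isolated in two small
  helpers so an alternate stencil can be swapped in.
* **No pre-smoothing.** σ enters raw. Smoothing would suppress exactly
  the jagged-edge signal the metric exists to measure.
* **Summation.** |H| is summed over all pixels (it vanishes away from
  edges) using exactly-rounded summation (`math.fsum`), which makes the
  scalar bit-identical under mirror flips and integer translations of
  the mask — the symmetry laws the tests assert as exact equalities.
* **Sign.** The stored curvature map keeps the leading minus sign of the
  mean-curvature convention; the metric uses |H| so the sign never
  affects it.
* **Resampling.** Masks are resampled to 1 mm isotropic (nearest
  neighbour) before measurement so areas and curvature sums are
  comparable across cases; nearest neighbour guarantees binary output
  without a threshold parameter. The resampler maps each output cell
  center to the input cell containing it, which preserves the physical
  extent within one voxel and is exactly idempotent.
* **Degenerate inputs.** Empty masks are refused everywhere a ratio or
  extent would be undefined (roughness, length, Dice on two empty
  masks): an empty contour is a data problem, not a zero or a perfect
  score. Projections smaller than 3×3 are refused because the stencil is
  undefined.

## Geometric metrics

* **Length** is the contiguous craniocaudal extent — (z_max − z_min + 1)
  slices times slice thickness — not the count of occupied slices; the
  occupied-slice count is reported separately so gapped (pathological)
  masks are visible. Full vs partial classification uses an inclusive
  18 cm threshold, the conventional boundary between whole-organ
  esophagus contours (conventionally fractionated radiotherapy) and
  tumour-level partial contours (SBRT).
* **Dice** is voxel-count overlap 2|A∩B|/(|A|+|B|). For partial
  references, both masks are first restricted to the axial slices where
  the reference has foreground, so a full-length prediction is not
  penalized against a truncated ground truth.
* **Outlier tabulation** counts cases with Dice ≤ threshold (inclusive)
  at 20/40/50/70% by default.

## Cohort statistics

* **Quantile filtering** partitions a cohort by a quality key into Q1
  (key ≤ 25th percentile), Q4 (key ≥ 75th) and the middle 50%.
  Percentiles use linear interpolation between order statistics.
  Assignment is evaluated in the fixed order Q1 → Q4 → middle50, so tied
  boundary records land on one side and the three branches always
  partition the input. On 248 records with distinct keys this yields
  62/62/124.
* **Dunn's test** (after a Kruskal–Wallis gate) uses mid-ranks for ties
  and the tie-corrected pooled variance N(N+1)/12 − Σ(t³−t)/(12(N−1));
  two-sided p-values come from the standard normal. P-values are
  reported unadjusted by default — the significance convention is a
  fixed two-sided 0.01 — with an optional Holm step-down correction.
  Null calibration (three identical groups, 1000 replicates) is verified
  in the acceptance suite.
* **Fisher exact** follows the standard two-sided definition (sum of
  hypergeometric probabilities ≤ the observed table's); the test suite
  cross-checks it against an exact integer enumeration for every 2×2
  table with N ≤ 40.
* **t comparisons** default to the Welch (unequal-variance) form, the
  safer choice when variances are unknown; the pooled form is a flag.

## The synthetic phantom generator

`generate_tube` emulates what a clinician produces when contouring a
roughly cylindrical organ slice by slice: per axial slice, a filled disk
whose center follows a smooth one-period sinusoidal drift (default
amplitude 4 px — gentle anatomical curvature), plus an independent
uniform integer jitter in [−j, +j] px per in-plane axis (the
inconsistency knob), with per-slice radius ~ N(8, 0.5) px floored at
1 px. Defaults describe a full-length esophagus on a 1 mm grid: 200
slices (20 cm), radius 8 mm. Jitter is independent per slice — the
simplest model of slice-to-slice shift; autocorrelated jitter would be
an extension, not the default. An optional 3-slice moving average of the
centers emulates interpolation/smoothing tools (and measurably lowers
roughness at jitter ≥ 2 px, which the tests check). Partial contours are
a contiguous crop (random start), matching clinical partial contours
around a tumour level. All draws come from one seeded generator with
integer jitter, so outputs are bit-reproducible across platforms.

`generate_cohort` samples each case's segmented length from the style's
normal distribution (floored at 4 cm); cases flagged partial (with the
style's probability) realize that length as a random-start contiguous
crop of a nominally full-length tube, so the sampled length is always
the measured length regardless of the flag. Records carry the length and
roughness actually measured on the generated mask, not the sampled
parameters.

What the phantoms do **not** emulate: anatomical cross-sections (disks,
not esophageal lumens), CT intensities and their artifacts, reader-
specific systematic boundary bias, or correlated multi-slice drift of a
hurried annotator. Passing tests therefore demonstrate that the metric
responds correctly to the geometric mechanism it targets — per-slice
lateral shift — under controlled conditions; they do not certify
clinical effect sizes, which depend on private clinical data.

## Problem sizes

The validation suite uses 20 phantoms per jitter level for monotonicity,
30 cases per style for the two-style discrimination cohort, a 290-case
pool filtered to 248 full-length cases for the quantile design, and
1000 replicates for the Dunn null calibration; these sizes give stable
statistics for the properties being checked while keeping the whole
suite quick on a single CPU.

## Known limitations

* Roughness values depend on grid resolution; comparisons are only valid
  at a common spacing (hence the default 1 mm resampling step).
* The curvature formula treats a binary image as a height field; the
  resulting H values are a roughness functional, not a differential-
  geometric curvature of the organ surface.
* Rasterization of RT-STRUCT contours uses an even–odd fill at voxel
  centers with a half-open edge rule; treatment-planning systems vary in
  their fill conventions, so voxel counts near boundaries may differ
  from a TPS export by a sub-voxel layer.
* In-plane handedness of loaded volumes follows the file's native frame
  after axis-order normalization (z axial); all metrics are mirror-
  invariant, so this does not affect results.
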