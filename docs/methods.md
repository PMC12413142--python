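# Methods

## Tissue classification

Classification applies closed HU intervals to a calibrated slice: NAMA
[+30, +150], LAMA [−29, +29], IMAT [−190, −30] within the muscle boundary,
and the same fat window [−190, −30] for VFAT/SFAT within the visceral and
subcutaneous compartments. Two conventions are worth stating explicitly:

* **Integer semantics.** HU are rounded to the nearest integer (ties away
  from zero) before the window tests. CT attenuation is integer-quantized
  at acquisition, and integer semantics make the adjacent printed bounds
  (−30 fat / −29 LAMA) exhaustive: every real-valued HU in between rounds
  into exactly one window.
* **Explicit unclassified bucket.** Muscle-boundary pixels with rounded HU
  above +150 or below −190 are counted as `unclassified` and excluded from
  SMA. This preserves the exact partition identity
  NAMA + LAMA + IMAT + unclassified = muscle area for every input, rather
  than silently dropping pixels.

IMAT is computed only inside the muscle boundary (it is *intra*muscular by
definition); fat outside muscle belongs to VFAT/SFAT through their own
masks. Areas are `count × spacing_row × spacing_col / 100` cm². BMI is
kept at full precision; display rounding (half away from zero, one
decimal) happens only at the report layer. Masks are inputs — this package
performs no segmentation; it consumes segmentations from any source.

## Muscle age

The model is a sex-specific linear regression of SMA/BMI on age, fitted by
OLS to reference subjects aged 35–65 (about the 5th–95th age percentiles
of a healthy adult population; rows outside the window are excluded and
counted). The inverse map age&#770;(s) = (s − a)/b defines muscle age, and the
delta method propagates the coefficient covariance:
Var = J Σ Jᵀ with J = [−1/b, −(s − a)/b²]. Design choices:

* **HC flavor.** Σ is heteroscedasticity-consistent; HC3 is the default
  for its small-sample behavior, with HC0–HC2 selectable. Reference
  populations show age-dependent spread in SMA/BMI, so a homoscedastic
  covariance would understate the SE at the extremes.
* **s treated as fixed.** No measurement-error term for the subject's own
  SMA/BMI enters the variance; the SE quantifies reference-model
  uncertainty only.
* **Display clamp.** Raw estimates are preserved, but displayed values are
  clamped to [20, 90] years with an explicit flag. A linear fit inverted
  far outside the reference support extrapolates without evidence; the
  clamp bounds the reported number while keeping the raw one auditable.
* **Invertibility floor.** Fits with |b| below 10⁻⁶ × SD(s)/SD(age) are
  refused rather than inverted: at that scale the line is numerically
  flat and the inverse explodes.

The original 11,845-subject reference population is not redistributable,
so fitting always runs against user-supplied or synthetic reference
cohorts; the numeric muscle ages in any real deployment depend on the
reference fit and are not reproduced here.

## Cohort statistics

Subjects are banded by age decade (half-open [20, 30) … [60, 70), 70+
open-ended; under-20s excluded with a warning). Summaries report n, mean,
and sample SD (n−1; absent for singleton cells). The ANOVA is classical
equal-variance one-way ANOVA computed from sums of squares —
F = [SSB/(k−1)] / [SSW/(N−k)] — with p from the F survival function; it is
implemented directly (scipy supplies only the F distribution) and
cross-checked in tests against `scipy.stats.f_oneway` and the two-group
t² identity. No Welch correction and no multiple-testing adjustment are
applied, matching the analysis being reproduced. Degenerate inputs are
defined, not errors: SSW = 0 with distinct means gives F = ∞, p = 0 (with
a warning); all-constant data gives F = 0, p = 1. Display formatting
prints p < 10⁻³ as "<.001"; raw values are retained in machine output.

## Segmentation evaluation

DSC(A, B) = 2|A∩B|/(|A|+|B|) by exact integer arithmetic; multi-class
label images are scored one-vs-rest per label. Two masks that are both
empty score 1.0 (perfect agreement on absence) with a `both_empty` flag,
since the ratio is otherwise 0/0. Suite-level output reports per-case,
per-class DSC plus mean and sample SD across cases.

## Synthetic phantoms and cohorts

The phantom emulates the geometry of a segmented L3 slice, not its
anatomy: a body ellipse containing a circular muscle annulus, visceral
interior, and subcutaneous rim. Concentric shapes were chosen because
their pixel counts — and therefore every ground-truth area — are exact by
construction. Per-class HU values are drawn uniformly inside the class
window shrunk by `hu_margin` (default 10 HU), plus Gaussian noise
truncated at ±4 SD (default SD 2 HU). The validated constraint
`hu_margin > 4 × noise_sd_hu` makes the no-boundary-crossing guarantee
provable rather than probabilistic: no sampled pixel can leave its
intended window, so quantification reproduces the generator's ground
truth bit-exactly. HU grids are integer-valued, which also makes the
DICOM stored-pixel round trip exact (RescaleSlope 1, Intercept 0, signed
16-bit). Defaults (256 px at 1 mm, body semi-axes 110 × 90 mm, muscle
ring 45–65 mm, class fractions 0.7/0.2/0.1, VFAT 40 cm², SFAT 60 cm²)
give a mid-sized adult abdomen with plausible area magnitudes.

The reference-cohort generator draws ages uniformly and SMA/BMI as
a + b·age plus mean-zero Gaussian noise whose SD may grow linearly with
age (heteroscedasticity). Default coefficients (male a=8.6, b=−0.045;
female a=5.9, b=−0.028; SD 0.6) were chosen so that window-restricted
means and the decline per decade are of the magnitude seen in healthy
adult cohorts; they are free parameters, not published values. The
check-up generator draws each subject's metrics independently from the
published per sex × decade means/SDs (`ctcomp.reference_tables`), with
ages uniform in the band; the open-ended 70+ band is generated on
[70, 80) so moments are finite and the band midpoint convention (75)
holds.

What the synthetic data deliberately does **not** emulate: anatomical
shape variation, partial-volume mixing at tissue interfaces, scanner
artifacts and dose modulation, contrast-phase effects, and correlation
between metrics within a subject (check-up metrics are drawn
independently although real NAMA/SMA/IMAT are strongly dependent).
Passing tests therefore demonstrate correctness of the measurement and
statistics pipeline, not segmentation robustness or physiological realism.

## Numerical and validation choices

* All randomness flows through explicit `numpy.random.default_rng` seeds;
  identical inputs reproduce bit-identical outputs, and batch re-runs are
  byte-identical (timings excluded).
* Monte-Carlo checks use problem sizes chosen to make sampling error
  negligible relative to the tolerance: n = 10,000 draws for group-mean
  recovery (bound 3·SD/√n), 200 replicates of n = 5,000 for slope CI
  coverage (accepted range 92–98%), and a 2,000-replicate pairs bootstrap
  on n = 1,000 for the delta-method SE comparison (15% relative
  tolerance).
* Per-case pipeline isolation is contractual: a failure is captured as a
  failed report with its reason, and #success + #failed = #cases always.
  Stage timings are logged for monitoring but never asserted.

## Known limitations

* Slice selection and segmentation are out of scope; quality of the input
  masks bounds the quality of every downstream number.
* The muscle-age model is linear by design; real age trends may flatten or
  steepen at the extremes, which the 35–65 fit window mitigates but does
  not remove.
* Single-slice, single-phase analysis only; no volumetric or longitudinal
  modeling beyond the serial-report listing.
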