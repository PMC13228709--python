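# Methods

This note documents the models, conventions and defaults behind `kneeasym`,
the choices made where the design was genuinely open, and what the
synthetic-data validation does and does not establish.

## Coordinates and geometry

Landmarks are image pixel coordinates: origin at the top-left corner, `x`
mediolateral (columns), `y` proximo-distal (rows, increasing distally),
sub-pixel positions allowed. All physical quantities are computed after
scaling by the pixel spacing (`row_mm`, `col_mm`), read from the DICOM
`Imager Pixel Spacing` attribute by preference (`Pixel Spacing` as
fallback; the precedence is configurable). Working in pixel space with
explicit spacing keeps anisotropic detectors honest — angles are computed
in mm space, so anisotropic spacing changes them, as it does physically.

Definitions per knee:

* **Joint-space width** (medial, lateral): Euclidean distance between the
  paired femoral and tibial points on the condyle centerline,
  `sqrt((Δx·col_mm)² + (Δy·row_mm)²)`. A vertical-only reading of the gap
  was the alternative; the Euclidean form is the more general choice and
  reduces to the vertical distance when the pair shares `x`, which our
  landmark constructor and detector both produce.
* **Intercondylar distance**: the centerlines are vertical lines, so this
  is a mediolateral-only distance: `|x̄_med − x̄_lat| · col_mm`, where each
  centerline `x̄` is the mean `x` of the compartment's femoral and tibial
  joint-space points. Note this measure is deliberately *not* rotation
  invariant (it is a distance between vertical lines, not points).
* **Femur width**: Euclidean distance between the condylar outer margins at
  the level of the top of the intercondylar fossa.
* **Tibia widths**: outer-margin distances at 1 cm (proximal) and 10 cm
  (distal) below the plateau.
* **FT angle**: tibial anatomic axis (line through the midpoints of the
  1 cm and 10 cm tibial margin pairs) versus the femoral axis taken as the
  distally pointing perpendicular of the condylar tangent through the two
  femoral joint-space points.
* **VV angle**: tibial anatomic axis versus the femoral anatomic axis. The
  femoral anatomic axis has no canonical landmark definition on a knee
  radiograph; we mirror the tibial construction — midpoints of shaft-width
  margin pairs at two levels above the condylar tangent, 1 cm and 10 cm by
  default and configurable (the phantom uses 2.5 cm / 8.5 cm so the shaft
  segment fits its canvas).

**Angle sign convention**: the signed angle between the distally pointing
axes (via the 2-D cross product) multiplied by a side factor (+1 right
knee, −1 left), so that positive means varus (distal segment deviating
medially) on either side. Mirroring an image in `x` with a fixed side label
therefore flips the sign and preserves the magnitude. Only the absolute
values enter the asymmetry statistic.

**Asymmetry statistic**: `X_diff = ||X_L| − |X_R|| / |(X_L + X_R)/2|`.
When the denominator is exactly zero (possible for signed angles of equal
magnitude and opposite sign) the value is undefined and flagged per field,
never returned as infinity. Verified properties: swap symmetry, invariance
under positive rescaling, zero iff equal magnitudes, range [0, 2] for
same-sign inputs.

**Intra-rater variability**: for repeated measurements of the same knees,
we report per measure the mean absolute difference between repeats (native
units) and a relative percentage defined as that difference divided by the
grand mean of the measured magnitudes × 100. The magnitude (not signed)
mean keeps the denominator away from zero for the signed angles. This is
one of several defensible readings of a "relative variability" percentage;
it is fixed here and used consistently, including by the noise-calibration
closed form below.

## Landmark constructor (geometry oracle)

`construct_landmarks` inverts `measure_knee`: given target measures it
places all fifteen landmarks so the measures are recovered exactly
(verified to 1e-9 relative over a thousand random draws, machine precision
in practice). The canonical layout puts the condylar tangent horizontal and
solves the tibial and femoral axis tilts from the requested angles; mirror
and rotation (|rotation| < 60°) are applied as rigid maps about the joint
center. Because the intercondylar distance is an x-only measure, the
condylar span is solved against the layout's rotation/mirror so that the
*measured* value equals the target even in rotated layouts. Unrealizable
requests (non-positive lengths, joint space ≥ femur width, angles outside
(−90°, 90°)) raise a construction error.

## Phantom renderer and detection

The phantom is deliberately schematic — femoral shaft, two rectangular
condyles with flat bottoms on the tangent, a tapered tibia whose plateau
line passes through the tibial joint-space points — because only the
measurement geometry needs to be exact. Shapes are rasterized by area
coverage (anti-aliased), which is what makes sub-pixel edge localization
possible downstream. Intensities: background 0.15, bone 0.85 (contrast
must be ≥ 0.2); optional additive Gaussian noise with a mandatory seed.

Canvas default: 1024×1024 px at 0.2 mm isotropic spacing (204.8 mm
square). A narrower canvas cannot hold two anatomically sized legs
(~75–80 mm femur width) side by side together with the 10 cm tibial level,
so the square canvas is the default; everything is configurable. The
condyle width is `femur_width − intercondylar`, so geometry with
`2·intercondylar − femur_width` below 3 mm leaves no renderable notch and
raises a render error.

Detection stage (all thresholds from a two-class split of the intensity
histogram; the edge-crossing level is the midpoint of the background and
bone levels, and every edge is localized by linear sub-pixel
interpolation):

1. **Legs**: columns whose above-threshold pixel count exceeds a minimum
   form runs; exactly two dominant runs (≥ 40 % of the longest) are
   required, else a detection error. Boxes take the run extent plus the
   bright row extent, padded 6 px.
2. **Joint line**: the darkest band of the row-mean profile within the
   central half of the box; both band edges are localized at the half-rise
   toward the neighbouring bone shoulders and their midpoint is returned.
   This centers the estimate between the condylar tangent and the mean
   plateau level, and makes it exactly translation equivariant.
3. **Landmark proposals**: condyle centerlines as intensity-weighted
   centroids of the two condylar blobs in a slab 4–12 mm above the joint
   line; joint-space points as the sub-pixel bone boundaries scanned along
   the centerline columns; the fossa top as the first bone crossing
   scanning up the midline notch; margins as the outermost row-edge
   crossings at the prescribed offsets (1 cm / 10 cm below the plateau,
   the configured femoral shaft levels above the tangent). The offsets are
   the a-priori measurement levels shared with the renderer's layout, not
   ground-truth values. Medial/lateral labels follow the AP convention
   (medial side toward the image midline; the left-most box is the
   patient's right knee).

Measured accuracy on noiseless phantoms across a 50-geometry sweep: joint
line within 0.3 px, landmarks within ~1.5 px, lengths within 0.8 % and
angles within 0.25° of ground truth — comfortably inside the 2 px / 5 % /
1° acceptance envelopes. The phantom does not emulate soft tissue,
osteophytes, exposure gradients or projection obliquity; detection numbers
on it bound algorithmic error only, not clinical performance.

## Cohort rules

* Pooled baseline exclusions, each subject counted once: age > 67 (strict:
  exactly 67 is retained), injury or knee surgery/arthroscopy history,
  baseline KL > 2 in either knee, and weight change > 10 kg — evaluated as
  `max_t |weight_t − weight_baseline|` over the recorded series, the
  "change from baseline at any time" reading (change between consecutive
  visits was the alternative). The limited-tibia-view exclusion follows as
  its own step. An audit records every step; counts are conserved by
  construction and re-checked.
* Knee grouping at follow-up: KL 0–1 → KL01, 2 → KL2, 3–4 → KL34S; knee
  arthroplasty is absorbing (surgery without a follow-up grade is still
  KL34S). Missing follow-up grade without surgery makes a knee ungradable.
  Subject grouping takes the maximum severity of the two knees.
* Asymmetry dataset: subjects with both knees gradable and baseline KL
  difference < 2 (a 0-vs-2 pair says the knees already differ structurally,
  which would contaminate an asymmetry exposure).
* Longitudinal dataset: implant knees get zero follow-up joint space by
  convention (an implant gap is not a joint space) and are excluded from
  follow-up statistics — the KL34 group is KL34S minus implants — while
  remaining in KL34S summaries.

## Statistics

* Odds ratios are unadjusted by design (descriptive risk-factor table);
  no covariate-adjusted OR mode is offered. CI: Woolf log method with
  `z = Φ⁻¹(0.975)`. Zero cells raise a signal and are reported as such;
  the Haldane–Anscombe +0.5 correction is available only behind an explicit
  flag. Cumulative asymmetry thresholds are inclusive (exactly 10 % is
  exposed) and share the fixed `< 10 %` reference.
* Group comparisons: linear model of the measure on group plus age, sex,
  weight and height. Clustered data (knees within subjects, repeated
  timepoints within knees) get random intercepts (ML, not REML); with one
  observation per cluster the mixed model is degenerate and the fit *is*
  ordinary least squares, which we use directly — the two coincide there.
  Pairwise contrasts are Bonferroni-adjusted over the group pairs,
  mirroring the Dunn–Bonferroni choice used for demographics.
* Demographics: Kruskal–Wallis omnibus plus Dunn's pairwise z tests with
  the standard tie-corrected rank variance and Bonferroni adjustment.
  Dunn's test is implemented here (no installed dependency provides it)
  and is cross-checked in the tests against an independent rank
  computation.
* Figure-style summaries use mean ± 1.96·SE, checked against a bootstrap.

## Synthetic cohort generator

The generator defines the validation conditions; its defaults are fixed:

* Demographics: age ~ U(45, 67) at baseline; 68 % female; height and
  weight normal by sex (male 1760±70 mm, 85±13 kg; female 1630±65 mm,
  72±13 kg); weight follows a per-subject drift (sd 0.8 kg/yr) plus visit
  noise (sd 1 kg) over 8 years, so a realistic few percent of subjects
  trip the >10 kg exclusion.
* True geometry: per measure, left/right values are bivariate normal with
  a left-right correlation (0.85–0.97 depending on the measure). The
  population means and sds (e.g. medial JS 5.0±0.8 mm, femur width
  75±4 mm) are plausible round numbers chosen for this simulation — they
  are explicitly *not* estimates from any cohort dataset.
* Measurement noise: multiplicative log-normal for dimensions (positive,
  median-unbiased) with relative sds at the intra-rater variability
  magnitudes (medial JS 6.13 %, lateral JS 4.96 %, intercondylar 1.62 %,
  femur width 0.94 %, proximal tibia 1.26 %, distal tibia 2.33 %);
  additive normal for the angles with the reported mean absolute
  differences (0.38°, 0.79°) used directly as the sd. The repeatability
  emulator re-noises true values twice at `1/√2` of these sds, so the
  *difference* of two replicates has the configured sd; the folded-normal
  closed form `E|Δ| = 2·s·mean/√π` then predicts the variability report
  and is asserted within 10 %.
* Outcome: subject-level logistic model,
  `logit p = −2.4 + ln(2)·[asym ≥ 10 %] + 0.04·(age−56) + 0.06·(BMI−27.5)`,
  giving roughly 10 % advanced OA. The exposure indicator is the
  **measured** (post-noise) baseline medial JS asymmetry — the quantity a
  reader of the radiographs can actually compute — so the pipeline's
  tabulated exposure coincides with the generating one and the threshold
  OR of 2.0 is the pipeline's estimand. Had the outcome been tied to the
  latent noise-free asymmetry instead, exposure misclassification at these
  noise magnitudes would attenuate the realized OR well below 2 and no
  estimator working from the emitted tables could recover it; the chosen
  design separates pipeline correctness from the (real and interesting,
  but distinct) attenuation phenomenon. Mild OR non-collapsibility from
  the age/BMI terms biases the marginal OR a few percent toward the null,
  well inside the CI widths at the validation sizes.
* Progression: group-specific 8-year joint-space narrowing (medial
  1.8±0.4 mm for OA knees, 0.5 mm KL2, 0.15 mm KL01; lateral roughly
  half), small drifts for the other dimensions, VV-angle shrinkage, a 12 %
  implant probability among OA knees (absorbing, half with missing
  follow-up grades to exercise that rule), and 12 % missing follow-up KL
  grades overall.

Validation under these conditions (all computed by the tests and
`scripts/acceptance.py`): the truth-ledger OR tabulated from the generated
tables is within 15 % of 2.0 at n=5000; the pipeline's Woolf CI covers 2.0
in ≥ 93 % of 200 seeded replicates; under the null the median pipeline OR
is ~1.0 with CI coverage inside 93–97 % over 500 replicates; increasing
measurement noise never decreases the mean measured asymmetry (folded-
normal inflation, checked over a seeded sweep). Passing these shows the
pipeline is an unbiased, correctly calibrated estimator of its estimand
under the generator's assumptions — it does not validate the clinical
claim on real radiographs, where projection geometry, rater behaviour and
unmodelled confounding all enter.

## Numerical choices and problem sizes

* Exact-geometry assertions use 1e-9 relative tolerance; stochastic checks
  state their tolerance per test (10–15 % for closed-form noise checks,
  two-sided 93–97 % bands for coverage).
* Sub-pixel edges interpolate the midpoint crossing linearly between pixel
  centers; pixel `i` spans `[i, i+1)` with center coordinate `i + 0.5`.
* CSV readers use round-trip float parsing so landmark files survive
  write/read losslessly.
* Validation sizes: 1,000 geometry round trips; 1,000 random tables and
  1,000 coverage simulations (tables of 500); 200 recovery and 200 null
  pipeline replicates at 5,000 subjects plus a 500-replicate null
  calibration at 2,000 subjects; 50 phantom geometries; 1,000 type-I
  replicates at n=100. These sizes put simulation error well below every
  asserted tolerance while keeping the full suite under a few minutes.

## Known limitations

* The phantom's intensity model is binary-plus-noise; detection thresholds
  would need re-derivation for images with soft-tissue gradients.
* The femoral anatomic-axis construction is a package convention; VV
  angles are comparable within the package but not necessarily to goniometric
  conventions elsewhere.
* The generator draws measures independently of each other (only left and
  right of the *same* measure are correlated), so cross-measure
  correlations present in real knees are not emulated.
* Odds ratios are unadjusted throughout; confounded exposure–outcome
  structures in real data are out of scope by design.
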