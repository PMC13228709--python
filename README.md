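# kneeasym

Bilateral knee-radiograph morphometry and joint-space-asymmetry risk
analysis for radiographic osteoarthritis (OA).

Absolute knee dimensions measured from a single radiograph say little about
who will develop OA, but people carry their own internal control: the
contralateral knee. This package implements a pipeline built on that idea.
Eight measures are taken per knee from anterior-posterior weight-bearing
radiograph landmarks — medial and lateral joint-space width (JS),
intercondylar distance, femur width at the top of the intercondylar fossa,
proximal (1 cm) and distal (10 cm) tibia widths, the femur–tibia (FT) angle
and the varus–valgus (VV) angle — and for every measure `X` the relative
left–right asymmetry is

```
X_diff = | |X_left| − |X_right| |  /  | (X_left + X_right) / 2 |
```

a dimensionless fraction: symmetric in the two sides, invariant under
rescaling, zero iff the magnitudes agree, and at most 2 for same-sign
inputs. Subjects are grouped by Kellgren–Lawrence (KL) grade at an 8-year
follow-up — KL01 (grades 0–1), KL2 (grade 2), KL34S (grades 3–4 or partial/
total knee arthroplasty) — and the association between baseline medial JS
asymmetry and later advanced OA is quantified with unadjusted odds ratios
over cumulative thresholds (≥ 10 %, ≥ 12.5 %, ≥ 15 %, each versus < 10 %),
with the Woolf (log-normal) 95 % confidence interval

```
exp( ln OR ± z_0.975 · sqrt(1/a + 1/b + 1/c + 1/d) ),   OR = (a·d)/(b·c).
```

The package contains:

* **`morphometry`** — landmark geometry (all eight measures, anisotropic
  pixel spacing via the DICOM header convention), the asymmetry statistic,
  and intra-rater repeatability reports;
* **`phantom`** — a schematic radiograph renderer with exact ground-truth
  geometry, plus the intensity-profile detection stage (leg boxes, joint
  line, rough landmark proposals) so the automation is testable end to end;
* **`cohort`** — the baseline exclusion cascade (age > 67, injury/surgery
  history, baseline KL > 2, weight change > 10 kg — pooled, each subject
  counted once — then limited tibia view), KL grouping, and the three
  analysis datasets (knee-level baseline, subject-level asymmetry,
  longitudinal with implant zero-joint-space handling);
* **`stats` / `risk`** — the odds-ratio model (`AsymmetryRiskModel` /
  `AsymmetryRiskResults`, statsmodels-style), covariate-adjusted group
  comparisons (mixed model with random intercepts, reducing to OLS for
  person-level data) and Kruskal–Wallis/Dunn–Bonferroni demographics tests;
* **`synthetic`** — a cohort generator with correlated bilateral geometry,
  measurement noise at intra-rater magnitudes, demographics, and a logistic
  outcome model with a known threshold odds ratio, used to validate the
  whole pipeline by parameter recovery.

## Worked example

```python
from kneeasym.synthetic import CohortConfig, generate_cohort
from kneeasym.cohort import Cohort
from kneeasym.risk import AsymmetryRiskModel

cohort = generate_cohort(CohortConfig(n_subjects=2000, seed=7))
model = AsymmetryRiskModel.from_cohort(Cohort.from_synthetic(cohort))
print(model.fit().summary())
```

prints (abridged):

```
Odds of advanced OA (KL34S) by exposure category, n = 1122
Variable                              Category      OR (95 % CI)            a/b/c/d
------------------------------------------------------------------------------------------
Sex (vs Male)                         Female        0.70 (0.48 - 1.03)      78/675/52/317
Age (years) (vs < 60)                 ≥ 60          1.24 (0.85 - 1.81)      48/318/82/674
BMI (kg m^-2) (vs < 25)               ≥ 30          2.13 (1.29 - 3.51)      46/269/27/336
Medial JS asymmetry (%) (vs < 10.0)   ≥ 10.0        2.40 (1.65 - 3.48)      78/382/52/610
Medial JS asymmetry (%) (vs < 10.0)   ≥ 15.0        2.51 (1.61 - 3.91)      40/187/52/610
```

Of the 2000 simulated subjects, 878 fall to the exclusion cascade and the
ungradable/KL-difference-2 drops (`model.audit` holds the step-by-step
counts), leaving 1122 in the asymmetry analysis. The generator's true
threshold odds ratio is 2.0: subjects whose measured baseline medial JS
asymmetry is ≥ 10 % have twice the conditional odds of advanced OA at
follow-up, and the fitted OR of 2.40 (CI 1.65–3.48) recovers it within
sampling error. Cells are printed `a/b/c/d` = exposed-OA / exposed-healthy /
reference-OA / reference-healthy.

The same flow is available from the shell:

```sh
kneeoa simulate -n 2000 --seed 7 --out data/
kneeoa analyze --data data/ --mode all --out results/
kneeoa report --results results/
kneeoa phantom render --seed 1 --out scratch/ph && kneeoa phantom detect --image scratch/ph.png --out scratch/det.json
```

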