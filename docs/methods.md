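# Methods

## The statistical procedure

A limited-sampling strategy (LSS) approximates a full-profile
pharmacokinetic metric by a linear form over a few timed samples.  For
each probe the package:

1. computes per-subject **best estimates** from the complete profile —
   linear-trapezoidal AUC(0–12h) for caffeine, fexofenadine and
   midazolam; parent:metabolite AUC(0–12h) ratio for metoprolol and
   omeprazole;
2. fits, by ordinary least squares, **every** size-k subset of the
   candidate sampling times (k = 1…3 by default) with the metric as
   response and the timed concentrations — or, for the ratio probes, the
   per-time parent:metabolite concentration ratios — as predictors;
3. ranks the C(n, k) equations by the training coefficient of
   determination R², breaking ties toward the subset whose latest sample
   comes earliest (shorter clinic visits), then lexicographically;
4. compares candidate *shared* time sets across all five probes by the
   mean ± SD of the per-probe R², flags sets with mean R² > 0.95, and
   tests the leading sets against each other with a one-way fixed-effects
   ANOVA treating the five per-probe R² values as the group observations;
5. validates chosen equations two ways: **externally**, applying the
   frozen training-phase coefficients to the second study phase and
   comparing with that phase's own best estimates; and by **jack-knife**,
   refitting n times on n−1 subjects at fixed times and pooling the n
   out-of-fit predictions into a single summary.

Bias and precision are reported as the mean ± sample SD (n−1) of the
signed and absolute per-subject percentage differences
d = (predicted − best)/best·100 (MD%, MAD%).  Two R² notions are kept
deliberately distinct: *training R²* is the OLS coefficient of
determination; *evaluation r²* is the squared Pearson correlation between
predicted and best-estimate values on whatever dataset is being judged.
Agreement on the metric scale uses Bland–Altman statistics: mean
difference ± 1.96 sample SD, plotted against the pairwise mean.

Notable policy choices, made where the procedure leaves room:

* **Linear trapezoid throughout** (no lin-log variant, no extrapolation
  past 720 min): it is the conservative reading of "trapezoidal method"
  and exact on piecewise-linear fixtures.
* **BLQ handling is positional, not value-based**: a sampling time is
  inadmissible for model development if *any* analysed analyte is BLQ at
  that time in *any* subject.  Within NCA, BLQ records contribute their
  recorded value (the generator preserves it); real data recording BLQ as
  missing would be imputed as zero with a logged warning.
* **Ratio-probe predictors are always per-time ratios**, never raw
  concentrations.
* **Negative predictions are reported and logged, never truncated** —
  truncation would silently bias MD%.
* **No multiple-testing correction** is applied to the exhaustive subset
  search; the resulting optimism is precisely what the external and
  jack-knife validations measure (the test suite asserts the expected
  ordering: mean validation r² ≤ mean training R²).
* The jack-knife summary r² pools the n out-of-fit predictions into one
  squared-Pearson computation rather than averaging per-fold values,
  matching the one-R²-per-model reporting convention.
* Subjects whose metabolite is BLQ in more than half their samples (poor
  metabolizers) are excluded from development, validation and
  admissibility assessment *for that probe only*.

## The synthetic cohort

The trial emulated by the generator (16 healthy adults, two phases 15
days apart, samples at 0, 15, 30, 45, 60, 90, 120, 180, 240, 300, 360,
480, 600, 720 min) did not publish raw concentrations, so all
development and testing runs on synthetic data with the same structure.

**Kinetics.**  Parents follow a one-compartment model with first-order
absorption (Bateman):

    Cp(t) = S·D·ka / (V·(ka − ke)) · (e^(−ke·t) − e^(−ka·t))

with dose D (mg), absorption and elimination constants ka, ke (1/h),
apparent volume V (L), and a dimensionless scale S folding
bioavailability and unit conversion.  Metabolites obey formation-limited
one-compartment kinetics, dCm/dt = s·fm·ke·Cp − km·Cm with Cm(0) = 0,
where fm ∈ [0,1] is the formation fraction and s a single constant
folding the parent:metabolite volume ratio; the closed-form solution is
used everywhere and is verified against a stiff ODE integration in the
tests.  Coincident rate constants are separated by a relative 1e−9
jitter.  AUCs of both curves have closed forms, which provide the
noise-free ground-truth metrics returned alongside each simulated
dataset.

**Calibration.**  Typical ka/ke/V per probe were fixed at
textbook-magnitude values for each drug; S (and the metabolite fold s and
km) were then solved analytically, once, so the typical subject's
AUC(0–12h) and metabolic ratios land on the published cohort medians
(caffeine ≈ 1135 ng·h/mL, fexofenadine ≈ 60, midazolam ≈ 1.1,
metoprolol ratio ≈ 0.64, omeprazole ratio ≈ 0.37).  The resulting
constants live in `data/default_population.yaml` and are versioned; a
simulated cohort's medians bracket the published values (asserted at the
calibration seed, 42).

**Variability.**  Subject parameters are lognormal around the typical
values: CV 40% on S (AUC spread), 20–25% on ka/ke, 15% on km, and 60% on
fm for the ratio probes — the formation fraction carries the wide
(>5-fold) enzyme-activity range that makes the metabolic ratio a useful
phenotype, and it cancels identically from neither the per-time ratio
nor the AUC ratio, which is what lets single-sample ratio models work.
fm draws are capped at 0.95.  Phase 2 reuses each subject's parameters
with a 10% inter-occasion CV on S and fresh residual noise.  Residual
error is proportional (CV 10%) plus additive (SD = 0.5 × LLOQ),
truncated at zero.  LLOQ censoring is flag-only: values are retained and
the `blq` flag drives the admissibility rule, so the downstream policy
stays in the selection module.  Default LLOQs are set at realistic assay
floors for each analyte; with the calibrated kinetics they typically
disqualify the pre-dose, absorption-phase and late terminal samples,
reproducing a mid-profile (≈60–300 min) admissible window.  An optional
"poor metabolizer" subject sets fm = 0.02 for metoprolol, driving α-OH
metoprolol below LLOQ in most samples.

**What the synthetic cohort does not emulate** — and hence what passing
tests do not establish about real data: no multi-compartment or
enterohepatic kinetics, no absorption lag, no correlation between a
subject's enzyme activity and the parent drug's own clearance (real
CYP2D6 variation widens the metoprolol parent AUC far more than this
generator does), no assay batch effects, and no dropout or missing
samples.  Consequently single-point models for the AUC probes can
perform better here than in real cohorts; the regime assertions in the
tests are therefore one-sided (2-point AUC models and 1-point ratio
models must fit well) rather than claims that fewer samples must fail.

## Numerical conventions

* Times are minutes everywhere in data files; rate constants are per
  hour and the minutes→hours factor (60) is applied exactly once, inside
  `trapezoid_auc` and the kinetic closed forms.  AUCs are ng·h/mL.
* OLS uses a QR-based least-squares solve with an explicit intercept
  column; designs are rejected as rank-deficient (naming the offending
  constant/duplicate time columns) when the augmented matrix loses rank.
  Training R² is clamped to [0, 1] and defined as 0 for a constant
  response.
* R² ties during ranking are resolved at a 1e−10 tolerance.
* Sample SD (n−1) is used for every "± SD" and for Bland–Altman limits.
* Simulated cohorts, and therefore the whole pipeline, are reproducible
  byte-for-byte from a single integer seed; one `numpy` Generator is
  consumed in a fixed traversal order (subject → probe → phase).

## Problem sizes in the test suite

Unit and property tests run on cohorts of 2–16 subjects.  The optimism-
ordering check uses 100 seeded 16-subject replicates of a single-probe
design; the all-subsets oracle checks 50 random instances (8–16
subjects, k ≤ 3).  The full suite completes in well under a minute on a
single core, and the acceptance script's complete pipeline run takes a
few seconds.

## Known limitations

* The registry stores the published equations and statistics verbatim,
  including internal inconsistencies between the source tables (the same
  nominal model can carry slightly different MD%/MAD% in the training
  and jack-knife tables); the package surfaces both with their table of
  origin and does not attempt to reconcile them.
* The ANOVA across candidate model sets treats per-probe R² values as
  independent replicates, an interpretation (consistent with error-bar
  reporting across probes) rather than a derivation.
* The published per-analyte record accounting ("1,320 points for LSS
  development") does not factor evenly into the stated design; the
  generator reports raw record counts (16·14·7·2 = 3,136) and makes no
  attempt to reproduce that figure.
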