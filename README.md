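# cocktail-lss

Limited-sampling-strategy (LSS) modelling for CYP/ABCB1 phenotyping-cocktail
studies.

## The problem

Phenotyping cocktails give subjects simultaneous sub-therapeutic doses of
enzyme- and transporter-selective probe drugs (caffeine for CYP1A2,
metoprolol for CYP2D6, midazolam for CYP3A, omeprazole for CYP2C19,
fexofenadine for ABCB1) and read enzyme/transporter activity off a
pharmacokinetic metric: the probe's AUC(0–12h), or the parent:metabolite
AUC(0–12h) ratio for metoprolol (α-OH metoprolol) and omeprazole
(5-OH omeprazole).  Computing those "best estimates" requires a full
14-sample, 12-hour profile per subject — impractical in routine use.  A
limited sampling strategy replaces the full profile with a linear equation
over one to three timed samples:

    AUC(0–12h)  =  A0 + A1·C(t1) + A2·C(t2) + … + An·C(tn)

(with per-time parent:metabolite concentration *ratios* replacing raw
concentrations for the ratio-metric probes).  This package implements the
full development and validation workflow for such equations:

* **Non-compartmental best estimates** — linear-trapezoidal AUC(0–12h) and
  AUC ratios from the complete profiles.
* **All-subsets regression** — exhaustive OLS over every size-k subset of
  the candidate sampling times, ranked by training R².
* **Candidate-time admissibility** — times where any analyte is below the
  quantification limit (BLQ) in any subject are disqualified, so the
  shared schedule works for every probe at once; cross-probe model sets
  are ranked by mean ± SD of per-probe R² and compared by one-way ANOVA.
* **Validation** — frozen-coefficient application to a second study phase,
  jack-knife (leave-one-subject-out) refitting, bias (MD%) and precision
  (MAD%) statistics, and Bland–Altman limits of agreement.
* **Published-equation registry** — the published training and validation
  equations for this cocktail, stored verbatim as a checksummed fixture
  and applicable, frozen, to any compatible dataset.
* **Synthetic study generator** — because the underlying trial's raw
  concentrations are unpublished, a seeded simulator reproduces its
  structure (16 subjects × 2 phases × 14 times × 7 analytes) from
  one-compartment Bateman kinetics with formation-limited metabolites,
  lognormal between-subject variability, assay noise and LLOQ censoring,
  returning analytic ground-truth metrics for recovery testing.

## Worked example

```python
from cocktail_lss import (load_population, default_design, simulate_cohort,
    best_estimates, predictor_matrix, enumerate_and_rank, jackknife_validate,
    admissible_times)

population = load_population()                     # packaged calibration
design = default_design(population)                # 16 subjects, 14 times
sim = simulate_cohort(design, population, seed=42)

metrics = best_estimates(sim.dataset, phase=1)     # trapezoidal AUCs / ratios
times = [t for t in admissible_times(sim.dataset, phase=1) if 60 <= t <= 300]
print("candidate times:", times)

y = metrics[metrics.probe == "caffeine"].set_index("subject_id")["value"]
X = predictor_matrix(sim.dataset, "caffeine", phase=1, times=times)
best = enumerate_and_rank(X, y, k=2, probe="caffeine", metric_kind="auc")[0]
print(f"best 2-point caffeine model: times={best.sampling_times} "
      f"A0={best.intercept:.2f} A=({best.coefficients[0]:.3f}, "
      f"{best.coefficients[1]:.3f}) R2={best.training_r2:.3f}")

jk = jackknife_validate(sim.dataset, "caffeine", best.sampling_times, phase=1)
ev = jk.evaluation
print(f"jack-knife: r2={ev.r2:.3f} MD%={ev.md_pct_mean:.2f}+/-{ev.md_pct_sd:.2f} "
      f"MAD%={ev.mad_pct_mean:.2f}+/-{ev.mad_pct_sd:.2f}")
```

prints

```
candidate times: [60, 90, 120, 180, 240]
best 2-point caffeine model: times=(120, 240) A0=-57.27 A=(4.596, 3.916) R2=0.996
jack-knife: r2=0.992 MD%=0.12+/-7.03 MAD%=5.45+/-4.22
```

Reading: with BLQ-driven exclusion of the absorption-phase and terminal
samples, the admissible window is 60–240 min; the best two-sample caffeine
equation uses the 120- and 240-min concentrations and explains 99.6% of
the between-subject variance in AUC(0–12h).  Leave-one-out refitting —
where no subject influences the coefficients used for its own prediction —
keeps r² at 0.99 with essentially no bias (MD% ≈ 0.1%) and ~5% mean
absolute error.

The same workflow is scriptable from the shell:

```bash
lss-cocktail run --seed 42 --out results/run42     # full pipeline
lss-cocktail simulate --seed 42 --out data/        # individual stages
lss-cocktail nca --in data/cocktail_data.csv --out metrics.csv
lss-cocktail apply --in data/cocktail_data.csv --out published.csv
```

## Layout

```
src/cocktail_lss/
  simulate.py    # synthetic cocktail-study generator + kinetic closed forms
  nca.py         # trapezoidal AUC, metabolic ratios, best estimates
  lss.py         # OLS fitting, all-subsets enumeration, prediction, MD%/MAD%
  selection.py   # BLQ admissibility, cross-probe ranking, ANOVA
  validation.py  # external + jack-knife validation, Bland–Altman, plots
  registry.py    # published-equation fixture and frozen application
  pipeline.py    # end-to-end orchestration with manifest
  cli.py         # `lss-cocktail` command group
  data/          # published_models.csv, default_population.yaml
```

See `docs/methods.md` for the model assumptions, the generator's
calibration and what the synthetic cohort does and does not emulate.
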