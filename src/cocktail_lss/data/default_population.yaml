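# Default synthetic-population calibration, schema_version 1.
#
# Typical kinetic values per probe were fixed from textbook-scale kinetics
# for each drug at sub-therapeutic cocktail doses; bioavail_scale (which
# folds bioavailability and unit conversion) and metab_scale (metabolite
# volume fold) were then solved once, analytically, so that the typical
# subject's AUC(0-12h) and parent:metabolite AUC ratios land on the
# published cohort medians.  Between-subject CVs are lognormal; metabolic
# ratio variability is carried chiefly by fm, emulating wide (>5-fold)
# enzyme-activity ranges across subjects.
schema_version: 1
probes:
  caffeine:
    dose_mg: 10.0
    typical:
      bioavail_scale: 710.9
      ka_per_h: 3.0
      ke_per_h: 0.14
      vd_f_l: 36.0
    bsv_cv:
      bioavail_scale: 0.40
      ka: 0.20
      ke: 0.25
    lloq_ng_ml:
      caffeine: 5.0
  fexofenadine:
    dose_mg: 10.0
    typical:
      bioavail_scale: 408.2
      ka_per_h: 0.8
      ke_per_h: 0.20
      vd_f_l: 300.0
    bsv_cv:
      bioavail_scale: 0.40
      ka: 0.20
      ke: 0.25
    lloq_ng_ml:
      fexofenadine: 1.0
  midazolam:
    dose_mg: 0.2
    typical:
      bioavail_scale: 199.0
      ka_per_h: 4.0
      ke_per_h: 0.45
      vd_f_l: 80.0
    bsv_cv:
      bioavail_scale: 0.40
      ka: 0.20
      ke: 0.25
    lloq_ng_ml:
      midazolam: 0.02
  metoprolol:
    dose_mg: 10.0
    typical:
      bioavail_scale: 112.2
      ka_per_h: 1.5
      ke_per_h: 0.20
      vd_f_l: 250.0
      fm: 0.40
      km_per_h: 0.25
      metab_scale: 6.127
    bsv_cv:
      bioavail_scale: 0.40
      ka: 0.20
      ke: 0.15
      km: 0.15
      fm: 0.60
    lloq_ng_ml:
      metoprolol: 0.2
      alpha_oh_metoprolol: 0.2
  omeprazole:
    dose_mg: 2.0
    typical:
      bioavail_scale: 232.9
      ka_per_h: 2.5
      ke_per_h: 0.90
      vd_f_l: 25.0
      fm: 0.50
      km_per_h: 0.50
      metab_scale: 3.005
    bsv_cv:
      bioavail_scale: 0.40
      ka: 0.20
      ke: 0.15
      km: 0.15
      fm: 0.60
    lloq_ng_ml:
      omeprazole: 0.1
      5_oh_omeprazole: 0.2
error_model:
  proportional_cv: 0.10
  additive_sd_lloq_frac: 0.5
  iov_cv: 0.10
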