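# cocktail-lss published limited-sampling model registry, schema=1
# Coefficients transcribed from the source publication's training-set
# (Table2) and external-validation (Table3) tables; unicode minus signs
# normalized to ASCII hyphen-minus at authoring time.  Table3 rows reuse
# the frozen Table2 equations (validation never refits); their reported_*
# columns carry the validation-set statistics.
probe,metric_kind,source_table,sampling_times,intercept,coefficients,reported_r2,reported_md_mean,reported_md_sd,reported_mad_mean,reported_mad_sd
caffeine,auc,Table2,90;240,-59.306,3.030;5.699,0.93,1.48,13.67,11.81,6.37
caffeine,auc,Table2,120;240,86.649,1.372;7.018,0.88,3.78,16.04,12.99,9.61
caffeine,auc,Table2,90;120;240,-64.496,2.969;0.458;5.193,0.93,1.54,13.63,11.49,6.89
fexofenadine,auc,Table2,90;240,-5.830,2.614;4.818,0.96,0.35,8.39,7.08,4.13
fexofenadine,auc,Table2,120;240,-2.789,2.076;5.041,0.90,1.59,11.99,9.66,6.85
fexofenadine,auc,Table2,90;120;240,-6.422,2.248;0.454;4.792,0.96,0.29,8.13,6.82,4.07
midazolam,auc,Table2,90;240,-0.113,2.091;6.445,0.97,0.38,10.91,8.56,6.41
midazolam,auc,Table2,120;240,-0.081,4.710;0.720,0.94,1.74,13.31,11.51,6.25
midazolam,auc,Table2,90;120;240,-0.114,2.069;0.061;6.365,0.97,0.37,10.86,8.54,6.36
metoprolol,auc_ratio,Table2,120,-0.026,0.7416,0.98,-2.06,12.33,9.57,7.63
metoprolol,auc_ratio,Table2,90;240,0.024,0.063;0.783,0.99,-1.64,13.49,9.55,9.34
metoprolol,auc_ratio,Table2,120;240,0.006,0.296;0.518,1.00,-2.22,9.27,6.39,6.89
metoprolol,auc_ratio,Table2,90;120;240,0.026,-0.107;0.394;0.518,1.00,-0.54,7.45,5.26,5.12
omeprazole,auc_ratio,Table2,120,0.041,0.8880,0.96,2.93,16.46,16.57,17.86
omeprazole,auc_ratio,Table2,90;240,0.100,0.272;0.7499,0.92,6.77,28.62,20.11,20.90
omeprazole,auc_ratio,Table2,120;240,0.044,0.849;0.055,0.96,3.13,16.89,11.96,11.96
omeprazole,auc_ratio,Table2,90;120;240,0.021,-0.655;1.974;-0.401,0.98,1.52,12.15,9.48,7.36
caffeine,auc,Table3,90;240,-59.306,3.030;5.699,0.95,3.60,16.11,11.88,11.08
caffeine,auc,Table3,120;240,86.649,1.372;7.018,0.96,9.12,11.53,11.39,9.13
fexofenadine,auc,Table3,90;240,-5.830,2.614;4.818,0.94,2.04,11.29,8.69,7.16
fexofenadine,auc,Table3,120;240,-2.789,2.076;5.041,0.88,5.44,12.19,10.29,8.20
midazolam,auc,Table3,90;240,-0.113,2.091;6.445,0.81,5.63,17.83,16.02,8.83
midazolam,auc,Table3,120;240,-0.081,4.710;0.720,0.73,0.49,22.62,14.67,16.80
metoprolol,auc_ratio,Table3,120,-0.026,0.7416,0.97,0.24,12.98,11.42,5.36
metoprolol,auc_ratio,Table3,90;240,0.024,0.063;0.783,0.97,5.12,11.79,10.73,6.60
metoprolol,auc_ratio,Table3,120;240,0.006,0.296;0.518,0.98,3.68,10.42,8.40,6.89
omeprazole,auc_ratio,Table3,120,0.041,0.8880,0.91,-4.48,17.13,13.85,10.51
omeprazole,auc_ratio,Table3,90;240,0.100,0.272;0.7499,0.89,-0.14,29.55,21.61,19.36
omeprazole,auc_ratio,Table3,120;240,0.044,0.849;0.055,0.91,-4.20,17.78,14.17,11.00
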