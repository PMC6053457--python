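{
  "comment": "Published ANOVA entries as printed; df 4/22 is inconsistent with a 15-coefficient model on 27 runs (14/12) and the residual SS is inconsistent with the published residual column, but derived quantities (MS, F, R^2) are reproducible as arithmetic from these SS/df.",
  "ss_regression": 4.445999,
  "df_regression": 4,
  "ms_regression": 1.1115,
  "ss_residual": 0.502399,
  "df_residual": 22,
  "ms_residual": 0.022836,
  "ss_total": 4.948399,
  "f_statistic": 48.67242,
  "r_squared": 0.89847
}
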