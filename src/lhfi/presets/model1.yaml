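# Distance downstream as the single health covariate.
name: model1
health_covariates: [dd]
two_level: false
metric_cov_structure: iid
b_bivariate: false
month_specific_variance: false
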