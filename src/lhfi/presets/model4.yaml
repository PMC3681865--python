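# As model3, with a correlated bivariate prior on (b0, b1).
name: model4
health_covariates: [salinity]
two_level: true
metric_cov_structure: iid
b_bivariate: true
month_specific_variance: false
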