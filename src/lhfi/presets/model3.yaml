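# Two-level: salinity regressed on distance downstream; health on salinity.
name: model3
health_covariates: [salinity]
two_level: true
metric_cov_structure: iid
b_bivariate: false
month_specific_variance: false
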