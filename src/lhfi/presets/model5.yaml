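# Two-level plus log-depth, log-silt-clay and their interaction.
name: model5
health_covariates: [log_depth, log_sc, "log_depth:log_sc", salinity]
two_level: true
metric_cov_structure: iid
b_bivariate: false
month_specific_variance: false
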