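# Published piecewise HbA1c correction coefficients.
# SHORT applies for RBC lifespan <= 66 days, MID for 67-89 days;
# lifespans >= 90 days are left uncorrected.
format = glyspan-models-1
short.beta_lifespan = -0.05629
short.beta_hba1c = 1.127
short.intercept = 3.178
short.multiple_r = 0.7360
mid.beta_lifespan = -0.004772
mid.beta_hba1c = 0.7569
mid.intercept = 2.394
mid.multiple_r = 0.7344
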