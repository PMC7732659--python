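# 2-week social-media-ostracism design with the fitted generative values:
# 53 persons, two daily baseline prompts, Poisson event arrivals, and the
# multilevel model's estimated fixed effects and random-effect SDs.
windows = 10:00-16:00,16:00-22:00
n_days = 14
n_persons = 53
beta_baseline = 13.5
beta_single = 7.0
beta_group = 11.5
sd_intercept = 3.29
sd_single_slope = 5.43
sd_group_slope = 8.88
residual_sd = auto      # calibrated so the null-model ICC is target_icc
target_icc = 0.089
rate_single = 1.34
rate_group = 0.34
response_prob = 0.594
seed = 0
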