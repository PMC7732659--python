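# 4-week angle-estimation field design: three daily prompts, 28 days.
windows = 08:00-11:00,11:00-14:00,14:00-17:00
n_days = 28
n_persons = 8
rate_single = 0
rate_group = 0
response_prob = 1.0
seed = 0
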