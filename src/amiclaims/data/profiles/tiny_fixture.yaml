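# 20-person unit-test profile: same structure as the calibrated profile
# but with a very high case rate so a handful of index events exist, and
# lighter background noise.
n_persons: 20
years: [2014, 2017]
annual_ami_rate_per_1000: 150
background_dx_rate: 1.0
background_drug_rate: 0.3
background_proc_rate: 0.3
enrollment_gap_prob: 0.1
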