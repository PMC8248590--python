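# Calibrated study-conditions profile.
#
# All marginals are the GeneratorConfig defaults, which encode the
# published descriptive frequencies this package characterizes: annual AMI
# diagnosis rate ~3/1,000 enrollees, inpatient share 63.4% of index
# settings, case age-bin mixture with 44.9% aged 65+, 61.4% male cases,
# per-code concurrent-diagnosis marginals, cardiac drug-class ordering
# (beta-blocker > anti-lipid > anti-platelet), EKG any-code rate 79.0%,
# 9.3% of 2015 cases carrying both ICD versions, and inpatient
# length-of-stay band probabilities 0.699 / 0.178 / 0.054 / 0.069.
n_persons: 200000
years: [2014, 2017]
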