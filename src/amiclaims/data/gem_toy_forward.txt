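# Synthetic toy ICD-9-CM -> ICD-10-CM GEM fixture (whitespace-separated:
# source, target, 5-digit flags: approximate/no-map/combination/scenario/choice).
# Covers the AMI code family at desk scale; not a CMS release.
41000 I2109 10000
41001 I2119 10000
41010 I2101 10000
41011 I2101 10000
41020 I2111 10000
41021 I2111 10000
41030 I2121 10000
41031 I2121 10000
41040 I2129 10000
41041 I2129 10000
41050 I2129 10000
41051 I2129 10000
41060 I214 10000
41061 I214 10000
41070 I214 10000
41071 I214 10000
41080 I2129 10000
41081 I2129 10000
41090 I213 10000
41091 I219 10000
41092 I220 10000
4109 I219 10000
412 I252 10000
4139 I209 10000
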