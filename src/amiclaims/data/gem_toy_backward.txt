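# Synthetic toy ICD-10-CM -> ICD-9-CM GEM fixture (whitespace-separated:
# source, target, 5-digit flags). Includes a round-trip discovery (I219 ->
# 4109, I220 -> 41092) and a no-map placeholder line; not a CMS release.
I2101 41011 10000
I2109 41001 10000
I2111 41021 10000
I2119 41001 10000
I2121 41031 10000
I2129 41041 10000
I213 41090 10000
I214 41071 10000
I219 41091 10000
I219 4109 10000
I219 41092 10000
I220 41092 10000
I221 41092 10000
I228 41092 10000
I229 41092 10000
I252 412 10000
I209 4139 10000
I21A1 NODX 11000
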