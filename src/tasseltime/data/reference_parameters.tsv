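parameter	value
alpha1	0.002000
alpha2	6.489431
alpha3	53.204799
beta	0.821720
omega	0.086782
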