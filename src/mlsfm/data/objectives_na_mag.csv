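magnification,numerical_aperture
1,0.06
2,0.11
4,0.20
10,0.45
20,0.80
40,1.15
60,1.42
100,1.45
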