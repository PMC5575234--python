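# fractional Nyquist frequency, value
# smooth parametric stand-in shaped like a counting direct detector
0.000,0.85000
0.050,0.84661
0.100,0.83651
0.150,0.81994
0.200,0.79730
0.250,0.76911
0.300,0.73600
0.350,0.69871
0.400,0.65802
0.450,0.61476
0.500,0.56977
0.550,0.52387
0.600,0.47782
0.650,0.43235
0.700,0.38809
0.750,0.34558
0.800,0.30528
0.850,0.26753
0.900,0.23258
0.950,0.20058
1.000,0.17161
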