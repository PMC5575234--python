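# fractional Nyquist frequency, value
# smooth parametric stand-in shaped like a counting direct detector
0.000,1.00000
0.050,0.99700
0.100,0.98807
0.150,0.97336
0.200,0.95313
0.250,0.92774
0.300,0.89763
0.350,0.86329
0.400,0.82531
0.450,0.78427
0.500,0.74082
0.550,0.69559
0.600,0.64921
0.650,0.60230
0.700,0.55544
0.750,0.50916
0.800,0.46394
0.850,0.42021
0.900,0.37833
0.950,0.33858
1.000,0.30119
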