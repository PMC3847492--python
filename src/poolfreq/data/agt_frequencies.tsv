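haplotype	frequency
1111011000	0.033
1101011110	0.016
1101001001	0.017
1001011001	0.017
1101011001	0.017
1111011101	0.507
0101100111	0.017
1100001111	0.033
0101001111	0.1
1101011111	0.193
1111111111	0.05
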