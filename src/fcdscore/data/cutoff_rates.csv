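cutoff,rate_a,rate_b,youden_printed
0,1.00,0.00,0.00
1,1.00,0.07,0.07
2,1.00,0.31,0.31
3,0.91,0.72,0.63
4,0.82,0.93,0.75
5,0.45,1.00,0.45
6,0.09,1.00,0.09
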