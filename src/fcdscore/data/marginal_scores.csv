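score,count
0,2
1,7
2,13
3,7
4,6
5,4
6,1
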