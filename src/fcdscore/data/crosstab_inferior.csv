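obs2_score,obs1_0,obs1_1,obs1_2,obs1_3
0,7,3,0,0
1,1,15,1,0
2,0,2,8,0
3,0,0,1,2
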