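case,kind,lateral_score,inferior_score
1,false_positive,2,1
2,false_positive,1,1
3,false_negative,3,1
4,false_negative,2,2
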