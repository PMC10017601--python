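wall,score,control_n,control_pct,fcd_n,fcd_pct
lateral,0,0,0.0,2,6.9
lateral,1,1,9.1,22,75.9
lateral,2,4,36.4,3,10.3
lateral,3,6,54.5,2,6.9
inferior,0,0,0.0,10,34.5
inferior,1,4,36.4,15,51.7
inferior,2,5,45.5,4,13.8
inferior,3,2,18.2,0,0.0
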