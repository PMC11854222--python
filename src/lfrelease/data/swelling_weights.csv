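t_h,y,sd
0,0.35,0.01
1,0.75,0.02
3,0.80,0.07
5,1.08,0.02
24,1.60,0.02
48,1.62,0.02
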