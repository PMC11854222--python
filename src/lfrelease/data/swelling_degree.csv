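sample,t_h,q_percent,sd
ALG,1,185.3,2.8
ALG,3,265.1,8.2
ALG,5,442.1,7.8
ALG,24,562.0,4.1
ALG,48,586.4,4.5
ALG:Lf,1,112.4,5.9
ALG:Lf,3,129.5,7.2
ALG:Lf,5,190.5,21.4
ALG:Lf,24,338.1,7.2
ALG:Lf,48,326.7,5.9
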