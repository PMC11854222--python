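batch,ee_percent
B1,55.4
B2,62.6
B3,78.1
B4,67.9
B5,64.8
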