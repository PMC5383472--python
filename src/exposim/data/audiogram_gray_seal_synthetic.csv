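frequency_khz,threshold_db
0.1,96
0.25,84
0.5,77
1.0,71
2.0,67
4.0,63
10.0,60
20.0,60
30.0,64
50.0,78
60.0,95
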