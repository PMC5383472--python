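frequency_khz,threshold_db
0.25,104
0.5,92
1.0,80
2.0,71
4.0,64
8.0,57
16.0,50
31.5,45
63.0,38
100.0,33
125.0,40
140.0,58
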