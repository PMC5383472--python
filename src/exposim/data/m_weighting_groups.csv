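functional_group,f_low_khz,f_high_khz
low-frequency cetacean,0.007,22
mid-frequency cetacean,0.15,160
high-frequency cetacean,0.2,180
pinniped-in-water,0.075,75
pinniped-in-air,0.075,30
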