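functional_group,pts_sel_db,tts_sel_db
low-frequency cetacean,215,195
mid-frequency cetacean,215,195
high-frequency cetacean,215,195
pinniped-in-water,203,183
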