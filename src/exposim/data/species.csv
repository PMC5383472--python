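name,functional_group,audiogram_file,swim_speed_typical_ms,swim_speed_max_ms,max_dive_depth_m,typical_dive_duration_s,surface_time_s,heading_sd_natural,responds_to_noise
gray seal,pinniped-in-water,audiogram_gray_seal_synthetic.csv,1.5,3.0,300,300,120,0.5,true
harbor porpoise,high-frequency cetacean,audiogram_harbor_porpoise_synthetic.csv,1.4,4.0,200,120,60,0.5,true
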