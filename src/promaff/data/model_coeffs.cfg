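# Frozen coefficients for -ln K_D (K_D in nM), ordinary least
# squares on the 173 packaged sequence anchors;
# sigma0 from the median |delta ln K_D|/Z of 87 anchor pairs.
# tables hash 5c25402d7471ed10
a0 = 14.568618005583023
a_pwm = 0.31631088667612872
a_slide = 6.9395584154428258
a_bend = -0.59913560259870924
resid_sd = 0.90509821877558083
sigma0 = 0.05780123759107085
provenance = calibrated
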