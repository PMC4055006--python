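velocity_mm_per_s,ce_mean_pct,ce_sd_pct,n,source
4,85.0,3.6,3,Fig 4C
20,68.7,4.7,3,Fig 4C
100,11.3,4.5,3,Fig 4C
500,1.6,0.75,3,Fig 4C
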