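group,mean_per_mm2,sd_per_mm2,n,source
PBS,917,137,6,"Results, angiogenesis"
NonMag,1200,85,6,"Results, angiogenesis"
Mag,1558,166,6,"Results, angiogenesis"
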