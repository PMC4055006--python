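group,mean_ratio,sd_ratio,n,source
Mag,0.61,0.06,6,"Results, cardiac MRI"
NonMag,0.88,0.08,6,"Results, cardiac MRI"
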