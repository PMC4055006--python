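group,mean_photon_per_s,sd_photon_per_s,n,source
Mag,26222,5102,6,"Results, fluorescence imaging"
NonMag,9620,1930,6,"Results, fluorescence imaging"
PBS,6155,953,6,"Results, fluorescence imaging"
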