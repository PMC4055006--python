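group,region,mean_cells_per_field,sd_cells_per_field,n,source
Mag,anterior,25.8,4.7,6,"Results, Prussian blue staining"
NonMag,anterior,8.5,1.98,6,"Results, Prussian blue staining"
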