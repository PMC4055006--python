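quantity,value,unit,n,source
retention_fold_mag_vs_nonmag_24h,2.87,fold,6,"Results, SRY qPCR"
infused_cells,1e6,cells,6,Methods
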