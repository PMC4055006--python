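quantity,mean,sd,low,high,unit,source
iron_per_cell,21.77,3.62,0,,pg,"Results, characterization"
cell_diameter,19.3,,6,36,um,"Results, characterization"
spio_particle_diameter,0.062,,,,um,Methods
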