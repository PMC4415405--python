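name,molecular_weight_kda,hydrodynamic_radius_nm,flexibility,hydrophobicity,isoelectric_point
dextran10,10,2.3,flexible,hydrophilic,
dextran70,70,6,flexible,hydrophilic,
dextran155,155,8.5,flexible,hydrophilic,
BSA,66.4,3.65,rigid,hydrophobic,5.0
lactoferrin,77,2.2,rigid,hydrophobic,8.5
alpha_s1_casein,23.6,2.9,flexible,amphiphile,4.94
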