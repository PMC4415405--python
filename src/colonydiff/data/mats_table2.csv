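strain,solvent,adhesion_percent_mean,adhesion_percent_sd,n
LD61,hexadecane,8.6,5.2,4
LD61,chloroform,11.3,9.8,3
TIL1230,hexadecane,12.8,5.3,6
TIL1230,chloroform,13.7,2.5,5
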