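gene_id,k_light_per_h,k_dark_per_h,orf_length_codons
LHY,0.40,0.25,645
CCA1,0.40,0.25,608
PRR9,0.45,0.80,468
PRR7,0.30,0.50,727
PRR5,0.30,0.70,558
TOC1,0.35,0.50,618
GI,0.30,0.40,1173
ELF3,0.20,0.45,695
ELF4,0.30,0.50,111
LUX,0.30,0.30,323
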