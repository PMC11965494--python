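regulator,target,parameter,kd_copies_per_cell,kd_nM,kd_per_chip_peak_nM,protein,target_gene,ema_kd_nM
cEC,cE4m,g2,596,8.6,0.18,LUX,ELF4,1.68
cEC,cGm,g14,206,3.0,0.06,LUX,GI,2.49
cEC,cP9m,g8,408,5.9,0.12,LUX,PRR9,2.54
cEC,cTm,g4,451,6.5,0.14,LUX,TOC1,3.17
cL,cE3m,g16,28141,408,0.26,CCA1,ELF3,
cL,cE4m,g6,24508,355,0.23,CCA1,ELF4,0.25
cL,cGm,g15,42247,612,0.40,CCA1,GI,0.58
cL,cLUXm,g6,24508,355,0.23,CCA1,LUX,0.34
cL,cP9m,g9,33342,483,0.31,CCA1,PRR9,0.32
cL,cTm,g5,20979,304,0.20,CCA1,TOC1,0.41
cL+cLmod,cP7m,g10,67505,978,0.63,CCA1,PRR7,0.32
cLmod,cP5m,g12,16905,245,0.16,RVE8 etc.,PRR5,
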