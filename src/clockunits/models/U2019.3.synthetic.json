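{
 "kd_map": [
  {
   "parameter": "g2",
   "regulator": "cEC",
   "target": "cE4m"
  },
  {
   "parameter": "g14",
   "regulator": "cEC",
   "target": "cGm"
  },
  {
   "parameter": "g8",
   "regulator": "cEC",
   "target": "cP9m"
  },
  {
   "parameter": "g4",
   "regulator": "cEC",
   "target": "cTm"
  },
  {
   "parameter": "g16",
   "regulator": "cL",
   "target": "cE3m"
  },
  {
   "parameter": "g6",
   "regulator": "cL",
   "target": "cE4m"
  },
  {
   "parameter": "g15",
   "regulator": "cL",
   "target": "cGm"
  },
  {
   "parameter": "g6",
   "regulator": "cL",
   "target": "cLUXm"
  },
  {
   "parameter": "g9",
   "regulator": "cL",
   "target": "cP9m"
  },
  {
   "parameter": "g5",
   "regulator": "cL",
   "target": "cTm"
  },
  {
   "parameter": "g10",
   "regulator": "cL+cLmod",
   "target": "cP7m"
  },
  {
   "parameter": "g12",
   "regulator": "cLmod",
   "target": "cP5m"
  }
 ],
 "notes": "SYNTHETIC reconstruction of the U2019 circuit architecture (activation-based daytime regulation): wiring, naming and scaling scheme follow the published model family, parameter values are this package's own and are non-canonical.",
 "parameters": {
  "a1": 0.4,
  "g1": 30.0,
  "g10": 15.0,
  "g12": 25.0,
  "g14": 35.0,
  "g15": 30.0,
  "g16": 40.0,
  "g17": 20.0,
  "g2": 10.0,
  "g4": 25.0,
  "g5": 25.0,
  "g6": 35.0,
  "g8": 30.0,
  "g9": 30.0,
  "m1": 1.0,
  "m10": 0.6,
  "m11D": 0.3,
  "m11L": 0.35,
  "m12": 0.65,
  "m13": 0.6,
  "m14D": 0.5,
  "m14L": 0.2,
  "m15D": 0.25,
  "m15L": 1.0,
  "m16": 0.7,
  "m17D": 0.5,
  "m17L": 0.3,
  "m18": 0.65,
  "m19": 0.35,
  "m2D": 0.35,
  "m2L": 0.5,
  "m3": 0.15,
  "m4": 1.0,
  "m5D": 0.8,
  "m5L": 0.45,
  "m6": 0.6,
  "m7D": 0.45,
  "m7L": 0.25,
  "m8": 0.4,
  "m9D": 0.7,
  "m9L": 0.25,
  "mAR": 0.1,
  "n1": 25.0,
  "n2": 40.0,
  "n3": 50.0,
  "n4": 40.0,
  "n5": 35.0,
  "n6": 50.0,
  "n7": 30.0,
  "n8": 40.0,
  "n9": 45.0,
  "nAR": 1.0,
  "p1": 1.0,
  "p2": 0.15,
  "p3": 0.5,
  "p4": 0.6,
  "p5": 0.6,
  "p6": 0.7,
  "p7": 0.4,
  "p8": 0.5,
  "p9": 0.5,
  "q1": 15.0,
  "qAR": 2.0,
  "s_L": 1.0,
  "s_LUX": 1.0,
  "s_P7": 1.0
 },
 "pools": {
  "EC": [
   "cEC"
  ],
  "ELF3": [
   "cE3",
   "cEC"
  ],
  "ELF4": [
   "cE4",
   "cEC"
  ],
  "LHY/CCA1": [
   "cL"
  ],
  "LUX": [
   "cLUX",
   "cEC"
  ],
  "PRR5": [
   "cP5"
  ],
  "PRR7": [
   "cP7"
  ],
  "PRR9": [
   "cP9"
  ],
  "TOC1": [
   "cT"
  ]
 },
 "rates": {
  "cAR": "nAR*(1-L) - (mAR + qAR*L)*cAR",
  "cE3": "s_LUX*p7*cE3m - (m14L*L + m14D*(1-L))*cE3",
  "cE3m": "n7*(s_L*g16)**2/((s_L*g16)**2 + (cL)**2) - m13*cE3m",
  "cE4": "s_LUX*p8*cE4m - (m17L*L + m17D*(1-L))*cE4",
  "cE4m": "n8*(s_L*g6)**2/((s_L*g6)**2 + (cL)**2)*(s_LUX*g2)**2/((s_LUX*g2)**2 + (cEC)**2) - m16*cE4m",
  "cEC": "a1*cLUX*(cE3)**2/((s_LUX*g17)**2 + (cE3)**2) - (m15L*L + m15D*(1-L))*cEC",
  "cGm": "n6*(0.2 + 0.8*L)*(s_L*g15)**2/((s_L*g15)**2 + (cL)**2)*(s_LUX*g14)**2/((s_LUX*g14)**2 + (cEC)**2) - m12*cGm",
  "cL": "s_L*p1*cLm - (m2L*L + m2D*(1-L))*cL",
  "cLUX": "s_LUX*p9*cLUXm - m19*cLUX - a1*cLUX*(cE3)**2/((s_LUX*g17)**2 + (cE3)**2)",
  "cLUXm": "n9*(s_L*g6)**2/((s_L*g6)**2 + (cL)**2) - m18*cLUXm",
  "cLm": "q1*L*cAR + n1*(s_P7*g1)**2/((s_P7*g1)**2 + (cP9 + cP7 + cP5 + cT)**2) - m1*cLm",
  "cLmod": "p2*cL - m3*cLmod",
  "cP5": "s_P7*p5*cP5m - (m9L*L + m9D*(1-L))*cP5",
  "cP5m": "n4*(0.3 + 0.7*L)*(cLmod)**2/((s_L*g12)**2 + (cLmod)**2) - m8*cP5m",
  "cP7": "s_P7*p4*cP7m - (m7L*L + m7D*(1-L))*cP7",
  "cP7m": "n3*(cLmod)**2/((s_L*g10)**2 + (cLmod)**2) - m6*cP7m",
  "cP9": "s_P7*p3*cP9m - (m5L*L + m5D*(1-L))*cP9",
  "cP9m": "n2*(0.05 + 0.95*L)*(cL)**2/((s_L*g9)**2 + (cL)**2)*(s_LUX*g8)**2/((s_LUX*g8)**2 + (cEC)**2) - m4*cP9m",
  "cT": "s_P7*p6*cTm - (m11L*L + m11D*(1-L))*cT",
  "cTm": "n5*(s_L*g5)**2/((s_L*g5)**2 + (cL)**2)*(s_LUX*g4)**2/((s_LUX*g4)**2 + (cEC)**2) - m10*cTm"
 },
 "reporters": {},
 "scale_factors": [
  "s_L",
  "s_P7",
  "s_LUX"
 ],
 "scaled_parameters": {
  "g1": "s_P7",
  "g10": "s_L",
  "g12": "s_L",
  "g14": "s_LUX",
  "g15": "s_L",
  "g16": "s_L",
  "g17": "s_LUX",
  "g2": "s_LUX",
  "g4": "s_LUX",
  "g5": "s_L",
  "g6": "s_L",
  "g8": "s_LUX",
  "g9": "s_L",
  "p1": "s_L",
  "p3": "s_P7",
  "p4": "s_P7",
  "p5": "s_P7",
  "p6": "s_P7",
  "p7": "s_LUX",
  "p8": "s_LUX",
  "p9": "s_LUX"
 },
 "species": {
  "cAR": 1.0,
  "cE3": 1.0,
  "cE3m": 1.0,
  "cE4": 1.0,
  "cE4m": 1.0,
  "cEC": 1.0,
  "cGm": 1.0,
  "cL": 1.0,
  "cLUX": 1.0,
  "cLUXm": 1.0,
  "cLm": 1.0,
  "cLmod": 1.0,
  "cP5": 1.0,
  "cP5m": 1.0,
  "cP7": 1.0,
  "cP7m": 1.0,
  "cP9": 1.0,
  "cP9m": 1.0,
  "cT": 1.0,
  "cTm": 1.0
 },
 "version": "U2019.3"
}
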