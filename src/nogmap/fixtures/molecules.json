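{
  "H2O": "water",
  "Pi": "phosphate",
  "F6P": "hkhhhp",
  "G6P": "khhhhp",
  "FBP": "pkhhhp",
  "G3P": "khp",
  "DHAP": "hkp",
  "DHA": "hkh",
  "E4P": "khhp",
  "Eu4P": "hkhp",
  "X5P": "hkhhp",
  "R5P": "khhhp",
  "S7P": "hkhhhhp",
  "SBP": "pkhhhhp",
  "XBP": "pkhhp",
  "Gly2P": "kp",
  "AcP": "ab",
  "AcH": "xb",
  "HPA": "xbh",
  "HPA-P": "abh",
  "formaldehyde": "k",
  "glycolaldehyde": "kh",
  "glyceraldehyde": "khh",
  "erythrose": "khhh",
  "erythrulose": "hkhh",
  "fructose": "hkhhhh",
  "glucose": "khhhhh"
}
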