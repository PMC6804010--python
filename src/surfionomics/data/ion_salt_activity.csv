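salt,laccase,xylanase,endoglucanase,cellobiohydrolase,beta_glucosidase
NH4F,12.34,141.68,109.84,126.50,135.70
NaH2PO4,37.56,146.81,99.06,100.10,141.80
MgCl2_6H2O,41.36,137.39,61.40,110.90,144.79
NH4Cl,43.39,155.04,23.44,103.80,138.54
CaCl2,43.07,147.14,120.15,119.30,144.23
KCl,42.72,148.24,140.31,109.50,146.57
LiCl,42.24,130.59,133.59,101.60,148.55
Na2SO4,29.41,181.60,110.78,137.30,152.23
MnCl2_4H2O,30.01,216.97,164.68,129.00,143.83
NaCl,38.20,175.46,134.68,129.70,150.57
KH2PO4,33.56,162.18,124.22,148.30,143.17
BaCl,34.04,139.41,123.43,144.30,143.57
ZnNO3_2,40.48,122.86,119.84,140.10,137.07
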