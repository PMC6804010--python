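ion,treatment,count,area_um2,average_size_um2
Li,Control,353,53.857,0.150
Li,SteamExplosion,88,0.054,0.027
Li,Microwave_H2SO4,63,0.027,0.027
Li,EtOH_DMSO_AO,320,30.879,0.097
Li,NaOH,16,4.569,0.286
Na,Control,71,349.574,6.221
Na,SteamExplosion,35,185.866,5.310
Na,Microwave_H2SO4,121,376.032,3.108
Na,EtOH_DMSO_AO,61,383.557,6.288
Na,NaOH,23,374.151,16.267
K,Control,19,432.026,26.729
K,SteamExplosion,50,254.450,5.089
K,Microwave_H2SO4,94,364.368,3.876
K,EtOH_DMSO_AO,38,387.346,10.193
K,NaOH,15,376.596,25.106
Mg,Control,144,249.479,2.058
Mg,SteamExplosion,107,116.690,1.091
Mg,Microwave_H2SO4,777,124.457,0.160
Mg,EtOH_DMSO_AO,570,105.242,0.185
Mg,NaOH,119,178.072,1.496
CaC3H4,Control,44,407.019,11.957
CaC3H4,SteamExplosion,122,231.607,1.898
CaC3H4,Microwave_H2SO4,28,487.885,17.424
CaC3H4,EtOH_DMSO_AO,83,393.608,4.742
CaC3H4,NaOH,42,316.961,7.547
F,Control,197,278.208,4.107
F,SteamExplosion,209,167.511,0.801
F,Microwave_H2SO4,778,168.263,0.216
F,EtOH_DMSO_AO,299,244.991,0.819
F,NaOH,46,386.540,8.403
Cl,Control,62,369.058,7.128
Cl,SteamExplosion,135,164.850,1.221
Cl,Microwave_H2SO4,65,457.812,7.043
Cl,EtOH_DMSO_AO,224,234.241,1.046
Cl,NaOH,53,367.540,6.935
DDA,Control,0,0.000,0.000
DDA,SteamExplosion,9,0.403,0.045
DDA,Microwave_H2SO4,7,0.215,0.031
DDA,EtOH_DMSO_AO,7,0.403,0.058
DDA,NaOH,9,2.365,0.263
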