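treatment,li_free_oh_area_pct
Control,77.92
EtOH_DMSO_AO,78.50
SteamExplosion,84.98
Microwave_H2SO4,85.00
NaOH,84.16
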