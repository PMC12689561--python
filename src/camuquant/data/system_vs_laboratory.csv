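stage,system_mg_per_100g,laboratory_mg_per_100g
Pinton Green,1576.42,1790.37
Ripe Pinton,2110.55,2033.32
Ripe,2309.21,2187.50
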