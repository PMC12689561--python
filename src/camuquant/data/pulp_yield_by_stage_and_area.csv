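stage,pulp_g,sample_weight_g,area_class
Ripe,12.30,100,more_than_8
Ripe,8.15,100,between_5_and_8
Ripe,6.10,100,less_than_5
Ripe Pinton,14.12,100,more_than_8
Ripe Pinton,9.18,100,between_5_and_8
Ripe Pinton,7.20,100,less_than_5
Pinton Green,10.21,100,more_than_8
Pinton Green,7.33,100,between_5_and_8
Pinton Green,5.26,100,less_than_5
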