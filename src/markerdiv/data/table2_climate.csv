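region,AMT,ART,WI,CI,AP,S
Naiman,7.5,36.1,56.3,86.2,269.9,21.8
Horqin Left Wing Rear,6.9,38.5,60.4,80.4,448.1,36.1
Jarud,6.6,36.5,61.2,80.2,382.5,29.8
Ar Horqin,5.9,35.9,74.7,64.0,369.7,30.2
Ongniud,6.4,34.7,58.7,75.7,369.9,31.3
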