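population,region,habitat
Pop1,Naiman,Mobile sand dune
Pop2,Naiman,Lowlands between mobile sand dunes
Pop3,Naiman,Fixed sand dune
Pop4,Naiman,Lowlands between fixed sand dunes
Pop5,Naiman,Semifixed sand dune
Pop6,Horqin Left Wing Rear,Mobile sand dune
Pop7,Horqin Left Wing Rear,Lowlands between mobile sand dunes
Pop8,Horqin Left Wing Rear,Fixed sand dune
Pop9,Horqin Left Wing Rear,Lowlands between fixed sand dunes
Pop10,Jarud,Mobile sand dune
Pop11,Jarud,Lowlands between mobile sand dunes
Pop12,Jarud,Lowlands between fixed sand dunes
Pop13,Ar Horqin,Mobile sand dune
Pop14,Ar Horqin,Lowlands between mobile sand dunes
Pop15,Ar Horqin,Fixed sand dune
Pop16,Ar Horqin,Semifixed sand dune
Pop17,Ongniud,Mobile sand dune
Pop18,Ongniud,Lowlands between mobile sand dunes
Pop19,Ongniud,Lowlands between fixed sand dunes
Pop20,Ongniud,Semifixed sand dune
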