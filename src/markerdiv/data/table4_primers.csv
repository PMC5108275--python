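primer,sequence,tm_c,n_bands,n_polymorphic,pct_polymorphic
UBC807,(AG)8T,54,25,25,100.00
UBC810,(GA)8T,53,19,16,84.21
UBC826,(AC)8C,54,18,17,94.44
UBC827,(AC)8G,54,14,14,100.00
UBC835,(AG)8YC,53,16,14,87.50
UBC836,(AG)8YA,52,20,19,95.00
UBC840,(GA)8YT,58,15,13,86.67
UBC842,(GA)8YG,58,27,25,92.59
UBC848,(CA)8RG,48,13,13,100.00
UBC857,(AC)8YG,58,26,24,92.31
UBC864,(ATG)6,52,23,23,100.00
UBC880,(GGAGA)3,58,25,24,96.00
UBC889,DBD(AC)7,52,14,13,92.86
UBC892,TAGATCTGATATCTGAATTCCC,48,18,16,88.89
UBC895,AGAGTTGGTAGCTCTTGATC,48,15,13,86.67
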