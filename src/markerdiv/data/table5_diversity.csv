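population,sample_size,n,P,Na,Na_sd,Ne,Ne_sd,h,h_sd,I,I_sd
Pop1,13,50,17.36,1.1736,0.3794,1.1190,0.2793,0.0683,0.1541,0.1004,0.2236
Pop2,13,29,10.07,1.1007,0.3014,1.0661,0.2135,0.0385,0.1189,0.0570,0.1737
Pop3,13,27,9.38,1.0938,0.2920,1.0649,0.2156,0.0371,0.1191,0.0544,0.1726
Pop4,13,19,6.60,1.0660,0.2487,1.0385,0.1580,0.0233,0.0916,0.0352,0.1358
Pop5,13,32,11.11,1.1111,0.3148,1.0720,0.2249,0.0417,0.1233,0.0619,0.1797
Pop6,13,40,13.89,1.1389,0.3464,1.0965,0.2579,0.0549,0.1420,0.0804,0.2052
Pop7,13,54,18.75,1.1875,0.3910,1.1283,0.2857,0.0740,0.1586,0.1089,0.2306
Pop8,13,113,39.24,1.3924,0.4891,1.3116,0.4107,0.1700,0.2177,0.2441,0.3092
Pop9,13,55,19.10,1.1910,0.3938,1.1188,0.2608,0.0714,0.1510,0.1066,0.2230
Pop10,13,65,22.57,1.2257,0.4188,1.1376,0.2811,0.0820,0.1596,0.1228,0.2344
Pop11,13,52,18.06,1.1806,0.3853,1.1227,0.2853,0.0701,0.1560,0.1032,0.2257
Pop12,13,37,12.85,1.1285,0.3352,1.0838,0.2395,0.0484,0.1323,0.0717,0.1924
Pop13,13,59,20.49,1.2049,0.4043,1.1322,0.2875,0.0768,0.1591,0.1140,0.2317
Pop14,13,58,20.14,1.2014,0.4017,1.1346,0.2914,0.0777,0.1613,0.1146,0.2342
Pop15,13,121,42.01,1.4201,0.4944,1.2992,0.3802,0.1702,0.2076,0.2486,0.2988
Pop16,13,104,36.11,1.3611,0.4812,1.2794,0.3985,0.1532,0.2113,0.2208,0.3005
Pop17,13,51,17.71,1.1771,0.3824,1.1135,0.2679,0.0664,0.1495,0.0987,0.2183
Pop18,13,32,11.11,1.1111,0.3148,1.0870,0.2505,0.0483,0.1382,0.0694,0.1980
Pop19,13,38,13.19,1.1319,0.3390,1.0832,0.2278,0.0496,0.1309,0.0738,0.1928
Pop20,13,90,31.25,1.3125,0.4643,1.2193,0.3567,0.1242,0.1926,0.1819,0.2771
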