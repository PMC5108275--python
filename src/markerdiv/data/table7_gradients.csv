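gradient,class,Na,Na_sd,Ne,Ne_sd,h,h_sd,I,I_sd,Gst,Nm
habitat,Mobile sand dune,1.1840,0.0330,1.1198,0.0162,0.0697,0.0104,0.1032,0.0162,0.7609,0.1571
habitat,Lowlands between mobile sand dunes,1.1563,0.0467,1.1077,0.0297,0.0617,0.0173,0.0906,0.0257,0.7980,0.1266
habitat,Fixed sand dune,1.2616,0.1326,1.1902,0.1067,0.1064,0.0579,0.1549,0.0828,0.5731,0.3725
habitat,Lowlands between fixed sand dunes,1.3021,0.1809,1.2252,0.1390,0.1258,0.0768,0.1824,0.1108,0.5017,0.4967
habitat,Semifixed sand dune,1.1294,0.0511,1.0811,0.0330,0.0482,0.0197,0.0718,0.0292,0.8384,0.0964
thermodynamic,Low-temperature region,1.1783,0.0486,1.1147,0.0278,0.0669,0.0170,0.0992,0.0258,0.6223,0.3035
thermodynamic,Medium-temperature region,1.2969,0.1109,1.2114,0.0904,0.1195,0.0493,0.1745,0.0704,0.5663,0.3830
thermodynamic,High-temperature region,1.1090,0.0397,1.0721,0.0292,0.0418,0.0164,0.0618,0.0239,0.6864,0.2284
humidity,Low-humidity region,1.1090,0.0397,1.0721,0.0292,0.0418,0.0164,0.0618,0.0239,0.6864,0.2284
humidity,Medium-humidity region,1.1832,0.0905,1.1258,0.0638,0.0721,0.0357,0.1060,0.0523,0.6862,0.2286
humidity,High-humidity region,1.2275,0.1125,1.1638,0.0994,0.0926,0.0523,0.1350,0.0739,0.5961,0.3388
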