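population,SOC,SAN,SOP,SOC/SAN,SOC/SOP,SAN/SOP
Pop1,0.118,0.004,0.006,31.837,18.624,0.603
Pop2,0.113,0.004,0.003,29.021,46.094,1.732
Pop3,1.870,0.008,0.006,248.033,30.805,1.267
Pop4,2.495,0.007,0.006,392.014,419.009,1.115
Pop5,0.360,0.004,0.004,100.002,90.055,0.870
Pop6,0.867,0.018,0.015,48.095,94.160,2.014
Pop7,1.336,0.023,0.010,54.002,16.258,3.049
Pop8,1.930,0.027,0.026,70.043,180.077,2.600
Pop9,1.920,0.028,0.007,70.051,360.089,5.480
Pop10,1.204,0.021,0.006,56.400,288.432,4.953
Pop11,0.300,0.009,0.004,34.067,95.123,2.966
Pop12,1.860,0.022,0.008,80.095,260.065,3.670
Pop13,0.474,0.012,0.007,39.918,73.663,1.828
Pop14,0.692,0.013,0.007,49.006,133.004,2.296
Pop15,1.380,0.019,0.006,70.046,350.089,4.990
Pop16,2.306,0.026,0.025,100.013,100.047,1.100
Pop17,1.176,0.017,0.010,58.291,265.794,3.101
Pop18,0.598,0.014,0.007,41.037,78.095,1.917
Pop19,2.110,0.025,0.009,80.095,230.750,2.870
Pop20,3.128,0.040,0.031,78.205,100.903,1.290
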