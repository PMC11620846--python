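plot,elevation,aspect,slope,topographic_position,crown_density,dist_coastline,dist_nearest_island,dist_mainland,air_temperature,precipitation,wind_speed
S1,42.4,160,30,Middle,0.75,1.438,2.844,3.699,20.206,1319.333,1.072
S2,81.1,160,30,Up,0.75,1.508,2.824,3.761,19.864,1328.361,1.072
S3,178.4,353,30,Up,0.80,0.596,1.455,3.488,19.989,1327.944,0.964
S4,71.9,312,30,Middle,0.75,0.302,1.238,3.222,19.989,1327.944,0.952
S5,123.2,261,37,Up,0.68,0.515,1.573,3.395,19.989,1327.944,0.964
S6,175.5,155,32,Middle,0.80,1.652,2.316,4.659,19.481,1330.194,1.097
S7,40.7,289,24,Low,0.75,0.911,2.657,4.210,20.042,1331.361,1.063
S8,96.0,23,23,Low,0.80,1.096,2.458,4.126,19.481,1330.194,1.052
S9,126.0,205,30,Up,0.55,0.512,1.738,4.035,19.436,1320.167,0.767
S10,157.2,180,30,Up,0.93,0.491,2.024,4.549,19.894,1325.778,0.690
S11,133.0,191,30,Middle,0.95,0.368,1.749,4.615,19.892,1322.500,0.767
S12,140.9,47,30,Middle,0.90,0.380,1.800,4.622,19.892,1322.500,0.690
S13,109.1,224,28,Low,0.60,0.152,3.428,3.287,19.991,1323.150,1.074
S14,109.1,197,35,Low,0.60,0.031,3.350,3.251,20.043,1323.280,1.094
S15,92.1,119,26,Middle,0.80,1.581,2.815,3.829,19.864,1328.361,1.072
S16,49.4,151,32,Low,0.65,1.420,2.650,3.626,20.206,1319.333,1.072
S17,55.0,115,22,Low,0.60,1.057,2.136,3.120,20.050,1326.528,0.929
S18,36.2,294,22,Low,0.58,0.181,1.016,3.102,19.989,1327.944,0.946
S19,89.3,39,27,Low,0.88,0.410,1.185,4.185,19.953,1332.000,1.111
S20,64.0,35,30,Low,0.85,0.446,1.072,4.217,19.953,1332.000,1.123
Q1,83.2,197,28,Middle,0.70,0.373,0.694,2.218,19.978,1304.139,1.247
Q2,74.4,212,26,Middle,0.80,0.376,0.825,1.975,19.978,1304.139,1.246
Q3,160.7,342,24,Middle,0.67,0.364,1.197,2.823,19.831,1305.028,1.214
Q4,92.4,7,34,Middle,0.80,0.205,1.375,2.991,19.831,1305.028,1.215
Q5,36.9,219,34,Low,0.80,0.118,0.631,2.231,19.901,1304.810,1.220
Q6,58.1,242,35,Middle,0.80,0.185,0.698,2.301,19.893,1304.760,1.224
C1,26.0,208,38,Up,0.65,0.054,1.515,2.206,19.908,1299.540,0.857
C2,49.2,175,36,Middle,0.95,0.250,0.761,1.570,19.883,1301.361,0.795
C3,54.2,351,26,Low,0.93,0.175,1.417,0.546,19.682,1311.060,0.683
C4,56.6,71,33,Low,0.65,0.079,1.143,0.734,19.772,1308.833,0.715
C5,16.2,55,27,Low,0.55,0.029,0.541,1.220,19.892,1303.472,0.795
J1,104.7,88,37,Up,0.70,0.321,0.961,1.816,19.681,1270.472,1.838
J2,44.6,83,24,Middle,0.80,0.140,0.891,2.066,19.681,1270.472,1.819
J3,47.7,38,38,Middle,0.70,0.228,1.239,1.561,19.688,1273.160,1.842
J4,19.3,3,28,Low,0.78,0.140,1.430,1.440,19.695,1274.560,1.854
B1,99.5,225,34,Up,0.68,0.328,1.737,2.078,19.614,1321.190,0.703
B2,45.8,127,22,Up,0.75,0.125,0.988,1.099,19.617,1321.500,0.650
B3,44.6,83,24,Middle,0.80,0.084,0.957,1.062,19.681,1270.472,1.819
D1,57.0,282,31,Up,0.85,0.227,1.073,2.134,19.928,1283.833,1.608
D2,63.0,291,23,Low,0.75,0.130,0.983,2.375,19.928,1283.833,1.617
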