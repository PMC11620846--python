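plot,pH,t_k,a_k,t_p,a_p,t_n,a_n,som,salt
S1,4.55,1.17,73.71,0.09,2.31,1.03,172.12,31.48,1.36
S2,4.66,0.41,52.89,0.06,1.40,0.72,157.09,23.36,1.62
S3,4.65,4.71,76.73,0.19,1.33,1.47,119.25,38.39,0.97
S4,4.66,3.19,44.26,0.34,3.95,1.67,161.40,43.98,0.97
S5,4.64,3.19,51.64,0.10,1.55,0.74,141.96,20.99,1.51
S6,4.44,6.95,32.71,0.26,1.10,1.38,179.98,47.05,1.34
S7,4.41,4.78,91.24,0.21,1.43,1.84,224.79,48.87,1.78
S8,4.30,5.04,45.62,0.11,1.80,1.33,214.71,45.98,1.46
S9,4.36,9.84,45.62,0.10,0.96,1.24,163.96,48.45,1.81
S10,4.60,3.68,51.89,0.12,1.51,1.22,152.48,37.95,0.87
S11,4.61,3.16,74.07,0.16,0.92,1.31,167.87,41.78,0.49
S12,4.61,3.32,102.86,0.15,1.24,1.64,231.32,42.81,1.49
S13,4.62,7.14,84.01,0.16,1.35,0.96,140.50,39.87,1.02
S14,4.67,8.82,84.01,0.19,1.68,1.38,180.03,41.16,1.64
S15,4.49,3.69,112.70,0.17,1.12,1.65,148.91,41.20,1.37
S16,4.67,2.07,55.02,0.09,1.31,1.06,136.17,29.22,1.69
S17,4.45,2.05,74.81,0.11,3.17,0.87,178.88,22.06,0.82
S18,4.68,7.59,23.69,0.23,0.85,1.36,166.64,45.70,1.07
S19,4.44,6.70,44.71,0.19,1.02,1.79,192.54,52.85,1.22
S20,4.22,9.06,44.48,0.21,1.30,1.30,204.37,34.74,0.50
Q1,4.92,2.66,55.58,0.15,1.63,1.32,80.06,37.04,1.36
Q2,5.37,2.51,44.71,0.17,0.66,1.35,76.42,35.35,1.62
Q3,5.21,2.52,34.50,0.16,0.61,1.13,68.50,31.23,0.97
Q4,5.14,1.69,63.51,0.21,1.16,1.54,90.79,43.13,0.97
Q5,5.05,2.85,75.57,0.17,1.12,1.72,118.29,44.19,1.51
Q6,5.31,2.61,53.93,0.14,0.78,1.04,84.51,31.23,1.34
C1,5.96,2.38,42.18,0.27,1.46,1.06,76.42,33.10,1.78
C2,4.82,3.04,93.48,0.19,0.64,1.01,102.75,37.69,1.46
C3,4.17,8.28,45.16,0.26,1.99,2.08,196.67,48.30,1.81
C4,4.32,9.71,35.56,0.22,2.21,1.46,164.10,64.02,0.87
C5,4.58,2.82,93.48,0.17,1.08,1.57,120.43,46.56,0.49
J1,4.66,3.81,126.26,0.28,1.62,2.10,250.19,54.73,1.49
J2,4.57,4.76,63.82,0.19,0.97,1.36,419.77,44.18,1.02
J3,4.37,4.80,44.48,0.18,0.98,1.24,135.82,50.28,1.64
J4,5.05,2.46,72.28,0.31,1.25,1.12,111.29,41.06,1.37
B1,4.82,2.69,74.44,0.17,1.86,1.51,126.13,49.71,1.69
B2,4.81,2.90,56.15,0.18,1.36,1.38,179.45,41.10,0.82
B3,5.00,4.43,145.07,0.22,1.36,2.20,205.19,65.73,1.07
D1,5.01,3.68,90.37,0.22,1.09,1.70,143.80,54.99,1.22
D2,4.82,4.71,118.48,0.21,0.69,1.38,147.95,44.92,0.50
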