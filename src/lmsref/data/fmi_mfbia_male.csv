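age,L,M,S,P1,P3,P5,P15,P25,P50,P75,P85,P95,P97,P99
5,0.951,2.04,0.453,0.15,0.39,0.57,1.10,1.43,2.04,2.69,3.08,3.86,4.23,5.07
5.5,0.777,2.14,0.480,0.19,0.45,0.62,1.14,1.48,2.14,2.87,3.28,4.04,4.36,5.00
6,0.622,2.26,0.505,0.27,0.53,0.69,1.19,1.54,2.26,3.08,3.56,4.45,4.81,5.54
6.5,0.488,2.39,0.530,0.36,0.61,0.76,1.26,1.61,2.39,3.33,3.90,4.96,5.41,6.32
7,0.377,2.55,0.552,0.44,0.68,0.84,1.34,1.70,2.55,3.61,4.28,5.57,6.13,7.28
7.5,0.290,2.71,0.571,0.51,0.75,0.91,1.42,1.81,2.71,3.91,4.69,6.23,6.92,8.36
8,0.223,2.89,0.584,0.57,0.82,0.98,1.51,1.91,2.89,4.21,5.09,6.89,7.70,9.45
8.5,0.171,3.05,0.591,0.64,0.89,1.05,1.60,2.02,3.05,4.49,5.47,7.51,8.45,10.51
9,0.129,3.21,0.594,0.70,0.96,1.13,1.69,2.13,3.21,4.74,5.80,8.05,9.11,11.45
9.5,0.096,3.34,0.594,0.76,1.02,1.20,1.77,2.22,3.34,4.94,6.07,8.48,9.64,12.20
10,0.070,3.43,0.590,0.81,1.08,1.26,1.84,2.29,3.43,5.08,6.25,8.78,10.00,12.74
10.5,0.049,3.49,0.585,0.85,1.13,1.30,1.89,2.34,3.49,5.16,6.34,8.94,10.19,13.03
11,0.035,3.51,0.579,0.88,1.16,1.33,1.91,2.37,3.51,5.17,6.35,8.95,10.21,13.08
11.5,0.026,3.49,0.572,0.90,1.17,1.34,1.92,2.36,3.49,5.12,6.28,8.84,10.08,12.91
12,0.022,3.43,0.566,0.90,1.17,1.34,1.90,2.34,3.43,5.02,6.15,8.63,9.83,12.57
12.5,0.023,3.37,0.560,0.90,1.16,1.33,1.88,2.31,3.37,4.91,6.00,8.38,9.53,12.15
13,0.027,3.31,0.553,0.89,1.15,1.32,1.86,2.27,3.31,4.79,5.84,8.12,9.23,11.72
13.5,0.033,3.26,0.547,0.89,1.14,1.31,1.84,2.25,3.26,4.70,5.71,7.90,8.95,11.32
14,0.041,3.23,0.540,0.89,1.14,1.30,1.83,2.23,3.23,4.63,5.61,7.72,8.73,10.99
14.5,0.050,3.22,0.534,0.89,1.15,1.31,1.84,2.24,3.22,4.60,5.55,7.59,8.56,10.73
15,0.060,3.23,0.527,0.90,1.16,1.33,1.85,2.25,3.23,4.59,5.53,7.52,8.46,10.54
15.5,0.072,3.26,0.521,0.92,1.18,1.35,1.88,2.29,3.26,4.62,5.54,7.49,8.41,10.43
16,0.083,3.32,0.514,0.94,1.21,1.38,1.92,2.33,3.32,4.67,5.59,7.51,8.41,10.38
16.5,0.095,3.38,0.509,0.96,1.24,1.42,1.97,2.39,3.38,4.74,5.66,7.57,8.45,10.38
17,0.108,3.47,0.503,0.99,1.28,1.46,2.03,2.45,3.47,4.84,5.76,7.66,8.54,10.44
17.5,0.121,3.56,0.498,1.02,1.32,1.50,2.09,2.53,3.56,4.95,5.88,7.78,8.66,10.54
18,0.134,3.67,0.493,1.06,1.36,1.55,2.16,2.61,3.67,5.08,6.02,7.93,8.80,10.68
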