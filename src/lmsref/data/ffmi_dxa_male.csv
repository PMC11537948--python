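age,L,M,S,P1,P3,P5,P15,P25,P50,P75,P85,P95,P97,P99
5,-2.030,11.47,0.057,10.36,10.48,10.56,10.79,10.99,11.47,12.03,12.30,12.69,12.82,13.05
5.5,-1.874,11.54,0.060,10.34,10.48,10.57,10.83,11.04,11.54,12.12,12.40,12.83,12.98,13.26
6,-1.732,11.61,0.063,10.32,10.48,10.58,10.88,11.09,11.61,12.20,12.50,12.98,13.15,13.47
6.5,-1.601,11.67,0.065,10.28,10.47,10.58,10.91,11.14,11.67,12.27,12.58,13.10,13.30,13.67
7,-1.479,11.70,0.068,10.22,10.44,10.56,10.92,11.16,11.70,12.31,12.64,13.20,13.42,13.85
7.5,-1.366,11.72,0.070,10.16,10.40,10.54,10.92,11.18,11.72,12.34,12.68,13.29,13.53,14.02
8,-1.261,11.77,0.073,10.11,10.39,10.54,10.95,11.22,11.77,12.39,12.75,13.40,13.67,14.21
8.5,-1.161,11.87,0.075,10.11,10.41,10.57,11.02,11.31,11.87,12.49,12.86,13.56,13.85,14.45
9,-1.068,11.99,0.077,10.13,10.46,10.64,11.12,11.42,11.99,12.62,13.01,13.74,14.06,14.72
9.5,-0.979,12.13,0.079,10.18,10.53,10.73,11.24,11.55,12.13,12.78,13.18,13.96,14.30,15.00
10,-0.895,12.30,0.081,10.25,10.63,10.84,11.38,11.70,12.30,12.96,13.38,14.20,14.56,15.31
10.5,-0.815,12.51,0.083,10.34,10.76,10.98,11.55,11.89,12.51,13.19,13.62,14.48,14.86,15.66
11,-0.739,12.75,0.086,10.48,10.91,11.15,11.75,12.11,12.75,13.46,13.91,14.80,15.20,16.05
11.5,-0.666,13.03,0.087,10.64,11.10,11.35,11.99,12.36,13.03,13.76,14.24,15.17,15.59,16.48
12,-0.596,13.35,0.089,10.83,11.33,11.59,12.26,12.65,13.35,14.11,14.60,15.58,16.02,16.95
12.5,-0.530,13.70,0.091,11.05,11.57,11.85,12.56,12.97,13.70,14.50,15.01,16.03,16.49,17.46
13,-0.465,14.07,0.093,11.29,11.84,12.13,12.87,13.30,14.07,14.91,15.44,16.51,16.99,17.99
13.5,-0.404,14.46,0.095,11.54,12.11,12.42,13.20,13.65,14.46,15.33,15.89,17.01,17.50,18.54
14,-0.344,14.85,0.097,11.78,12.39,12.71,13.53,14.00,14.85,15.76,16.35,17.50,18.02,19.09
14.5,-0.287,15.22,0.099,12.01,12.64,12.98,13.84,14.33,15.22,16.17,16.78,17.98,18.51,19.62
15,-0.231,15.55,0.100,12.21,12.87,13.22,14.11,14.63,15.55,16.55,17.18,18.42,18.96,20.10
15.5,-0.177,15.85,0.102,12.39,13.07,13.43,14.36,14.89,15.85,16.89,17.54,18.82,19.37,20.53
16,-0.125,16.12,0.104,12.53,13.23,13.61,14.57,15.12,16.12,17.19,17.87,19.17,19.74,20.91
17,-0.026,16.58,0.107,12.76,13.51,13.90,14.92,15.51,16.58,17.73,18.44,19.80,20.38,21.58
17.5,0.022,16.79,0.109,12.86,13.62,14.03,15.07,15.68,16.79,17.97,18.70,20.08,20.67,21.88
18,0.068,16.99,0.110,12.95,13.73,14.15,15.22,15.85,16.99,18.21,18.95,20.36,20.96,22.18
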