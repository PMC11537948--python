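age,L,M,S,P1,P3,P5,P15,P25,P50,P75,P85,P95,P97,P99
5,-0.268,13.45,0.069,11.49,11.84,12.03,12.53,12.84,13.45,14.10,14.46,15.10,15.36,15.86
5.5,-0.449,13.42,0.072,11.42,11.77,11.96,12.47,12.79,13.42,14.09,14.47,15.15,15.42,15.96
6,-0.707,13.42,0.074,11.40,11.74,11.93,12.45,12.77,13.42,14.12,14.52,15.25,15.54,16.13
6.5,-1.030,13.44,0.077,11.41,11.75,11.94,12.45,12.78,13.44,14.17,14.60,15.39,15.71,16.37
7,-1.382,13.48,0.079,11.45,11.78,11.96,12.48,12.81,13.48,14.25,14.71,15.56,15.93,16.67
7.5,-1.693,13.55,0.081,11.50,11.82,12.01,12.52,12.85,13.55,14.35,14.83,15.76,16.17,17.01
8,-1.907,13.62,0.083,11.55,11.88,12.06,12.58,12.91,13.62,14.46,14.97,15.97,16.41,17.36
8.5,-2.001,13.72,0.085,11.61,11.94,12.12,12.65,12.99,13.72,14.59,15.12,16.18,16.65,17.67
9,-1.978,13.83,0.087,11.66,12.00,12.19,12.73,13.08,13.83,14.73,15.28,16.38,16.87,17.94
9.5,-1.857,13.96,0.089,11.71,12.06,12.26,12.82,13.19,13.96,14.88,15.45,16.57,17.07,18.15
10,-1.673,14.11,0.091,11.77,12.14,12.34,12.92,13.31,14.11,15.05,15.64,16.76,17.26,18.33
10.5,-1.453,14.28,0.093,11.83,12.22,12.44,13.05,13.45,14.28,15.25,15.84,16.97,17.46,18.50
11,-1.220,14.46,0.095,11.90,12.31,12.54,13.18,13.60,14.46,15.46,16.05,17.19,17.67,18.69
11.5,-0.991,14.66,0.096,11.98,12.41,12.66,13.33,13.77,14.66,15.68,16.29,17.42,17.90,18.89
12,-0.778,14.88,0.098,12.07,12.53,12.79,13.50,13.95,14.88,15.93,16.54,17.68,18.15,19.12
12.5,-0.590,15.11,0.100,12.16,12.65,12.93,13.67,14.15,15.11,16.18,16.81,17.95,18.43,19.38
13,-0.432,15.36,0.101,12.27,12.79,13.08,13.86,14.36,15.36,16.46,17.09,18.25,18.72,19.68
13.5,-0.303,15.61,0.103,12.40,12.94,13.24,14.06,14.58,15.61,16.74,17.39,18.56,19.04,20.00
14,-0.201,15.87,0.104,12.53,13.10,13.41,14.26,14.80,15.87,17.03,17.70,18.89,19.38,20.34
14.5,-0.120,16.13,0.106,12.66,13.25,13.58,14.47,15.02,16.13,17.32,18.00,19.22,19.72,20.69
15,-0.057,16.38,0.107,12.80,13.41,13.75,14.67,15.24,16.38,17.61,18.31,19.55,20.06,21.05
15.5,-0.010,16.63,0.108,12.93,13.57,13.92,14.87,15.46,16.63,17.90,18.61,19.88,20.40,21.41
16,0.020,16.88,0.110,13.07,13.72,14.09,15.06,15.67,16.88,18.17,18.91,20.21,20.74,21.77
17,0.030,17.35,0.112,13.34,14.03,14.41,15.44,16.08,17.35,18.72,19.49,20.87,21.42,22.52
17.5,0.012,17.58,0.114,13.49,14.19,14.58,15.63,16.28,17.58,18.98,19.78,21.19,21.77,22.90
18,-0.016,17.81,0.115,13.63,14.35,14.74,15.81,16.48,17.81,19.25,20.07,21.52,22.12,23.29
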