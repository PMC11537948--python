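age,L,M,S,P1,P3,P5,P15,P25,P50,P75,P85,P95,P97,P99
5,-2.411,10.70,0.058,9.63,9.75,9.83,10.07,10.25,10.70,11.22,11.48,11.90,12.05,12.33
5.5,-2.315,10.95,0.060,9.81,9.95,10.03,10.28,10.48,10.95,11.49,11.77,12.21,12.38,12.68
6,-2.227,11.11,0.062,9.91,10.06,10.14,10.41,10.62,11.11,11.69,11.98,12.45,12.63,12.95
6.5,-2.146,11.17,0.066,9.90,10.06,10.15,10.44,10.65,11.17,11.78,12.10,12.61,12.80,13.16
7,-2.071,11.21,0.070,9.86,10.03,10.13,10.43,10.66,11.21,11.86,12.21,12.76,12.97,13.37
7.5,-2.002,11.25,0.075,9.80,9.98,10.09,10.41,10.66,11.25,11.94,12.32,12.93,13.16,13.61
8,-1.937,11.27,0.080,9.74,9.93,10.04,10.39,10.65,11.27,12.01,12.41,13.08,13.34,13.83
8.5,-1.876,11.31,0.084,9.69,9.90,10.02,10.38,10.66,11.31,12.10,12.52,13.24,13.52,14.06
9,-1.818,11.39,0.088,9.69,9.91,10.03,10.42,10.70,11.39,12.22,12.67,13.44,13.74,14.33
9.5,-1.763,11.51,0.092,9.72,9.95,10.08,10.49,10.79,11.51,12.38,12.86,13.69,14.02,14.66
10,-1.712,11.66,0.096,9.78,10.02,10.16,10.59,10.91,11.66,12.58,13.09,13.98,14.33,15.03
10.5,-1.663,11.84,0.100,9.86,10.11,10.26,10.72,11.05,11.84,12.81,13.35,14.29,14.68,15.43
11,-1.616,12.05,0.102,9.98,10.25,10.40,10.88,11.23,12.05,13.06,13.63,14.63,15.04,15.84
11.5,-1.571,12.30,0.104,10.15,10.42,10.59,11.08,11.45,12.30,13.35,13.93,14.97,15.40,16.24
12,-1.528,12.58,0.104,10.36,10.65,10.82,11.33,11.70,12.58,13.64,14.24,15.30,15.73,16.59
12.5,-1.487,12.85,0.103,10.59,10.89,11.07,11.59,11.97,12.85,13.92,14.52,15.59,16.02,16.88
13,-1.447,13.12,0.101,10.83,11.14,11.32,11.85,12.23,13.12,14.18,14.78,15.83,16.26,17.11
13.5,-1.409,13.36,0.099,11.06,11.37,11.55,12.09,12.47,13.36,14.41,15.00,16.04,16.46,17.29
14,-1.372,13.57,0.097,11.26,11.58,11.76,12.31,12.69,13.57,14.61,15.19,16.21,16.62,17.44
14.5,-1.337,13.75,0.095,11.44,11.76,11.95,12.49,12.88,13.75,14.78,15.35,16.35,16.76,17.56
15,-1.303,13.90,0.093,11.59,11.91,12.10,12.65,13.04,13.90,14.92,15.49,16.48,16.88,17.67
15.5,-1.270,14.03,0.092,11.71,12.03,12.22,12.78,13.17,14.03,15.04,15.61,16.59,16.99,17.77
16,-1.238,14.14,0.092,11.79,12.13,12.32,12.88,13.27,14.14,15.14,15.70,16.68,17.08,17.86
17,-1.177,14.26,0.091,11.89,12.23,12.43,13.00,13.39,14.26,15.26,15.82,16.80,17.20,17.98
17.5,-1.147,14.28,0.091,11.90,12.25,12.44,13.02,13.41,14.28,15.28,15.84,16.82,17.22,18.00
18,-1.119,14.28,0.091,11.89,12.24,12.44,13.02,13.41,14.28,15.28,15.84,16.82,17.21,18.00
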