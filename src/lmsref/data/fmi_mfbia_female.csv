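age,L,M,S,P1,P3,P5,P15,P25,P50,P75,P85,P95,P97,P99
5,0.463,2.40,0.457,0.56,0.80,0.95,1.41,1.72,2.40,3.20,3.68,4.57,4.95,5.70
5.5,0.381,2.52,0.468,0.62,0.86,1.01,1.48,1.80,2.52,3.40,3.93,4.95,5.38,6.26
6,0.307,2.62,0.478,0.67,0.92,1.07,1.53,1.87,2.62,3.57,4.16,5.30,5.80,6.83
6.5,0.242,2.72,0.489,0.72,0.96,1.11,1.58,1.93,2.72,3.74,4.39,5.68,6.24,7.44
7,0.189,2.82,0.502,0.75,1.00,1.15,1.63,1.99,2.82,3.91,4.63,6.07,6.71,8.09
7.5,0.149,2.92,0.512,0.79,1.03,1.19,1.68,2.05,2.92,4.08,4.86,6.45,7.17,8.73
8,0.121,3.02,0.517,0.82,1.07,1.23,1.74,2.11,3.02,4.25,5.08,6.79,7.57,9.28
8.5,0.104,3.13,0.518,0.86,1.12,1.28,1.80,2.19,3.13,4.41,5.28,7.08,7.91,9.74
9,0.095,3.26,0.513,0.92,1.18,1.35,1.89,2.29,3.26,4.59,5.48,7.35,8.22,10.11
9.5,0.092,3.42,0.505,0.99,1.27,1.44,2.00,2.42,3.42,4.79,5.71,7.63,8.52,10.45
10,0.095,3.62,0.493,1.07,1.37,1.55,2.14,2.58,3.62,5.02,5.96,7.91,8.80,10.75
10.5,0.104,3.83,0.479,1.17,1.49,1.68,2.30,2.76,3.83,5.27,6.22,8.18,9.07,11.01
11,0.118,4.07,0.463,1.29,1.62,1.83,2.48,2.96,4.07,5.53,6.49,8.44,9.33,11.23
11.5,0.136,4.33,0.446,1.42,1.78,2.00,2.69,3.19,4.33,5.82,6.78,8.72,9.59,11.44
12,0.157,4.61,0.429,1.56,1.95,2.19,2.91,3.43,4.61,6.12,7.09,9.01,9.86,11.66
12.5,0.180,4.91,0.412,1.72,2.13,2.39,3.15,3.69,4.91,6.44,7.41,9.30,10.14,11.88
13,0.205,5.21,0.395,1.88,2.33,2.59,3.40,3.96,5.21,6.76,7.73,9.60,10.42,12.11
13.5,0.231,5.51,0.380,2.05,2.52,2.81,3.65,4.23,5.51,7.07,8.03,9.88,10.68,12.32
14,0.256,5.79,0.366,2.22,2.72,3.01,3.89,4.49,5.79,7.36,8.32,10.14,10.92,12.51
14.5,0.282,6.05,0.353,2.38,2.90,3.21,4.11,4.73,6.05,7.62,8.57,10.36,11.12,12.67
15,0.307,6.27,0.342,2.52,3.06,3.38,4.31,4.94,6.27,7.84,8.78,10.53,11.27,12.77
15.5,0.332,6.45,0.332,2.65,3.21,3.53,4.48,5.11,6.45,8.01,8.93,10.65,11.37,12.82
16,0.357,6.59,0.323,2.75,3.32,3.66,4.61,5.25,6.59,8.12,9.03,10.71,11.41,12.81
16.5,0.382,6.67,0.315,2.82,3.41,3.74,4.71,5.34,6.67,8.18,9.07,10.70,11.38,12.73
17,0.407,6.71,0.308,2.87,3.46,3.80,4.77,5.40,6.71,8.19,9.06,10.64,11.29,12.59
17.5,0.432,6.71,0.302,2.90,3.49,3.83,4.79,5.42,6.71,8.15,8.99,10.52,11.15,12.39
18,0.456,6.67,0.297,2.91,3.50,3.84,4.79,5.41,6.67,8.08,8.89,10.36,10.96,12.15
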