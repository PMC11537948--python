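age,L,M,S,P1,P3,P5,P15,P25,P50,P75,P85,P95,P97,P99
5,-0.553,2.23,0.260,1.32,1.44,1.52,1.73,1.88,2.23,2.68,2.98,3.63,3.94,4.66
5.5,-0.518,2.36,0.279,1.35,1.48,1.56,1.80,1.97,2.36,2.88,3.23,3.98,4.35,5.20
6,-0.485,2.45,0.297,1.35,1.49,1.58,1.84,2.02,2.45,3.02,3.42,4.28,4.70,5.68
6.5,-0.455,2.51,0.314,1.33,1.48,1.58,1.85,2.05,2.51,3.13,3.56,4.52,4.99,6.09
7,-0.427,2.56,0.330,1.32,1.47,1.57,1.86,2.07,2.56,3.23,3.70,4.75,5.26,6.49
7.5,-0.401,2.62,0.345,1.31,1.47,1.57,1.88,2.10,2.62,3.35,3.86,5.00,5.56,6.91
8,-0.377,2.70,0.357,1.31,1.49,1.59,1.91,2.15,2.70,3.48,4.03,5.26,5.87,7.33
8.5,-0.355,2.79,0.367,1.32,1.50,1.61,1.95,2.20,2.79,3.62,4.20,5.51,6.16,7.72
9,-0.333,2.89,0.376,1.34,1.53,1.65,2.01,2.27,2.89,3.77,4.39,5.78,6.48,8.13
9.5,-0.313,3.03,0.382,1.38,1.58,1.71,2.08,2.36,3.03,3.96,4.62,6.10,6.84,8.58
10,-0.294,3.19,0.387,1.43,1.65,1.78,2.18,2.48,3.19,4.19,4.89,6.46,7.24,9.08
10.5,-0.275,3.37,0.391,1.50,1.73,1.87,2.30,2.61,3.37,4.43,5.18,6.84,7.66,9.59
11,-0.258,3.57,0.393,1.57,1.81,1.96,2.42,2.76,3.57,4.69,5.48,7.23,8.10,10.12
11.5,-0.241,3.78,0.394,1.65,1.91,2.07,2.56,2.92,3.78,4.98,5.81,7.65,8.56,10.66
12,-0.225,4.01,0.395,1.74,2.02,2.19,2.71,3.10,4.01,5.28,6.17,8.10,9.04,11.23
12.5,-0.210,4.27,0.395,1.84,2.14,2.32,2.88,3.29,4.27,5.61,6.54,8.57,9.56,11.83
13,-0.195,4.53,0.394,1.95,2.27,2.46,3.06,3.49,4.53,5.95,6.94,9.06,10.09,12.45
13.5,-0.181,4.80,0.394,2.05,2.39,2.60,3.24,3.70,4.80,6.30,7.33,9.56,10.63,13.07
14,-0.168,5.06,0.393,2.16,2.52,2.74,3.41,3.90,5.06,6.64,7.72,10.04,11.15,13.66
14.5,-0.154,5.31,0.393,2.26,2.64,2.87,3.58,4.09,5.31,6.96,8.08,10.48,11.63,14.21
15,-0.142,5.53,0.392,2.34,2.74,2.98,3.72,4.26,5.53,7.24,8.40,10.87,12.05,14.69
15.5,-0.129,5.71,0.392,2.41,2.83,3.08,3.85,4.41,5.71,7.47,8.67,11.20,12.39,15.07
16,-0.118,5.85,0.391,2.46,2.89,3.15,3.94,4.51,5.85,7.65,8.87,11.43,12.64,15.33
16.5,-0.106,5.94,0.391,2.49,2.93,3.19,4.00,4.58,5.94,7.77,9.00,11.57,12.79,15.47
17,-0.095,5.99,0.391,2.50,2.94,3.21,4.02,4.62,5.99,7.82,9.05,11.62,12.83,15.50
17.5,-0.084,5.99,0.391,2.49,2.93,3.20,4.02,4.61,5.99,7.81,9.04,11.59,12.78,15.41
18,-0.073,5.95,0.391,2.47,2.91,3.17,3.99,4.58,5.95,7.76,8.97,11.48,12.66,15.23
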