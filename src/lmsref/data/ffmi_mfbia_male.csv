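age,L,M,S,P1,P3,P5,P15,P25,P50,P75,P85,P95,P97,P99
5,-1.634,12.80,0.046,11.69,11.88,11.98,12.27,12.44,12.80,13.18,13.40,13.79,13.95,14.27
5.5,-1.534,12.99,0.049,11.78,11.99,12.11,12.41,12.61,12.99,13.42,13.66,14.10,14.28,14.64
6,-1.442,13.02,0.052,11.73,11.95,12.07,12.40,12.61,13.02,13.48,13.74,14.22,14.42,14.81
6.5,-1.358,12.96,0.055,11.60,11.83,11.95,12.30,12.52,12.96,13.44,13.72,14.23,14.45,14.87
7,-1.280,12.90,0.058,11.48,11.72,11.85,12.21,12.44,12.90,13.41,13.71,14.26,14.48,14.94
7.5,-1.207,12.88,0.061,11.39,11.64,11.77,12.15,12.39,12.88,13.42,13.73,14.32,14.56,15.05
8,-1.139,12.88,0.064,11.32,11.58,11.72,12.11,12.37,12.88,13.45,13.78,14.40,14.66,15.18
8.5,-1.076,12.90,0.066,11.27,11.54,11.69,12.10,12.36,12.90,13.50,13.85,14.51,14.78,15.35
9,-1.015,12.97,0.069,11.27,11.55,11.70,12.13,12.41,12.97,13.60,13.98,14.67,14.97,15.57
9.5,-0.958,13.09,0.072,11.30,11.60,11.76,12.21,12.50,13.09,13.75,14.15,14.89,15.21,15.85
10,-0.904,13.24,0.074,11.38,11.68,11.85,12.32,12.62,13.24,13.95,14.37,15.16,15.50,16.19
10.5,-0.853,13.43,0.077,11.47,11.79,11.97,12.46,12.78,13.43,14.17,14.62,15.46,15.82,16.56
11,-0.804,13.65,0.079,11.60,11.93,12.12,12.63,12.96,13.65,14.43,14.90,15.79,16.17,16.96
11.5,-0.757,13.89,0.082,11.76,12.10,12.30,12.83,13.17,13.89,14.71,15.20,16.13,16.53,17.37
12,-0.712,14.13,0.084,11.93,12.29,12.48,13.04,13.39,14.13,14.99,15.50,16.47,16.89,17.77
12.5,-0.669,14.37,0.086,12.10,12.47,12.67,13.24,13.61,14.37,15.26,15.79,16.79,17.23,18.14
13,-0.628,14.59,0.089,12.26,12.64,12.85,13.43,13.81,14.59,15.50,16.05,17.08,17.53,18.47
13.5,-0.588,14.80,0.091,12.41,12.80,13.01,13.61,13.99,14.80,15.72,16.28,17.34,17.80,18.76
14,-0.550,14.98,0.093,12.55,12.94,13.16,13.77,14.16,14.98,15.92,16.49,17.58,18.05,19.02
14.5,-0.513,15.15,0.095,12.68,13.08,13.30,13.92,14.32,15.15,16.11,16.69,17.79,18.27,19.26
15,-0.477,15.30,0.098,12.80,13.20,13.42,14.05,14.46,15.30,16.28,16.86,17.98,18.46,19.47
15.5,-0.443,15.44,0.100,12.90,13.31,13.53,14.17,14.58,15.44,16.42,17.02,18.15,18.64,19.65
16,-0.409,15.55,0.102,12.99,13.40,13.63,14.27,14.69,15.55,16.55,17.15,18.29,18.79,19.81
17,-0.345,15.70,0.106,13.09,13.51,13.75,14.40,14.83,15.70,16.72,17.33,18.49,18.99,20.03
17.5,-0.315,15.74,0.108,13.11,13.53,13.77,14.43,14.85,15.74,16.75,17.37,18.53,19.03,20.08
18,-0.285,15.74,0.111,13.11,13.53,13.77,14.43,14.86,15.74,16.76,17.38,18.54,19.04,20.09
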