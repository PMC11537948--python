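age,L,M,S,P1,P3,P5,P15,P25,P50,P75,P85,P95,P97,P99
5,-1.862,13.41,0.042,12.14,12.36,12.48,12.81,13.01,13.41,13.85,14.10,14.55,14.74,15.10
5.5,-1.825,13.27,0.046,11.94,12.17,12.29,12.63,12.85,13.27,13.74,14.00,14.48,14.67,15.06
6,-1.790,13.21,0.049,11.81,12.05,12.18,12.54,12.77,13.21,13.70,13.98,14.49,14.70,15.11
6.5,-1.759,13.21,0.053,11.73,11.98,12.12,12.50,12.74,13.21,13.72,14.02,14.56,14.78,15.22
7,-1.730,13.24,0.056,11.68,11.95,12.09,12.49,12.74,13.24,13.78,14.10,14.66,14.90,15.36
7.5,-1.703,13.27,0.059,11.64,11.92,12.07,12.49,12.75,13.27,13.85,14.18,14.77,15.02,15.51
8,-1.678,13.32,0.062,11.62,11.90,12.06,12.50,12.77,13.32,13.92,14.27,14.90,15.16,15.67
8.5,-1.654,13.39,0.065,11.61,11.91,12.08,12.53,12.82,13.39,14.02,14.39,15.04,15.32,15.86
9,-1.632,13.48,0.068,11.61,11.93,12.10,12.58,12.88,13.48,14.14,14.52,15.21,15.49,16.06
9.5,-1.611,13.58,0.071,11.64,11.97,12.15,12.64,12.96,13.58,14.27,14.67,15.39,15.69,16.29
10,-1.591,13.72,0.074,11.69,12.03,12.22,12.74,13.07,13.72,14.44,14.86,15.62,15.93,16.55
10.5,-1.572,13.90,0.077,11.77,12.13,12.33,12.87,13.21,13.90,14.65,15.09,15.88,16.21,16.87
11,-1.554,14.11,0.079,11.89,12.26,12.47,13.04,13.40,14.11,14.91,15.37,16.20,16.54,17.23
11.5,-1.536,14.37,0.081,12.03,12.43,12.64,13.24,13.61,14.37,15.20,15.68,16.55,16.91,17.64
12,-1.520,14.65,0.083,12.20,12.62,12.84,13.47,13.86,14.65,15.53,16.03,16.95,17.33,18.08
12.5,-1.504,14.96,0.084,12.39,12.83,13.07,13.72,14.13,14.96,15.88,16.41,17.37,17.77,18.57
13,-1.488,15.29,0.085,12.60,13.05,13.30,13.99,14.42,15.29,16.26,16.81,17.82,18.24,19.08
13.5,-1.474,15.63,0.086,12.80,13.28,13.54,14.26,14.72,15.63,16.64,17.22,18.28,18.72,19.59
14,-1.459,15.96,0.087,13.00,13.50,13.77,14.52,15.00,15.96,17.01,17.62,18.73,19.19,20.10
14.5,-1.446,16.26,0.087,13.17,13.69,13.98,14.76,15.26,16.26,17.36,17.99,19.15,19.63,20.58
15,-1.432,16.52,0.088,13.32,13.86,14.15,14.97,15.49,16.52,17.67,18.33,19.53,20.03,21.02
15.5,-1.420,16.76,0.088,13.43,13.99,14.30,15.14,15.68,16.76,17.94,18.63,19.87,20.39,21.41
16,-1.407,16.96,0.088,13.52,14.10,14.42,15.29,15.85,16.96,18.19,18.90,20.18,20.72,21.77
17,-1.383,17.31,0.089,13.65,14.26,14.60,15.53,16.12,17.31,18.61,19.37,20.73,21.29,22.42
17.5,-1.372,17.46,0.089,13.70,14.33,14.68,15.64,16.24,17.46,18.80,19.58,20.98,21.56,22.71
18,-1.361,17.61,0.089,13.74,14.39,14.75,15.73,16.36,17.61,18.99,19.79,21.23,21.82,23.00
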