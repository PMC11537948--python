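age,L,M,S,P1,P3,P5,P15,P25,P50,P75,P85,P95,P97,P99
5,-0.477,12.92,0.071,11.02,11.35,11.53,12.02,12.32,12.92,13.57,13.93,14.58,14.84,15.35
5.5,-0.522,13.13,0.075,11.12,11.47,11.66,12.18,12.50,13.13,13.82,14.21,14.91,15.19,15.75
6,-0.563,13.26,0.078,11.16,11.52,11.72,12.25,12.59,13.26,13.98,14.39,15.14,15.44,16.04
6.5,-0.600,13.30,0.081,11.13,11.50,11.71,12.26,12.61,13.30,14.06,14.50,15.28,15.60,16.24
7,-0.635,13.32,0.084,11.09,11.46,11.67,12.24,12.60,13.32,14.11,14.56,15.39,15.73,16.40
7.5,-0.668,13.33,0.086,11.04,11.43,11.64,12.22,12.59,13.33,14.15,14.62,15.48,15.84,16.55
8,-0.698,13.35,0.089,11.00,11.40,11.61,12.21,12.59,13.35,14.19,14.68,15.57,15.94,16.69
8.5,-0.727,13.38,0.091,10.99,11.39,11.61,12.22,12.60,13.38,14.25,14.76,15.68,16.07,16.84
9,-0.754,13.46,0.093,11.02,11.42,11.65,12.27,12.66,13.46,14.35,14.88,15.84,16.24,17.05
9.5,-0.779,13.59,0.095,11.09,11.50,11.73,12.36,12.77,13.59,14.51,15.05,16.04,16.46,17.30
10,-0.804,13.76,0.096,11.20,11.62,11.85,12.50,12.91,13.76,14.71,15.26,16.30,16.73,17.61
10.5,-0.827,13.96,0.098,11.34,11.77,12.01,12.67,13.09,13.96,14.94,15.51,16.58,17.03,17.95
11,-0.849,14.19,0.099,11.51,11.95,12.19,12.87,13.30,14.19,15.20,15.79,16.90,17.37,18.32
11.5,-0.869,14.45,0.099,11.71,12.15,12.40,13.09,13.54,14.45,15.48,16.09,17.23,17.71,18.70
12,-0.890,14.71,0.100,11.91,12.37,12.62,13.32,13.78,14.71,15.76,16.39,17.56,18.06,19.07
12.5,-0.909,14.96,0.100,12.12,12.58,12.84,13.55,14.01,14.96,16.04,16.68,17.87,18.38,19.41
13,-0.927,15.19,0.100,12.31,12.78,13.04,13.76,14.23,15.19,16.28,16.93,18.14,18.66,19.72
13.5,-0.945,15.39,0.099,12.49,12.96,13.22,13.95,14.42,15.39,16.50,17.16,18.38,18.91,19.98
14,-0.962,15.57,0.099,12.65,13.12,13.39,14.12,14.60,15.57,16.69,17.35,18.59,19.12,20.20
14.5,-0.979,15.73,0.099,12.79,13.26,13.53,14.27,14.75,15.73,16.85,17.52,18.77,19.30,20.39
15,-0.995,15.86,0.098,12.91,13.39,13.65,14.39,14.87,15.86,16.99,17.66,18.91,19.45,20.55
15.5,-1.010,15.97,0.098,13.01,13.49,13.76,14.50,14.98,15.97,17.10,17.77,19.04,19.58,20.68
16,-1.025,16.06,0.097,13.10,13.58,13.84,14.59,15.07,16.06,17.19,17.87,19.13,19.68,20.79
17,-1.054,16.17,0.097,13.20,13.68,13.95,14.69,15.18,16.17,17.30,17.98,19.25,19.79,20.91
17.5,-1.067,16.18,0.097,13.23,13.70,13.97,14.71,15.19,16.18,17.31,17.99,19.27,19.81,20.93
18,-1.081,16.18,0.097,13.23,13.71,13.97,14.71,15.19,16.18,17.31,17.99,19.26,19.80,20.93
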