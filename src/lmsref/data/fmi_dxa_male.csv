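age,L,M,S,P1,P3,P5,P15,P25,P50,P75,P85,P95,P97,P99
5,-0.234,3.54,0.233,2.20,2.36,2.46,2.76,2.99,3.54,4.22,4.60,5.25,5.51,6.02
5.5,-0.323,3.66,0.248,2.24,2.41,2.51,2.82,3.06,3.66,4.43,4.87,5.63,5.94,6.55
6,-0.401,3.79,0.264,2.29,2.45,2.55,2.88,3.13,3.79,4.65,5.16,6.05,6.42,7.14
6.5,-0.466,3.93,0.279,2.33,2.50,2.61,2.95,3.22,3.93,4.90,5.48,6.52,6.95,7.83
7,-0.518,4.09,0.294,2.39,2.57,2.68,3.03,3.32,4.09,5.18,5.84,7.06,7.58,8.62
7.5,-0.554,4.26,0.309,2.45,2.63,2.74,3.11,3.42,4.26,5.48,6.23,7.63,8.24,9.48
8,-0.574,4.41,0.323,2.50,2.68,2.80,3.19,3.51,4.41,5.75,6.59,8.19,8.88,10.33
8.5,-0.584,4.55,0.335,2.54,2.73,2.85,3.25,3.58,4.55,6.01,6.94,8.72,9.50,11.14
9,-0.586,4.67,0.347,2.57,2.76,2.88,3.30,3.65,4.67,6.24,7.25,9.20,10.06,11.88
9.5,-0.584,4.78,0.357,2.59,2.79,2.91,3.34,3.71,4.78,6.45,7.53,9.63,10.56,12.55
10,-0.580,4.89,0.366,2.62,2.82,2.95,3.39,3.77,4.89,6.66,7.80,10.04,11.03,13.15
10.5,-0.573,4.98,0.373,2.64,2.84,2.97,3.42,3.81,4.98,6.82,8.03,10.37,11.41,13.62
11,-0.563,5.01,0.379,2.63,2.84,2.97,3.42,3.82,5.01,6.91,8.14,10.55,11.61,13.87
11.5,-0.550,4.97,0.384,2.59,2.79,2.92,3.37,3.77,4.97,6.88,8.12,10.53,11.59,13.84
12,-0.532,4.85,0.388,2.51,2.71,2.84,3.28,3.67,4.85,6.75,7.98,10.34,11.37,13.54
12.5,-0.511,4.71,0.392,2.41,2.61,2.73,3.16,3.54,4.71,6.56,7.76,10.04,11.02,13.07
13,-0.486,4.55,0.394,2.32,2.50,2.62,3.04,3.41,4.55,6.36,7.51,9.69,10.62,12.53
13.5,-0.458,4.41,0.396,2.23,2.41,2.53,2.94,3.30,4.41,6.17,7.29,9.35,10.22,12.00
14,-0.428,4.31,0.398,2.16,2.34,2.45,2.85,3.21,4.31,6.02,7.10,9.06,9.88,11.53
14.5,-0.395,4.23,0.399,2.10,2.28,2.39,2.79,3.15,4.23,5.91,6.95,8.82,9.59,11.12
15,-0.359,4.19,0.399,2.07,2.24,2.36,2.75,3.11,4.19,5.84,6.85,8.64,9.36,10.79
15.5,-0.322,4.17,0.398,2.05,2.22,2.34,2.74,3.09,4.17,5.81,6.79,8.51,9.19,10.52
16,-0.283,4.17,0.398,2.03,2.21,2.33,2.73,3.09,4.17,5.80,6.76,8.41,9.06,10.30
16.5,-0.242,4.20,0.397,2.03,2.21,2.33,2.74,3.10,4.20,5.82,6.76,8.35,8.97,10.14
17,-0.201,4.24,0.395,2.03,2.22,2.34,2.76,3.13,4.24,5.85,6.78,8.33,8.91,10.02
17.5,-0.160,4.29,0.394,2.04,2.23,2.35,2.78,3.16,4.29,5.91,6.83,8.33,8.89,9.94
18,-0.119,4.35,0.393,2.06,2.25,2.37,2.81,3.20,4.35,5.98,6.89,8.35,8.89,9.90
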