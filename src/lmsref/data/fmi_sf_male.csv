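age,L,M,S,P1,P3,P5,P15,P25,P50,P75,P85,P95,P97,P99
5,-0.188,1.98,0.235,1.15,1.28,1.35,1.55,1.69,1.98,2.33,2.55,2.99,3.19,3.63
5.5,-0.223,2.06,0.269,1.14,1.27,1.35,1.57,1.72,2.06,2.48,2.75,3.28,3.52,4.05
6,-0.255,2.14,0.304,1.12,1.26,1.34,1.58,1.76,2.14,2.65,2.98,3.66,3.98,4.68
6.5,-0.283,2.24,0.341,1.09,1.24,1.33,1.60,1.79,2.24,2.83,3.24,4.11,4.53,5.48
7,-0.307,2.33,0.376,1.08,1.23,1.33,1.62,1.83,2.33,3.04,3.53,4.63,5.18,6.46
7.5,-0.327,2.44,0.408,1.07,1.23,1.33,1.64,1.87,2.44,3.25,3.85,5.20,5.90,7.60
8,-0.343,2.55,0.435,1.07,1.24,1.34,1.68,1.93,2.55,3.47,4.16,5.79,6.66,8.83
8.5,-0.355,2.66,0.455,1.08,1.26,1.37,1.72,1.99,2.66,3.69,4.46,6.36,7.39,10.06
9,-0.364,2.77,0.470,1.10,1.29,1.40,1.77,2.05,2.77,3.88,4.74,6.88,8.06,11.19
9.5,-0.370,2.88,0.480,1.13,1.32,1.44,1.82,2.12,2.88,4.06,4.99,7.32,8.63,12.15
10,-0.374,2.97,0.485,1.16,1.36,1.48,1.87,2.18,2.97,4.21,5.19,7.67,9.07,12.88
10.5,-0.376,3.05,0.487,1.19,1.39,1.52,1.92,2.24,3.05,4.34,5.35,7.92,9.38,13.36
11,-0.376,3.12,0.486,1.22,1.42,1.55,1.97,2.29,3.12,4.43,5.46,8.09,9.58,13.63
11.5,-0.374,3.18,0.485,1.24,1.45,1.58,2.01,2.34,3.18,4.51,5.55,8.19,9.69,13.75
12,-0.372,3.22,0.482,1.26,1.47,1.61,2.04,2.37,3.22,4.56,5.60,8.25,9.74,13.76
12.5,-0.368,3.25,0.480,1.28,1.49,1.63,2.06,2.40,3.25,4.59,5.64,8.27,9.75,13.71
13,-0.364,3.28,0.478,1.29,1.51,1.64,2.08,2.41,3.28,4.62,5.66,8.27,9.73,13.63
13.5,-0.360,3.29,0.476,1.30,1.51,1.65,2.09,2.43,3.29,4.63,5.67,8.26,9.70,13.52
14,-0.356,3.30,0.474,1.30,1.52,1.66,2.10,2.44,3.30,4.64,5.67,8.24,9.66,13.41
14.5,-0.352,3.31,0.473,1.31,1.53,1.67,2.11,2.45,3.31,4.64,5.67,8.22,9.62,13.31
15,-0.347,3.32,0.472,1.31,1.53,1.67,2.11,2.45,3.32,4.65,5.67,8.20,9.59,13.22
15.5,-0.342,3.33,0.471,1.31,1.53,1.67,2.12,2.46,3.33,4.66,5.67,8.18,9.56,13.14
16,-0.338,3.33,0.471,1.31,1.54,1.68,2.12,2.47,3.33,4.66,5.68,8.18,9.54,13.08
16.5,-0.333,3.34,0.471,1.31,1.54,1.68,2.13,2.47,3.34,4.67,5.69,8.18,9.54,13.05
17,-0.328,3.35,0.471,1.31,1.54,1.68,2.13,2.48,3.35,4.69,5.70,8.19,9.55,13.05
17.5,-0.323,3.36,0.472,1.31,1.54,1.68,2.13,2.48,3.36,4.70,5.72,8.22,9.58,13.09
18,-0.319,3.37,0.473,1.31,1.54,1.68,2.14,2.49,3.37,4.72,5.75,8.27,9.64,13.17
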