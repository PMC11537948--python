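age,L,M,S,P1,P3,P5,P15,P25,P50,P75,P85,P95,P97,P99
5,-1.106,4.07,0.202,2.79,2.97,3.07,3.37,3.59,4.07,4.72,5.16,6.16,6.66,7.89
5.5,-1.002,4.27,0.211,2.86,3.06,3.17,3.50,3.74,4.27,4.98,5.47,6.55,7.10,8.41
6,-0.908,4.46,0.223,2.92,3.13,3.25,3.62,3.88,4.46,5.25,5.79,6.98,7.57,9.01
6.5,-0.820,4.65,0.240,2.93,3.17,3.30,3.71,3.99,4.65,5.53,6.14,7.49,8.17,9.81
7,-0.740,4.83,0.263,2.91,3.17,3.32,3.77,4.09,4.83,5.84,6.54,8.12,8.93,10.89
7.5,-0.665,5.00,0.289,2.87,3.14,3.31,3.80,4.16,5.00,6.16,6.98,8.84,9.80,12.17
8,-0.595,5.16,0.314,2.81,3.11,3.29,3.83,4.23,5.16,6.47,7.41,9.57,10.68,13.46
8.5,-0.529,5.32,0.334,2.77,3.09,3.28,3.87,4.30,5.32,6.77,7.81,10.20,11.44,14.50
9,-0.466,5.48,0.348,2.76,3.10,3.30,3.93,4.39,5.48,7.03,8.13,10.66,11.96,15.14
9.5,-0.408,5.63,0.354,2.77,3.12,3.34,4.00,4.48,5.63,7.24,8.38,10.95,12.25,15.37
10,-0.352,5.78,0.355,2.80,3.17,3.40,4.09,4.59,5.78,7.42,8.57,11.11,12.36,15.32
10.5,-0.299,5.93,0.351,2.85,3.24,3.48,4.20,4.71,5.93,7.57,8.71,11.17,12.36,15.10
11,-0.248,6.07,0.344,2.92,3.33,3.57,4.31,4.84,6.07,7.71,8.82,11.17,12.29,14.82
11.5,-0.200,6.21,0.336,3.00,3.42,3.67,4.43,4.97,6.21,7.83,8.90,11.15,12.20,14.52
12,-0.153,6.34,0.327,3.09,3.52,3.78,4.56,5.11,6.34,7.93,8.98,11.11,12.09,14.22
12.5,-0.109,6.47,0.317,3.19,3.63,3.90,4.69,5.24,6.47,8.04,9.04,11.07,11.99,13.96
13,-0.066,6.60,0.307,3.28,3.74,4.02,4.82,5.38,6.60,8.14,9.11,11.04,11.91,13.74
13.5,-0.025,6.73,0.299,3.38,3.85,4.13,4.94,5.51,6.73,8.24,9.19,11.04,11.86,13.57
14,0.014,6.86,0.292,3.47,3.95,4.24,5.07,5.63,6.86,8.35,9.27,11.06,11.84,13.47
14.5,0.053,6.98,0.286,3.55,4.05,4.34,5.18,5.75,6.98,8.46,9.36,11.10,11.86,13.42
15,0.090,7.10,0.281,3.62,4.13,4.43,5.29,5.86,7.10,8.57,9.47,11.18,11.91,13.41
15.5,0.125,7.22,0.278,3.68,4.20,4.51,5.38,5.97,7.22,8.69,9.59,11.27,11.99,13.46
16,0.160,7.34,0.277,3.72,4.26,4.58,5.47,6.07,7.34,8.82,9.71,11.38,12.09,13.54
16.5,0.193,7.45,0.276,3.76,4.32,4.64,5.56,6.17,7.45,8.95,9.84,11.51,12.22,13.65
17,0.226,7.57,0.276,3.78,4.36,4.69,5.63,6.26,7.57,9.08,9.98,11.66,12.36,13.78
17.5,0.257,7.68,0.277,3.80,4.39,4.73,5.70,6.34,7.68,9.22,10.13,11.81,12.52,13.93
18,0.288,7.79,0.278,3.81,4.42,4.77,5.77,6.42,7.79,9.35,10.28,11.98,12.68,14.10
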