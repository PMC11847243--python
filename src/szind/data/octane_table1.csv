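row,SDZ,SDE,SDD,AcentFac,S,M1,M2,M3
1,27.48,14.21,15.00,0.40,111.00,40.68,17.97,96.30
2,31.29,14.37,17.33,0.38,109.84,32.65,15.96,68.47
3,32.36,14.38,16.67,0.37,111.26,34.24,16.42,73.27
4,32.63,14.42,16.67,0.37,109.32,32.74,16.04,68.20
5,36.44,14.40,18.67,0.35,108.02,28.15,14.92,51.99
6,36.17,14.40,19.00,0.34,106.98,28.61,15.02,53.75
7,35.10,14.37,19.67,0.36,105.72,24.60,13.95,40.66
8,37.24,14.43,18.00,0.34,106.59,30.14,15.52,57.77
9,36.17,14.37,21.75,0.34,103.42,29.74,15.23,58.35
10,37.50,14.43,20.50,0.32,104.74,32.82,16.18,67.13
11,33.70,14.40,16.00,0.36,109.43,27.81,14.84,50.79
12,44.86,15.00,27.50,0.26,93.06,9.59,8.76,2.54
13,40.25,14.83,20.67,0.32,102.39,16.27,11.20,18.20
14,41.05,14.83,22.83,0.30,101.31,19.91,12.19,29.84
15,39.98,14.75,24.08,0.30,104.09,17.81,11.65,22.58
16,41.31,14.92,22.25,0.29,102.06,18.97,12.00,26.36
17,38.57,14.92,19.25,0.31,101.48,16.27,11.30,17.50
18,37.50,14.83,18.00,0.33,106.06,15.45,10.98,15.69
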