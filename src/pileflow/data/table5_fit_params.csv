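sample,a,b,c,a_plus_b,aufc
1,-36.85,25.05,0.43,-11.79,26031.05
2,-46.14,30.57,0.40,-15.57,26326.58
3,-36.95,21.26,0.45,-15.70,24242.23
4,-41.38,27.56,0.40,-13.81,25211.94
5,-45.18,30.37,0.39,-14.81,26181.58
6,-23.75,14.11,0.50,-9.64,21505.26
7,-35.44,21.73,0.45,-13.71,24494.15
8,-39.72,26.23,0.42,-13.50,26183.06
9,-39.30,26.23,0.42,-13.07,25623.30
10,-41.21,26.06,0.42,-15.16,25164.99
11,-41.11,24.32,0.43,-16.79,25313.01
12,-42.45,25.18,0.43,-17.27,24918.38
13,-36.97,27.37,0.41,-9.61,26429.78
14,-57.80,41.95,0.34,-15.85,26903.19
15,-35.86,30.09,0.39,-5.77,27293.46
16,-36.16,23.92,0.42,-12.23,23353.74
17,-38.38,29.08,0.40,-9.29,27599.63
18,-28.46,21.37,0.43,-7.09,22905.91
19,-35.44,27.27,0.42,-8.17,27146.24
20,-44.48,35.10,0.38,-9.39,28408.06
21,-37.71,32.49,0.39,-5.22,27732.51
22,-35.58,27.30,0.42,-8.28,27499.81
23,-38.33,31.85,0.39,-6.48,27690.18
24,-39.49,30.95,0.39,-8.54,27571.28
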