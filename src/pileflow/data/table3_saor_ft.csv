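sample,saor_deg,ft_s
1,38.77,18.31
2,37.14,18.62
3,34.78,19.75
4,34.02,20.33
5,39.77,19.15
6,34.28,22.83
7,40.02,19.78
8,39.10,19.10
9,36.45,18.95
10,36.10,18.84
11,36.08,18.88
12,35.84,18.62
13,35.54,11.72
14,29.38,10.70
15,30.02,9.76
16,31.93,13.80
17,32.75,10.49
18,31.38,14.79
19,33.85,12.32
20,32.29,10.70
21,29.25,10.55
22,34.65,11.73
23,29.44,9.64
24,32.90,10.60
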