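sample,amplitude_px,wavelength_frames,count
1,5.47,25.17,18.00
2,7.00,23.29,24.00
3,7.54,22.73,26.00
4,5.39,22.86,28.00
5,5.38,22.27,26.00
6,6.07,20.03,32.00
7,5.09,24.94,18.00
8,7.43,23.86,21.00
9,6.98,24.37,19.00
10,5.71,22.61,18.00
11,6.65,22.05,21.00
12,9.07,20.67,15.00
13,6.08,19.11,35.00
14,4.54,17.00,32.00
15,3.80,21.56,25.00
16,7.51,21.45,29.00
17,7.37,20.00,26.00
18,7.96,22.24,29.00
19,6.94,19.08,24.00
20,6.62,17.96,27.00
21,8.52,15.19,32.00
22,7.19,15.55,29.00
23,4.79,20.64,22.00
24,8.29,21.33,21.00
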