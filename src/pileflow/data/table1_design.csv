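sample,particle_size_um,moisture_pct,glidant_code,particle_class
1,1100.0,3.0,-1.0,-1
2,1100.0,1.0,1.0,-1
3,350.0,3.0,1.0,-1
4,350.0,1.0,-1.0,-1
5,725.0,2.0,0.0,-1
6,194.7,2.0,0.0,-1
7,1255.3,2.0,0.0,-1
8,725.0,0.6,0.0,-1
9,725.0,3.4,0.0,-1
10,725.0,2.0,-1.4,-1
11,725.0,2.0,1.4,-1
12,725.0,2.0,0.0,-1
13,1100.0,3.0,-1.0,1
14,1100.0,1.0,1.0,1
15,350.0,3.0,1.0,1
16,350.0,1.0,-1.0,1
17,725.0,2.0,0.0,1
18,194.7,2.0,0.0,1
19,1255.3,2.0,0.0,1
20,725.0,0.6,0.0,1
21,725.0,3.4,0.0,1
22,725.0,2.0,-1.4,1
23,725.0,2.0,1.4,1
24,725.0,2.0,0.0,1
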