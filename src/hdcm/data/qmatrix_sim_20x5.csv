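item,V1,V2,V3,V4,V5
1,1,0,0,0,0
2,0,1,0,0,0
3,0,0,1,0,0
4,0,0,0,1,0
5,0,0,0,0,1
6,1,1,0,0,0
7,0,0,0,1,1
8,0,1,1,0,0
9,0,0,1,1,0
10,0,0,0,1,1
11,1,1,1,0,0
12,1,1,0,0,1
13,1,0,0,1,1
14,1,0,1,1,0
15,0,0,1,0,1
16,1,0,1,0,0
17,0,1,0,1,0
18,0,1,0,1,0
19,0,1,0,0,1
20,1,0,1,0,1
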