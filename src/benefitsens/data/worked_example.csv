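subject,X,Y,Y0,Y1
1,1,1,1,1
2,1,1,1,1
3,1,1,1,1
4,1,1,1,1
5,1,1,1,1
6,1,1,1,1
7,1,1,0,1
8,1,1,0,1
9,1,1,0,1
10,1,0,1,0
11,1,0,1,0
12,1,0,1,0
13,1,0,0,0
14,1,0,0,0
15,1,0,0,0
16,1,0,0,0
17,1,0,0,0
18,1,0,0,0
19,0,1,1,1
20,0,1,1,1
21,0,1,1,1
22,0,1,1,0
23,0,1,1,0
24,0,1,1,0
25,0,1,1,0
26,0,1,1,0
27,0,1,1,0
28,0,0,0,1
29,0,0,0,1
30,0,0,0,1
31,0,0,0,1
32,0,0,0,1
33,0,0,0,1
34,0,0,0,0
35,0,0,0,0
36,0,0,0,0
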