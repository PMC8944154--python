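time,status,x
9,1,1
13,1,1
13,0,1
18,1,1
23,1,1
28,0,1
31,1,1
34,1,1
45,0,1
48,1,1
161,0,1
5,1,0
5,1,0
8,1,0
8,1,0
12,1,0
16,0,0
23,1,0
27,1,0
30,1,0
33,1,0
43,1,0
45,1,0
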