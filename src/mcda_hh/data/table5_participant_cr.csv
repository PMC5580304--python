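participant,cr
1,0.09
2,0.08
3,0.09
4,0.07
5,0.09
6,0.07
7,0.08
8,0.08
9,0.08
10,0.07
11,0.09
12,0.08
13,0.09
14,0.07
15,0.08
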