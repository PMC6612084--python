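run,A,B,C,D
1,1,1,1,1
2,1,2,2,2
3,1,3,3,3
4,2,1,2,3
5,2,2,3,1
6,2,3,1,2
7,3,1,3,2
8,3,2,1,3
9,3,3,2,1
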