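condition,A,B,C,D,defective,good,sample
1,1,1,1,1,7,23,30
2,1,2,2,2,6,24,30
3,1,3,3,3,10,20,30
4,2,1,2,3,10,20,30
5,2,2,3,1,16,14,30
6,2,3,1,2,9,21,30
7,3,1,3,2,11,19,30
8,3,2,1,3,12,18,30
9,3,3,2,1,5,25,30
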