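id,fold,P,PP,TP,FN,FP
2,0,154,166,134,21,32
1,0,125,141,118,7,23
3,0,112,115,108,4,7
7,0,106,98,94,13,4
6,1,100,134,96,4,38
16,1,100,123,76,26,47
5,1,238,247,193,45,54
13,1,103,120,51,52,69
10,2,115,121,110,5,11
12,2,111,136,90,23,46
15,2,103,148,67,57,81
0,2,104,119,101,3,18
8,3,226,238,31,195,207
11,3,270,285,263,7,22
4,3,102,119,58,44,61
14,4,263,264,231,32,33
17,4,225,236,149,80,87
9,4,123,121,107,16,14
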