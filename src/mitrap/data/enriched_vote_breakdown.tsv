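votes	n_mirs
0	93
1	175
2	48
3	14
4	14
5	7
6	1
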