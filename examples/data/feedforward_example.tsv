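%vertices: 1 2 3 4 5 6 7 8
1	2
4	3
4	5
6	3
6	5
7	4
8	6
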