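PIKAA ACDEFGHIKLMNPQRSTVWY
start
24 E NATAA
5 E NATAA
6 E NATAA
22 E NATAA
27 E NATAA
29 E NATAA
20 E PIKAA R
28 E PIKAA E
30 E PIKAA L
1 E NOTAA ED
4 E NOTAA ED
7 E NOTAA ED
8 E NOTAA ED
13 E NOTAA ED
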