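>MA0212.1 bcd
A [  2  0 34  1  0  1  0  6 ]
C [  8  2  0  0  0 33  3  8 ]
G [  3  1  1  0 35  0  1 14 ]
T [ 22 32  0 34  0  1 31  7 ]
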