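>MA0049.1 hb
A [  3 35  2 37  3 37 36  4 ]
C [  6  0 33  0  1  0  0  3 ]
G [  2  2  1  1  0  1  1  2 ]
T [ 27  1  2  0 34  0  1 29 ]
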