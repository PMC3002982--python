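(((melanogaster:0.06,simulans:0.05):0.04,pseudoobscura:0.12):0.03,(virilis:0.1,grimshawi:0.11):0.05);
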