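locus,genome,chromosome,locus_scope
BH1,1236,154,20
HH2,47,9,2
HH3,28,26,14
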