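locus,stage,chrom,start_bp,end_bp
BH1,original,7,42545709,47002161
BH1,refined,7,42811272,47002161
HH2,original,1,93172083,98133752
HH2,refined,1,94860836,96553339
HH3,original,8,92485682,96594716
HH3,refined,8,95057877,95468310
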