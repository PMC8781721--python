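response,observed
TPC,1985
TFC,1364
ABTS,122
DPPH,174
FRAP,468
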