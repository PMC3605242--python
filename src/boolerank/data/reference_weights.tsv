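attribute	r_phi	p_value
Meth	0.021944	0.0803
PTM	0.046598	0.0004
PK	0.037870	0.0030
SP	0.036727	0.0026
TS	0.038675	0.0019
Hub	0.072986	0.0001
TF	0.048745	0.0002
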