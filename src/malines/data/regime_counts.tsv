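regime	m	lines	callable_sites	generations	transitions	transversions
YoungT1	12	6	90566554	3	12	0
PeakT2	5	6	93817854	3	5	0
OldT5	20	6	92742405	3	19	1
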