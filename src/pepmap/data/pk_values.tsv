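# Bjellqvist-style pK set used for isoelectric-point bisection.
# group: side chains (positive/negative), termini defaults, and
# residue-specific terminal overrides.
group	key	pk
positive	Nterm	7.50
positive	K	10.00
positive	R	12.00
positive	H	5.98
negative	Cterm	3.55
negative	D	4.05
negative	E	4.45
negative	C	9.00
negative	Y	10.00
nterm_override	A	7.59
nterm_override	M	7.00
nterm_override	S	6.93
nterm_override	P	8.36
nterm_override	T	6.82
nterm_override	V	7.44
nterm_override	E	7.70
cterm_override	D	4.55
cterm_override	E	4.75
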