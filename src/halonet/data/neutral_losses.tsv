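name	formula	context
H2O	H2O
HBr	HBr
HCl	HCl
ketene	C2H2O
NaOH	HNaO	sodiated precursors only
Br	Br	radical bromine loss from even-electron ions
C2H6	C2H6
1-bromopropa-1,2-diene	C3H3Br
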