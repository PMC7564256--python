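id	formula	charge	phase
oleate	C18H33O2	-1	aqueous
acetate	C2H3O2	-1	aqueous
H2	H2	0	gas
CH4	CH4	0	gas
HCO3	CHO3	-1	aqueous
FeOH3	Fe(OH)3	0	solid, amorphous ferric hydroxide
Fe2	Fe	2	aqueous
H2O	H2O	0	liquid
H	H	1	aqueous proton
e	-	-1	free electron (pseudo-species)
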