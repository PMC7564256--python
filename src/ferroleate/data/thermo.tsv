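# Standard transformed Gibbs energies of formation (kJ/mol, 25 degC, pH 7)
# for the methanogenic species, after the classic anaerobic bioenergetics
# compilations. The proton entry is the pH 7 transformed value (-RT ln 1e-7).
# Oleate and the Fe(OH)3/Fe2+ couple are deliberately absent: no consistent
# published triple reproduces the printed elementary values exactly, so
# formation-energy computation stays a tolerance cross-check for the
# methanogenic reactions only.
species	delta_gf0_kj	citation
H2	0.0	element reference state
H2O	-237.17	Thauer-style compilation
HCO3	-586.85	Thauer-style compilation
CH4	-50.75	Thauer-style compilation (gas)
acetate	-369.41	Thauer-style compilation
H	-39.87	pH 7 transformed proton
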