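# Elementary half-reactions of anaerobic oleate degradation under
# iron-reducing (IR) and methanogenic (M) conditions, with standard
# transformed Gibbs energies (kJ per reaction as written; 1 mol/L solutes,
# 1e5 Pa gas, 25 degC, pH 7).
label	condition	equation	delta_g0_kj
r1	neutral	oleate + 16 H2O -> 9 acetate + 15 H2 + 8 H	325.7
r2	IR	acetate + 8 FeOH3 + 15 H -> 2 HCO3 + 8 Fe2 + 20 H2O	-32.9
r3	M	acetate + H2O -> HCO3 + CH4	-31.0
r4	IR	H2 + 2 FeOH3 + 4 H -> 2 Fe2 + 6 H2O	-34.4
r5	M	H2 + 0.25 HCO3 + 0.25 H -> 0.25 CH4 + 0.75 H2O	-33.9
eq10	IR	acetate + 4 H2O -> 2 HCO3 + 9 H + 8 e
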