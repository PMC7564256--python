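# ferroleate

Stoichiometric and thermodynamic accounting for anaerobic oleate
degradation under iron-reducing and methanogenic conditions.

Long-chain fatty acids (LCFA) such as oleate (C18:1) are degraded
anaerobically by syntrophic consortia: β-oxidizing bacteria split the acid
into acetate and hydrogen, and partners — hydrogenotrophic/acetoclastic
methanogens or iron(III)-reducing bacteria — keep the intermediates low
enough for the thermodynamics to work. Interpreting such incubations is an
exercise in bookkeeping: composing half-reactions with exact coefficients,
combining ΔG°′ values, partitioning electron equivalents between CH₄ and
Fe(II), predicting theoretical yields, and summarizing cumulative
production curves. `ferroleate` packages that bookkeeping for
bioprocess/anaerobic-digestion researchers, with a synthetic incubation
generator so every stage is testable without measured data.

At its core are the composed conversions of syntrophic oleate degradation,
e.g. the overall methanogenic route obtained as r1 + 9 r3 + 15 r5
(β-oxidation + 9× acetoclastic + 15× hydrogenotrophic methanogenesis):

C₁₈H₃₃O₂⁻ + 13.75 H₂O → 5.25 HCO₃⁻ + 12.75 CH₄ + 4.25 H⁺,  ΔG°′ = −461.8 kJ

with exact rational coefficients (12.75 = 51/4), and the electron
convention H₂ = 2 e⁻, CH₄ = acetate = 8 e⁻, Fe(OH)₃ → Fe²⁺ = 1 e⁻, giving
102 e⁻ per oleate on full oxidation. See `docs/methods.md` for the model,
conventions and numerical choices.

## Worked example

Predict yields for a 3 mmol L⁻¹ oleate dose and back-calculate oleate
consumption from blank-corrected Fe(II) (treatment 60, blank 23 mmol L⁻¹):

```text
$ ferroleate predict --dose 3 --fe2 60 --blank-fe2 23
theoretical_methane: 38.25 mmol/L    [theoretical_product, overall methanogenic route (r1 + 9 r3 + 15 r5)]
methane_from_hydrogen: 11.25 mmol/L    [theoretical_product, acetogenic H2 route (r1 + 15 r5)]
methane_with_diversion: 7.5 mmol/L    [partitioned_methane, fraction 1/3 of H2 electrons to Fe(III)]
blank_corrected_fe3_consumption: 37.0 mmol/L    [blank-equivalence: treatment 60.0 - blank 23.0 (assumed 1:1)]
inferred_oleate_consumption: 1.2 mmol/L    [infer_substrate_from_acceptor via r6 (30 Fe(OH)3 per oleate)]
```

Reading: full conversion of the dose would give 38.25 mmol L⁻¹ CH₄; if only
the β-oxidation hydrogen is methanized the cap is 11.25, and diverting one
third of those electrons to Fe(III) reduction lowers it to 7.5. The
blank-corrected 37 mmol L⁻¹ of Fe(III) reduction corresponds to
1.2 mmol L⁻¹ of oleate oxidized to acetate (30 Fe(OH)₃ per oleate).

Electron accounting for an enrichment fed 1 mmol L⁻¹ oleate that produced
1.2 mmol L⁻¹ CH₄ and left 3.4 mmol L⁻¹ acetate:

```text
$ ferroleate predict --dose 1 --ch4 1.2 --acetate 3.4
...
methane_electron_fraction_acetogenic: 32 %    [methane_electron_fraction, scope=acetogenic]
methane_electron_fraction_full: 9 %    [methane_electron_fraction, scope=full]
expected_fe2_from_h2: 20.4 mmol/L    [expected_fe2: surplus H2 x 2 Fe(II)/H2 (r1, r5, r4)]
acetate_available_for_iron: 5.6 mmol/L    [expected_fe2: 9 x dose - measured acetate (r1)]
expected_fe2_from_acetate: 44.8 mmol/L    [expected_fe2: available acetate x 8 Fe(II) (r2)]
expected_fe2_total: 65.2 mmol/L    [expected_fe2: H2-derived + acetate-derived]
```

The methane captured 32 % of the electrons available as β-oxidation H₂
(9 % of all 102 e⁻ per oleate); the rest should appear as 65.2 mmol L⁻¹ of
Fe(II) — 20.4 from surplus H₂ plus 44.8 from the 5.6 mmol L⁻¹ of acetate
not seen in the medium.

Simulate a triplicate incubation and summarize it:

```text
$ ferroleate simulate --scenario suspended-sludge --seed 1 --out sim/
$ ferroleate account --timeseries sim/suspended-sludge.tsv --dose 3
IR/CH4: max 20.3 mmol/L, lag 5.7 d, recovery 53%    [max_cumulative/lag_time/window_rate]
...
M/CH4: max 27.5 mmol/L, lag 13.3 d, recovery 72%    [max_cumulative/lag_time/window_rate]
```

The methanogenic series recovers its generative parameters (asymptote 28,
lag 13 d) within noise; recovery is the maximum cumulative methane over
the 38.25 mmol L⁻¹ theoretical maximum.

Other subcommands: `ferroleate balance` validates the bundled reaction
table (elemental + charge balance, exact); `ferroleate compose "1 + 9*3 +
15*5"` composes arbitrary recipes and reports their ΔG°′. All subcommands
accept `--config file.yaml` for defaults and `--out` for machine-readable
JSON sidecars with provenance strings.

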