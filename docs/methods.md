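# Methods

## Scope and model

`ferroleate` implements the stoichiometric and thermodynamic accounting used
to interpret anaerobic degradation of oleate (the C18:1 long-chain fatty
acid) by mixed methanogenic communities amended with amorphous ferric
hydroxide. The system is described by five elementary conversions:

1. syntrophic β-oxidation of oleate,
   C₁₈H₃₃O₂⁻ + 16 H₂O → 9 C₂H₃O₂⁻ + 15 H₂ + 8 H⁺ (ΔG°′ = +325.7 kJ);
2. acetate oxidation on Fe(III),
   C₂H₃O₂⁻ + 8 Fe(OH)₃ + 15 H⁺ → 2 HCO₃⁻ + 8 Fe²⁺ + 20 H₂O (−32.9 kJ);
3. acetoclastic methanogenesis, C₂H₃O₂⁻ + H₂O → HCO₃⁻ + CH₄ (−31.0 kJ);
4. H₂ oxidation on Fe(III), H₂ + 2 Fe(OH)₃ + 4 H⁺ → 2 Fe²⁺ + 6 H₂O (−34.4 kJ);
5. hydrogenotrophic methanogenesis,
   H₂ + ¼ HCO₃⁻ + ¼ H⁺ → ¼ CH₄ + ¾ H₂O (−33.9 kJ);

plus the explicit acetate-oxidation half-reaction
C₂H₃O₂⁻ + 4 H₂O → 2 HCO₃⁻ + 9 H⁺ + 8 e⁻ used for electron counting. All
ΔG°′ are standard transformed values (1 mol L⁻¹ solutes, 10⁵ Pa gas, 25 °C,
pH 7), per reaction as written. The four composite conversions are exact
rational combinations of the elementary ones:

| net conversion | recipe |
|---|---|
| oleate → acetate on Fe(III) | r1 + 15 r4 |
| oleate → CO₂ on Fe(III) | r1 + 9 r2 + 15 r4 |
| oleate → acetate + CH₄ | r1 + 15 r5 |
| oleate → CH₄ (overall) | r1 + 9 r3 + 15 r5 |

The multipliers are what the conventional shorthand ("6 = 1 + 4") leaves
implicit; only the fully multiplied recipes cancel the shared H₂ and
acetate pools and reproduce the published coefficients (30 or 102 Fe(OH)₃
per oleate, 12.75 CH₄ per oleate, and so on).

### Electron convention

Electron equivalents are counted with Fe(OH)₃/Fe²⁺ as the reference
one-electron couple: H₂ = 2 e⁻, CH₄ = 8 e⁻, acetate = 8 e⁻ on full
oxidation to bicarbonate. One oleate therefore carries 30 e⁻ as
β-oxidation hydrogen ("acetogenic" scope) and 102 e⁻ in total ("full"
scope); the identity 102 = 2·15 + 8·9 closes the budget. Electron contents
are always read off a registered oxidation reaction, never hard-coded.

## Numerical choices

* **Exact rational arithmetic.** Stoichiometric coefficients are
  `fractions.Fraction` throughout; 3.75 is stored as 15/4. Balance checks
  demand residuals of exactly zero, with no tolerance. Composition is a
  plain linear sum with removal of zero-net species.
* **ΔG°′ combination.** `combined_delta_g` sums multiplier × ΔG°′ exactly
  (decimal inputs are promoted to rationals) and reports at 1 decimal.
  The composite methanogenic routes reproduce the printed −182.8 and
  −461.8 kJ exactly; the iron-coupled composites combine to −190.3 and
  −486.4 kJ against printed −189.9 and −485.9 — a 0.4–0.5 kJ drift that is
  pure 1-decimal rounding propagation in the source values, so comparisons
  there use a ±0.6 kJ band while the methanogenic pair is asserted exactly.
* **Formation-energy cross-check.** The bundled ΔGf°′ table covers the
  methanogenic species only (H₂ 0, H₂O −237.17, HCO₃⁻ −586.85, CH₄ −50.75,
  acetate⁻ −369.41, H⁺(pH 7) −39.87 kJ mol⁻¹, after the classic anaerobe
  bioenergetics compilations). It reproduces the elementary methanogenesis
  ΔG°′ within ±1.0 kJ and serves as a consistency check, not a source of
  truth: no published, mutually consistent triple of oleate and iron-couple
  formation energies reproduces the printed iron-reaction values exactly,
  and back-deriving them from those values would make the check circular.
* **Temperature/concentration corrections** are deliberately absent: the
  accounting is defined at standard transformed conditions only. No
  activity corrections, no van 't Hoff extrapolation, no E°′ interface.
* **Reporting precision.** Internal arithmetic is unrounded; headline
  reporting uses 1 decimal for concentrations and integer percent for
  electron fractions and recoveries. The published accounting itself
  rounds from unrounded intermediates (its 45.0 vs the computable 44.8
  mmol L⁻¹ Fe(II); recoveries 72/75 vs 73.2/75.8 from the printed maxima),
  so recovery comparisons carry a ±1.5 percentage-point band.
* **Blank correction** subtracts the blank signal 1:1 from the treatment
  (`max(treatment − blank, 0)`, clamped values flagged) — stated as an
  assumption in the output provenance, because it is an assumption, not a
  measurement.
* **Negative intermediate pools** (surplus H₂, unobserved acetate) are
  clamped to zero and flagged rather than raised: measurement noise can
  legitimately produce small negatives.

## Time-series descriptors

Incubation series are tidy tables (treatment, analyte, replicate, day,
mmol L⁻¹); times must be strictly increasing per replicate and negative
readings are clamped with a count. Descriptors:

* **Maximum cumulative product** — maximum over time of the replicate-mean
  concentration.
* **Windowed rate** — per-replicate least-squares slope over a stated day
  window, aggregated as mean ± sample SD (ddof = 1). Rates are computed per
  replicate first; pooling happens only in the summary.
* **Lag time** — tangent-intercept definition: the maximum slope over
  sliding 5-sample least-squares windows of the replicate-mean curve,
  extrapolated back to the initial value. This is the definition implicit
  in the modified-Gompertz parameterization and standard in anaerobic
  biodegradability work; the method tag is recorded in every estimate so a
  threshold-based alternative could be added without breaking outputs.
  Caveat: a curve with near-zero lag starts at the non-negligible value
  A·e^{−e} ≈ 0.066 A, which shifts the tangent-to-baseline intercept up to
  ~1 day past the generative λ; for well-separated lags (≳ 10 d) the bias
  is negligible. Curves that never rise above baseline + noise floor
  (default 0.5 mmol L⁻¹) return an undefined-lag flag.

## Synthetic data generator

The generator emulates the statistical structure of batch incubation
measurements — lag, near-linear rise, plateau, triplicate noise, blank
series, imperfect Fe(II) recovery — so the whole pipeline is testable
without measured data. It is a measurement-level emulation, not a
mechanistic kinetic model of the four guilds.

* **Curve family.** Modified Gompertz,
  y(t) = A·exp(−exp(Rmax·e/A·(λ − t) + 1)); its three parameters are
  exactly the descriptors the analysis estimates (asymptote A, maximum
  rate Rmax, lag λ). Acetate transients (rise then fall) are a production
  curve minus a delayed consumption curve, clamped at zero — a modelling
  choice; the real transient's shape is not parameterized anywhere.
* **Noise** is homoscedastic Gaussian per analyte (default σ = 0.3
  mmol L⁻¹, the magnitude of the reported triplicate SDs), added per
  replicate and clamped at zero with a flag count.
* **Fe(II) recoverability.** Observed Fe(II) = ρ × true Fe(II), default
  ρ = 0.65, emulating the shortfall of HCl-extractable Fe(II) when
  secondary mineralization (magnetite) sequesters part of the pool. ρ is a
  free scenario parameter, not a claimed constant; no speciation chemistry
  is modelled beyond this scalar.
* **Two scenario builders.** `suspended_sludge_scenario()` assigns each
  treatment × analyte its own curve, with the reported descriptors as
  defaults (methanogenic CH₄: A = 28 mmol L⁻¹, Rmax = 1.4 mmol L⁻¹ d⁻¹,
  λ = 13 d; iron-reducing CH₄: A = 22, 0.6, 3; Fe(II) rising to 60 of
  which 23 is blank-equivalent; ρ = 1 since the raw measurements of that
  experiment showed no mineral shortfall). It is the scenario for
  parameter-recovery checks. `stoichiometric_scenario()` instead derives
  every analyte from a single underlying β-oxidation extent curve P(t)
  plus electron-routing fractions (a share φ, default 1/3, of the H₂
  electrons to iron; delayed acetate turnover feeding methanogenesis), so
  8·CH₄ + corrected Fe(II) + 8·acetate = 102·P(t) ≤ 102·dose holds
  identically in noiseless data. The two builders exist because a set of
  independent per-analyte curves matching the reported descriptors cannot
  simultaneously satisfy the pointwise electron budget — the descriptors
  summarize different phases of a shared process. Parameter recovery is
  checked on the first, the budget invariant on the second.
* **Determinism.** Generation iterates treatments/analytes/replicates in
  sorted order from a single `numpy` Generator, so a (scenario, seed) pair
  reproduces bit-exactly; the full ground truth (curve parameters, σ, ρ,
  dose, seed) is embedded in the dataset and written as a JSON sidecar.

What passing synthetic tests do *not* show: correctness on real curves
with heteroscedastic noise, irregular sampling, non-Gompertz kinetics
(diauxic or inhibited phases), or chemical Fe speciation dynamics.

## Problem sizes

Default schedules are 51 daily samples × 3 replicates. The
parameter-recovery property uses 200 seeded datasets (≈ 1 s total); the
composition oracle property checks 1,000 random recipes (< 1 s). The whole
suite runs in a few seconds on one CPU.

## Known limitations

* ΔG°′ only — no in-situ ΔG′; the thermodynamic layer cannot rank
  feasibility at real metabolite concentrations.
* The formation-energy table is incomplete by design (see above), so only
  the methanogenic elementary reactions are cross-checkable from it.
* The lag estimator inherits the tangent definition's baseline sensitivity
  for shallow-lag curves.
* The electron budget audit treats the blank correction and the declared
  dose as exact; it flags violations but cannot attribute them.
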