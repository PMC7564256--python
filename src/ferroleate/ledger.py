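"""Yield prediction and electron-equivalent accounting.

Translates substrate doses into theoretical product concentrations via
composed reaction stoichiometry, partitions the reducing equivalents of
beta-oxidation between Fe(III) reduction and methanogenesis, applies blank
corrections, and computes recovery metrics.

Electron bookkeeping convention (single-electron equivalents, Fe(III)/Fe(II)
as the reference 1 e- couple): H2 = 2 e-, CH4 = 8 e-, acetate = 8 e- on full
oxidation to bicarbonate; one oleate releases 30 e- as H2 during
beta-oxidation ("acetogenic" scope) and 102 e- in total ("full" scope).

Concentrations are mmol/L throughout. Internal arithmetic is unrounded;
reporting precision (1 decimal for concentrations, integer percent for
headline fractions) is applied by callers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Literal, Mapping

from .chem import (
    DEFAULT_ACCEPTOR_ID,
    ChemError,
    Reaction,
    composed_reactions,
    electron_content,
    standard_reactions,
)

__all__ = [
    "LedgerError",
    "DoseSpec",
    "ElectronLedger",
    "FeBalance",
    "RecoveryResult",
    "BlankCorrected",
    "Fe2Expectation",
    "theoretical_product",
    "partitioned_methane",
    "acceptor_demand",
    "blank_correct",
    "infer_substrate_from_acceptor",
    "methane_electron_fraction",
    "expected_fe2",
    "methane_recovery",
    "build_ledger",
    "ELECTRONS_PER_CH4",
    "ELECTRONS_PER_ACETATE",
    "ELECTRONS_PER_H2",
    "ELECTRONS_PER_FE",
]

#: electron equivalents per mole (Fe(III)/Fe(II) = 1 e- reference couple)
ELECTRONS_PER_CH4 = 8
ELECTRONS_PER_ACETATE = 8
ELECTRONS_PER_H2 = 2
ELECTRONS_PER_FE = 1


class LedgerError(ValueError):
    """Inconsistent or unusable accounting inputs."""


@dataclass(frozen=True)
class DoseSpec:
    """Substrate and electron-acceptor dose of an incubation (mmol/L)."""

    substrate_id: str = "oleate"
    substrate_mmol: float = 3.0
    acceptor_id: str = DEFAULT_ACCEPTOR_ID
    acceptor_mmol: float = 0.0

    def __post_init__(self) -> None:
        if self.substrate_mmol < 0 or self.acceptor_mmol < 0:
            raise LedgerError("dose concentrations must be >= 0")


@dataclass(frozen=True)
class BlankCorrected:
    """A blank-subtracted value with a flag when clamping to zero occurred."""

    value: float
    clamped: bool
    provenance: str = ""

    def __float__(self) -> float:
        return self.value


@dataclass(frozen=True)
class RecoveryResult:
    """Measured vs theoretical maximum product and their ratio in percent."""

    measured_mmol: float
    theoretical_mmol: float
    recovery_percent: float
    exceeds_100: bool

    def as_printed(self) -> int:
        """Integer-percent headline value (internal arithmetic unrounded)."""
        return round(self.recovery_percent)


@dataclass(frozen=True)
class Fe2Expectation:
    """Fe(II) expected from the reducing equivalents not captured in CH4.

    ``h2_derived``: Fe(II) from the surplus H2 (beta-oxidation H2 minus H2
    consumed by the measured methane). ``acetate_available``: acetate pool
    not seen in the medium, assumed oxidized on Fe(III).
    """

    h2_derived: float
    acetate_available: float
    acetate_derived: float
    total: float
    clamped_h2: bool = False
    clamped_acetate: bool = False


@dataclass(frozen=True)
class FeBalance:
    """Iron speciation bookkeeping for one treatment (mmol/L)."""

    total_fe: float
    fe2_measured: float
    blank_fe2: float

    def __post_init__(self) -> None:
        if min(self.total_fe, self.fe2_measured, self.blank_fe2) < 0:
            raise LedgerError("iron concentrations must be >= 0")

    @property
    def fe3_by_difference(self) -> float:
        """Fe(III) = total Fe - Fe(II); clamped at zero."""
        return max(self.total_fe - self.fe2_measured, 0.0)

    @property
    def corrected_fe3_consumption(self) -> BlankCorrected:
        """Fe(III) reduction attributable to the added substrate: treatment
        Fe(II) minus the blank Fe(II) (assumed equivalent residual-substrate
        consumption)."""
        return blank_correct(self.fe2_measured, self.blank_fe2)


def _ratio(reaction: Reaction, num_id: str, den_id: str) -> Fraction:
    num = reaction.coeff(num_id)
    den = reaction.coeff(den_id)
    if den == 0:
        raise LedgerError(
            f"species {den_id!r} absent from reaction {reaction.label!r}"
        )
    if num == 0:
        raise LedgerError(
            f"species {num_id!r} absent from reaction {reaction.label!r}"
        )
    return abs(num / den)


def theoretical_product(
    dose: DoseSpec, net_reaction: Reaction, product_id: str
) -> float:
    """Product concentration from complete substrate conversion (mmol/L).

    Returns dose x |product coeff / substrate coeff| of ``net_reaction``.
    The reaction must consume the dosed substrate and produce the product.
    """
    if net_reaction.coeff(dose.substrate_id) >= 0:
        raise LedgerError(
            f"reaction {net_reaction.label!r} does not consume "
            f"{dose.substrate_id!r}"
        )
    if net_reaction.coeff(product_id) <= 0:
        raise LedgerError(
            f"reaction {net_reaction.label!r} does not produce {product_id!r}"
        )
    return dose.substrate_mmol * float(
        _ratio(net_reaction, product_id, dose.substrate_id)
    )


def partitioned_methane(
    dose: DoseSpec,
    fraction_to_acceptor,
    h2_yield_reaction: Reaction | None = None,
) -> float:
    """Methane expected when part of the beta-oxidation electrons go to iron.

    ``fraction_to_acceptor`` of the H2-borne electron equivalents is diverted
    to Fe(III) reduction; the remainder feeds hydrogenotrophic methanogenesis.
    ``h2_yield_reaction`` is the acetogenic+hydrogenotrophic net conversion
    (default: composed r8); methane = (1 - fraction) x its CH4 expectation.
    """
    f = Fraction(fraction_to_acceptor) if not isinstance(
        fraction_to_acceptor, (int, float, Fraction)
    ) else fraction_to_acceptor
    if not 0 <= f <= 1:
        raise LedgerError("fraction_to_acceptor must lie in [0, 1]")
    if h2_yield_reaction is None:
        h2_yield_reaction = composed_reactions()["r8"]
    ch4_max = theoretical_product(dose, h2_yield_reaction, "CH4")
    return (1 - float(f)) * ch4_max


def acceptor_demand(
    product_conc: float,
    oxidation_reaction: Reaction,
    substrate_id: str | None = None,
    acceptor_id: str = DEFAULT_ACCEPTOR_ID,
    registry=None,
) -> float:
    """Acceptor (Fe(OH)3) concentration needed to oxidize ``product_conc``
    mmol/L of an accumulated product via ``oxidation_reaction``.

    When ``substrate_id`` is omitted, the oxidized species is inferred as
    the unique consumed carbon-bearing species of the reaction.
    """
    if product_conc < 0:
        raise LedgerError("product concentration must be >= 0")
    if oxidation_reaction.coeff(acceptor_id) >= 0:
        raise LedgerError(
            f"reaction {oxidation_reaction.label!r} does not consume "
            f"{acceptor_id!r}"
        )
    if substrate_id is None:
        from .chem import standard_registry

        reg = registry if registry is not None else standard_registry()
        organic = [
            sid
            for sid, c in oxidation_reaction.stoich.items()
            if c < 0 and sid in reg and reg[sid].formula.get("C", 0) > 0
        ]
        if len(organic) != 1:
            raise LedgerError(
                "cannot infer the oxidized substrate; pass substrate_id"
            )
        substrate_id = organic[0]
    return product_conc * float(_ratio(oxidation_reaction, acceptor_id, substrate_id))


def blank_correct(treatment_value: float, blank_value: float) -> BlankCorrected:
    """Subtract the blank signal, clamping at zero with a flag.

    Implements the 1:1 blank-equivalence assumption: the blank's signal
    (residual substrate, endogenous decay) is assumed to occur identically
    in the amended treatment.
    """
    if treatment_value < 0 or blank_value < 0:
        raise LedgerError("values must be >= 0")
    raw = treatment_value - blank_value
    return BlankCorrected(
        value=max(raw, 0.0),
        clamped=raw < 0,
        provenance=(
            f"blank-equivalence: treatment {treatment_value} - blank "
            f"{blank_value} (assumed 1:1)"
        ),
    )


def infer_substrate_from_acceptor(
    fe3_consumed: float,
    coupled_reaction: Reaction,
    substrate_id: str = "oleate",
    acceptor_id: str = DEFAULT_ACCEPTOR_ID,
) -> float:
    """Back-calculate substrate consumption from acceptor consumption.

    substrate = fe3_consumed x |substrate coeff / acceptor coeff| of the
    coupled net reaction (exact; callers round to 1 decimal for reporting).
    """
    if fe3_consumed < 0:
        raise LedgerError("acceptor consumption must be >= 0")
    acc = coupled_reaction.coeff(acceptor_id)
    if acc == 0:
        raise LedgerError(
            f"reaction {coupled_reaction.label!r} has zero {acceptor_id!r} "
            "coefficient"
        )
    return fe3_consumed * float(_ratio(coupled_reaction, substrate_id, acceptor_id))


Scope = Literal["acetogenic", "full"]


def _electrons_per_substrate(
    scope: Scope, reactions: Mapping[str, Reaction] | None = None
) -> Fraction:
    """Electron equivalents per mole of oleate under the declared scope.

    acetogenic: electrons carried by the beta-oxidation H2 (2 e- per H2);
    full: all electrons of complete oxidation, read off the composed
    Fe(III)-coupled overall reaction (1 e- per Fe).
    """
    rxns = standard_reactions() if reactions is None else dict(reactions)
    if scope == "acetogenic":
        h2_yield = _ratio(rxns["r1"], "H2", "oleate")
        return ELECTRONS_PER_H2 * h2_yield
    if scope == "full":
        full_ox = composed_reactions(rxns)["r7"]
        return electron_content("oleate", full_ox)
    raise LedgerError(f"unknown scope {scope!r}")


def methane_electron_fraction(
    ch4_mmol: float,
    substrate_mmol: float,
    scope: Scope = "acetogenic",
    reactions: Mapping[str, Reaction] | None = None,
) -> float:
    """Percent of the substrate's electron equivalents captured in methane.

    fraction = 8 x CH4 / (substrate x electrons-per-substrate) x 100, with
    30 e- per oleate under the acetogenic scope and 102 e- under the full
    scope. Returns the unrounded percent; headline reporting rounds to the
    nearest integer.
    """
    if substrate_mmol <= 0:
        raise LedgerError("substrate concentration must be > 0")
    if ch4_mmol < 0:
        raise LedgerError("methane concentration must be >= 0")
    e_total = substrate_mmol * float(_electrons_per_substrate(scope, reactions))
    return ELECTRONS_PER_CH4 * ch4_mmol / e_total * 100.0


def expected_fe2(
    substrate_mmol: float,
    ch4_measured: float,
    acetate_measured: float,
    reactions: Mapping[str, Reaction] | None = None,
) -> Fe2Expectation:
    """Fe(II) expected from the electrons not captured in measured products.

    Surplus H2 = (H2 yield per substrate) x substrate - (H2 per CH4) x CH4;
    each surplus H2 reduces 2 Fe(III). The acetate produced but not seen in
    the medium (9 x substrate - measured) is assumed oxidized on Fe(III),
    8 Fe(II) per acetate. Negative intermediate pools are clamped to zero
    and flagged (measurement noise), not raised.
    """
    if substrate_mmol < 0 or ch4_measured < 0 or acetate_measured < 0:
        raise LedgerError("concentrations must be >= 0")
    rxns = standard_reactions() if reactions is None else dict(reactions)
    h2_per_sub = _ratio(rxns["r1"], "H2", "oleate")  # 15
    ac_per_sub = _ratio(rxns["r1"], "acetate", "oleate")  # 9
    h2_per_ch4 = 1 / _ratio(rxns["r5"], "CH4", "H2")  # 4
    fe2_per_h2 = _ratio(rxns["r4"], "Fe2", "H2")  # 2
    fe2_per_ac = _ratio(rxns["r2"], "Fe2", "acetate")  # 8

    surplus_h2 = float(h2_per_sub) * substrate_mmol - float(h2_per_ch4) * ch4_measured
    clamped_h2 = surplus_h2 < 0
    surplus_h2 = max(surplus_h2, 0.0)

    available_ac = float(ac_per_sub) * substrate_mmol - acetate_measured
    clamped_ac = available_ac < 0
    available_ac = max(available_ac, 0.0)

    h2_derived = float(fe2_per_h2) * surplus_h2
    ac_derived = float(fe2_per_ac) * available_ac
    return Fe2Expectation(
        h2_derived=h2_derived,
        acetate_available=available_ac,
        acetate_derived=ac_derived,
        total=h2_derived + ac_derived,
        clamped_h2=clamped_h2,
        clamped_acetate=clamped_ac,
    )


def methane_recovery(measured_max: float, theoretical: float) -> RecoveryResult:
    """Measured maximum cumulative methane over the stoichiometric maximum.

    recovery (%) = measured / theoretical x 100. Values above 100 (blanks,
    noise) are flagged, not rejected.
    """
    if theoretical <= 0:
        raise LedgerError("theoretical methane must be > 0")
    if measured_max < 0:
        raise LedgerError("measured methane must be >= 0")
    pct = measured_max / theoretical * 100.0
    return RecoveryResult(
        measured_mmol=measured_max,
        theoretical_mmol=theoretical,
        recovery_percent=pct,
        exceeds_100=pct > 100.0,
    )


@dataclass(frozen=True)
class ElectronLedger:
    """Electron-equivalent budget of a dose split over sinks (mmol e-/L).

    ``allocations`` maps sink id (CH4, FeII, acetate) to electron
    equivalents; their sum may not exceed ``total``.
    """

    total: float
    allocations: Mapping[str, float]
    scope: Scope = "full"

    def __post_init__(self) -> None:
        if any(v < -1e-9 for v in self.allocations.values()):
            raise LedgerError("negative electron allocation")
        object.__setattr__(self, "allocations", dict(self.allocations))

    @property
    def allocated(self) -> float:
        return sum(self.allocations.values())

    @property
    def unallocated(self) -> float:
        return self.total - self.allocated

    def is_conserved(self, tol: float = 1e-9) -> bool:
        """True when the allocations exactly exhaust the budget."""
        return abs(self.unallocated) <= tol

    def within_budget(self, tol: float = 1e-9) -> bool:
        return self.allocated <= self.total + tol


def build_ledger(
    dose: DoseSpec,
    ch4_mmol: float,
    fe2_mmol: float,
    acetate_mmol: float,
    scope: Scope = "full",
    reactions: Mapping[str, Reaction] | None = None,
) -> ElectronLedger:
    """Assemble the electron ledger of one treatment from measured pools.

    8 e- per CH4 and per residual acetate, 1 e- per Fe(II); the total is the
    substrate dose times its electron content under ``scope``.
    """
    total = dose.substrate_mmol * float(_electrons_per_substrate(scope, reactions))
    alloc = {
        "CH4": ELECTRONS_PER_CH4 * ch4_mmol,
        "FeII": ELECTRONS_PER_FE * fe2_mmol,
    }
    if scope == "full":
        alloc["acetate"] = ELECTRONS_PER_ACETATE * acetate_mmol
    return ElectronLedger(total=total, allocations=alloc, scope=scope)
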