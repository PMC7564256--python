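"""Exact reaction algebra and Gibbs-energy bookkeeping.

This module holds the chemistry layer of the package: chemical species with
integer formulas and charges, reactions with signed *rational* stoichiometric
coefficients, elemental/charge balance verification, linear composition of
half-reactions with cancellation of shared intermediates (H2, acetate), and
combination of standard transformed Gibbs energies (dG0', 25 degC, pH 7).

All coefficient arithmetic uses :class:`fractions.Fraction`, so decimal
coefficients such as 3.75 are stored as 15/4 and composed reactions reproduce
printed coefficients bit-exactly. Sign convention: consumed species carry
negative coefficients, produced species positive; reversing a reaction is
multiplication by -1.

Electron equivalents are counted with the Fe(OH)3/Fe2+ couple as the
reference one-electron acceptor: H2 releases 2 e-, acetate 8 e- on full
oxidation to bicarbonate, and one mole of oleate releases 102 e-.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from fractions import Fraction
from importlib import resources
from typing import Iterable, Iterator, Mapping, Sequence

__all__ = [
    "ChemError",
    "FormulaError",
    "UnknownSpeciesError",
    "MissingDeltaGError",
    "ELECTRON_ID",
    "parse_formula",
    "Species",
    "SpeciesRegistry",
    "Reaction",
    "BalanceReport",
    "CompositionRecipe",
    "check_balance",
    "compose",
    "combined_delta_g",
    "delta_g_from_formation",
    "electron_content",
    "parse_equation",
    "load_species_registry",
    "load_reactions",
    "load_thermo_table",
    "standard_registry",
    "standard_reactions",
    "standard_recipes",
    "composed_reactions",
    "standard_thermo_table",
]

Rational = Fraction

#: id of the free-electron pseudo-species used by explicit half-reactions
#: (no elements, charge -1). It is the only species allowed an empty formula.
ELECTRON_ID = "e"

#: default electron-accepting mineral couple: Fe(OH)3 -> Fe2+, 1 e- per Fe.
DEFAULT_ACCEPTOR_ID = "FeOH3"


class ChemError(ValueError):
    """Base class for chemistry-layer errors."""


class FormulaError(ChemError):
    """Malformed chemical formula string."""


class UnknownSpeciesError(ChemError, KeyError):
    """A reaction references a species id absent from the registry."""

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message flat
        return ValueError.__str__(self)


class MissingDeltaGError(ChemError):
    """A composition needs a dG0' that a member reaction does not carry."""


# ---------------------------------------------------------------------------
# formulas and species
# ---------------------------------------------------------------------------

_ELEMENT = re.compile(r"([A-Z][a-z]?)(\d*)")
_INT = re.compile(r"\d+")


def parse_formula(text: str) -> dict[str, int]:
    """Parse a chemical formula into exact integer element counts.

    Supports element symbols with optional counts and parenthesized groups
    with integer multipliers, e.g. ``"Fe(OH)3" -> {"Fe": 1, "O": 3, "H": 3}``.

    Raises :class:`FormulaError` naming the offending position on malformed
    input.
    """
    if not text:
        raise FormulaError("empty formula")

    def group(i: int, depth: int) -> tuple[dict[str, int], int]:
        counts: dict[str, int] = {}
        while i < len(text):
            ch = text[i]
            if ch == "(":
                inner, i = group(i + 1, depth + 1)
                if i >= len(text) or text[i] != ")":
                    raise FormulaError(f"unclosed '(' in {text!r}")
                i += 1
                m = _INT.match(text, i)
                mult = 1
                if m:
                    mult = int(m.group())
                    i = m.end()
                if mult == 0:
                    raise FormulaError(
                        f"zero group multiplier at position {i - 1} in {text!r}"
                    )
                for el, n in inner.items():
                    counts[el] = counts.get(el, 0) + n * mult
            elif ch == ")":
                if depth == 0:
                    raise FormulaError(
                        f"unmatched ')' at position {i} in {text!r}"
                    )
                return counts, i
            else:
                m = _ELEMENT.match(text, i)
                if not m or not m.group(1):
                    raise FormulaError(
                        f"unexpected character {ch!r} at position {i} in {text!r}"
                    )
                el = m.group(1)
                n = int(m.group(2)) if m.group(2) else 1
                if n == 0:
                    raise FormulaError(
                        f"zero count for element {el!r} at position {i} in {text!r}"
                    )
                counts[el] = counts.get(el, 0) + n
                i = m.end()
        if depth:
            raise FormulaError(f"unclosed '(' in {text!r}")
        return counts, i

    counts, _ = group(0, 0)
    return counts


@dataclass(frozen=True)
class Species:
    """A chemical species: id, elemental formula and elementary charge.

    ``phase_note`` is informational only (aqueous/solid/gas); it plays no
    role in balancing or energetics.
    """

    id: str
    formula: Mapping[str, int]
    charge: int
    phase_note: str = ""

    def __post_init__(self) -> None:
        if any(n < 0 for n in self.formula.values()):
            raise ChemError(f"negative element count in species {self.id!r}")
        if not self.formula and self.id != ELECTRON_ID:
            raise ChemError(
                f"species {self.id!r} has no elements (only the electron "
                f"pseudo-species {ELECTRON_ID!r} may be element-free)"
            )
        object.__setattr__(self, "formula", dict(self.formula))

    @classmethod
    def from_formula(
        cls, id: str, formula: str, charge: int, phase_note: str = ""
    ) -> "Species":
        counts = {} if formula in ("", "-") else parse_formula(formula)
        return cls(id, counts, charge, phase_note)


class SpeciesRegistry:
    """Mapping of species id -> :class:`Species` with uniqueness enforced."""

    def __init__(self, species: Iterable[Species] = ()) -> None:
        self._species: dict[str, Species] = {}
        for sp in species:
            self.add(sp)

    def add(self, sp: Species) -> None:
        if sp.id in self._species:
            raise ChemError(f"duplicate species id {sp.id!r}")
        self._species[sp.id] = sp

    def __getitem__(self, species_id: str) -> Species:
        try:
            return self._species[species_id]
        except KeyError:
            raise UnknownSpeciesError(
                f"unknown species id {species_id!r}"
            ) from None

    def __contains__(self, species_id: str) -> bool:
        return species_id in self._species

    def __iter__(self) -> Iterator[Species]:
        return iter(self._species.values())

    def __len__(self) -> int:
        return len(self._species)

    def ids(self) -> list[str]:
        return list(self._species)


# ---------------------------------------------------------------------------
# reactions
# ---------------------------------------------------------------------------


def _as_fraction(x) -> Fraction:
    """Exact coercion: strings and decimals like '3.75' become 15/4."""
    if isinstance(x, Fraction):
        return x
    if isinstance(x, float):
        # floats only enter through user code; use their decimal repr so that
        # 3.75 -> 15/4 and 0.1 -> 1/10 rather than binary expansions
        return Fraction(repr(x))
    return Fraction(x)


@dataclass(frozen=True)
class Reaction:
    """A reaction as a signed rational stoichiometric map.

    Negative coefficient = consumed, positive = produced. Zero coefficients
    are never stored. ``delta_g0_prime`` is the standard transformed Gibbs
    energy in kJ per reaction as written (1 mol/L solutes, 1e5 Pa gas,
    25 degC, pH 7) or None when unknown. ``condition_tag`` is one of
    ``IR`` (iron-reducing), ``M`` (methanogenic) or ``neutral``.
    """

    stoich: Mapping[str, Fraction]
    delta_g0_prime: float | None = None
    label: str = ""
    condition_tag: str = "neutral"

    def __post_init__(self) -> None:
        if self.condition_tag not in ("IR", "M", "neutral"):
            raise ChemError(f"bad condition tag {self.condition_tag!r}")
        clean = {
            sid: _as_fraction(c) for sid, c in self.stoich.items() if c != 0
        }
        object.__setattr__(self, "stoich", clean)

    def coeff(self, species_id: str) -> Fraction:
        return self.stoich.get(species_id, Fraction(0))

    def species(self) -> list[str]:
        return list(self.stoich)

    @property
    def reactants(self) -> dict[str, Fraction]:
        return {s: -c for s, c in self.stoich.items() if c < 0}

    @property
    def products(self) -> dict[str, Fraction]:
        return {s: c for s, c in self.stoich.items() if c > 0}

    def scaled(self, multiplier) -> "Reaction":
        m = _as_fraction(multiplier)
        dg = None if self.delta_g0_prime is None else float(m) * self.delta_g0_prime
        return Reaction(
            {s: m * c for s, c in self.stoich.items()},
            delta_g0_prime=dg,
            label=f"{m} x ({self.label})" if self.label else "",
            condition_tag=self.condition_tag,
        )

    def is_empty(self) -> bool:
        return not self.stoich

    def equation(self) -> str:
        """Human-readable ``A + 2 B -> 3 C`` form (unit coefficients omitted)."""

        def side(terms: dict[str, Fraction]) -> str:
            parts = []
            for sid, c in terms.items():
                mag = c if c > 0 else -c
                parts.append(sid if mag == 1 else f"{_fmt_coeff(mag)} {sid}")
            return " + ".join(parts) if parts else "(nothing)"

        return f"{side(self.reactants)} -> {side(self.products)}"


def _fmt_coeff(c: Fraction) -> str:
    """Print 15/4 as '3.75' when the decimal form terminates, else 'p/q'."""
    if c.denominator == 1:
        return str(c.numerator)
    f = float(c)
    if Fraction(repr(f)) == c:
        return repr(f)
    return f"{c.numerator}/{c.denominator}"


@dataclass(frozen=True)
class BalanceReport:
    """Exact per-element and charge residuals of a reaction.

    ``balanced`` is True iff every residual is exactly zero (rational
    arithmetic -- no tolerance).
    """

    element_residuals: Mapping[str, Fraction]
    charge_residual: Fraction
    balanced: bool

    @property
    def nonzero(self) -> dict[str, Fraction]:
        out = {el: r for el, r in self.element_residuals.items() if r != 0}
        if self.charge_residual != 0:
            out["charge"] = self.charge_residual
        return out


def check_balance(reaction: Reaction, registry: SpeciesRegistry) -> BalanceReport:
    """Verify elemental and charge conservation of ``reaction`` exactly."""
    elements: dict[str, Fraction] = {}
    charge = Fraction(0)
    for sid, c in reaction.stoich.items():
        sp = registry[sid]
        for el, n in sp.formula.items():
            elements[el] = elements.get(el, Fraction(0)) + c * n
        charge += c * sp.charge
    balanced = charge == 0 and all(r == 0 for r in elements.values())
    return BalanceReport(elements, charge, balanced)


# ---------------------------------------------------------------------------
# composition
# ---------------------------------------------------------------------------


class CompositionRecipe:
    """An ordered list of (reaction, rational multiplier) terms.

    The sum of multiplier-scaled reactions defines a net conversion; shared
    intermediates whose net coefficient is zero cancel out of the composed
    reaction.
    """

    def __init__(self, terms: Iterable[tuple[Reaction, object]]) -> None:
        self.terms: list[tuple[Reaction, Fraction]] = []
        for rxn, mult in terms:
            m = _as_fraction(mult)
            if m == 0:
                raise ChemError("zero multiplier in composition recipe")
            self.terms.append((rxn, m))

    def __iter__(self) -> Iterator[tuple[Reaction, Fraction]]:
        return iter(self.terms)

    def __len__(self) -> int:
        return len(self.terms)


def _as_recipe(recipe) -> CompositionRecipe:
    if isinstance(recipe, CompositionRecipe):
        return recipe
    return CompositionRecipe(recipe)


def compose(recipe, label: str = "", condition_tag: str | None = None) -> Reaction:
    """Sum multiplier-scaled reactions, cancelling zero-net species.

    The coefficient of each species in the result is the exact rational
    sum of multiplier * coefficient over the recipe terms; species whose net
    coefficient is zero (cancelled intermediates such as H2) are removed.
    """
    recipe = _as_recipe(recipe)
    if len(recipe) == 0:
        raise ChemError("empty composition recipe")
    total: dict[str, Fraction] = {}
    tags = set()
    for rxn, m in recipe:
        tags.add(rxn.condition_tag)
        for sid, c in rxn.stoich.items():
            total[sid] = total.get(sid, Fraction(0)) + m * c
    if condition_tag is None:
        tags.discard("neutral")
        condition_tag = tags.pop() if len(tags) == 1 else "neutral"
    return Reaction(total, label=label, condition_tag=condition_tag)


def combined_delta_g(recipe) -> float:
    """dG0' of a composed reaction from member dG0' values, in kJ.

    Returns sum(multiplier * dG0'), rounded to one decimal to match the
    precision of printed tables. Raises :class:`MissingDeltaGError` naming
    the first reaction lacking a dG0'.
    """
    recipe = _as_recipe(recipe)
    if len(recipe) == 0:
        raise ChemError("empty composition recipe")
    total = Fraction(0)
    for rxn, m in recipe:
        if rxn.delta_g0_prime is None:
            raise MissingDeltaGError(
                f"reaction {rxn.label or rxn.equation()!r} has no dG0'"
            )
        total += m * Fraction(repr(rxn.delta_g0_prime))
    return round(float(total), 1)


def delta_g_from_formation(reaction: Reaction, table: Mapping[str, float]) -> float:
    """dG0' of ``reaction`` from standard transformed formation energies.

    ``table`` maps species id -> dGf0' (kJ/mol, 25 degC, pH 7). Returns
    sum(coeff * dGf0') in kJ per reaction as written. Used as a cross-check
    of printed elementary values, not an exact reproduction (the literature
    tables themselves carry ~0.1 kJ rounding).
    """
    total = 0.0
    for sid, c in reaction.stoich.items():
        if sid not in table:
            raise UnknownSpeciesError(
                f"no formation energy for species {sid!r}"
            )
        total += float(c) * table[sid]
    return total


def electron_content(
    species_id: str,
    oxidation_reaction: Reaction,
    acceptor_id: str = DEFAULT_ACCEPTOR_ID,
) -> Fraction:
    """Electron equivalents released per mole of ``species_id`` on full
    oxidation, read off ``oxidation_reaction``.

    The reaction must consume the species and either consume the Fe(III)
    acceptor (one electron per Fe(OH)3 -> Fe2+) or produce free electrons
    explicitly. Returns the exact rational number of single-electron
    equivalents per mole of substrate.
    """
    s = oxidation_reaction.coeff(species_id)
    if s >= 0:
        raise ChemError(
            f"reaction {oxidation_reaction.label!r} does not consume "
            f"{species_id!r}"
        )
    e_out = oxidation_reaction.coeff(ELECTRON_ID)
    if e_out > 0:
        return e_out / -s
    acc = oxidation_reaction.coeff(acceptor_id)
    if acc < 0:
        return acc / s  # both negative -> positive ratio
    raise ChemError(
        f"reaction {oxidation_reaction.label!r} neither consumes "
        f"{acceptor_id!r} nor produces electrons; cannot count electron "
        f"equivalents for {species_id!r}"
    )


# ---------------------------------------------------------------------------
# file formats and the bundled reaction set
# ---------------------------------------------------------------------------

_COEFF_TERM = re.compile(r"^\s*(?:(\d+(?:\.\d+)?(?:/\d+)?)\s+)?(\S+)\s*$")


def parse_equation(
    text: str,
    delta_g0_prime: float | None = None,
    label: str = "",
    condition_tag: str = "neutral",
) -> Reaction:
    """Parse an ``A + 2 B -> 3 C`` equation string into a :class:`Reaction`.

    Coefficients may be integers, terminating decimals ("3.75") or
    fractions ("15/4"); species tokens are registry ids.
    """
    for arrow in ("->", "→", "="):
        if arrow in text:
            lhs, rhs = text.split(arrow, 1)
            break
    else:
        raise ChemError(f"no '->' in equation {text!r}")
    stoich: dict[str, Fraction] = {}
    for side, sign in ((lhs, -1), (rhs, 1)):
        side = side.strip()
        if not side:
            raise ChemError(f"empty reaction side in {text!r}")
        for term in side.split(" + "):
            m = _COEFF_TERM.match(term)
            if not m:
                raise ChemError(f"cannot parse term {term!r} in {text!r}")
            coeff = Fraction(m.group(1)) if m.group(1) else Fraction(1)
            sid = m.group(2)
            stoich[sid] = stoich.get(sid, Fraction(0)) + sign * coeff
    return Reaction(
        stoich,
        delta_g0_prime=delta_g0_prime,
        label=label,
        condition_tag=condition_tag,
    )


def _read_tsv(path_or_text) -> list[dict[str, str]]:
    """Tiny TSV reader: first row is the header; '#' lines are comments."""
    import io
    import os

    if isinstance(path_or_text, (str, os.PathLike)) and "\n" not in str(path_or_text):
        with open(path_or_text, encoding="utf-8") as fh:
            lines = fh.read().splitlines()
    elif isinstance(path_or_text, io.IOBase):
        lines = path_or_text.read().splitlines()
    else:
        lines = str(path_or_text).splitlines()
    lines = [ln for ln in lines if ln.strip() and not ln.startswith("#")]
    if not lines:
        return []
    header = lines[0].split("\t")
    return [dict(zip(header, ln.split("\t"))) for ln in lines[1:]]


def load_species_registry(path_or_text) -> SpeciesRegistry:
    """Load a species registry from TSV columns: id, formula, charge, phase."""
    reg = SpeciesRegistry()
    for row in _read_tsv(path_or_text):
        reg.add(
            Species.from_formula(
                row["id"],
                row["formula"],
                int(row["charge"]),
                row.get("phase", ""),
            )
        )
    return reg


def load_reactions(path_or_text) -> dict[str, Reaction]:
    """Load reactions from TSV columns: label, condition, equation, delta_g0_kj."""
    out: dict[str, Reaction] = {}
    for row in _read_tsv(path_or_text):
        dg = row.get("delta_g0_kj", "").strip()
        rxn = parse_equation(
            row["equation"],
            delta_g0_prime=float(dg) if dg else None,
            label=row["label"],
            condition_tag=row.get("condition", "neutral") or "neutral",
        )
        if rxn.label in out:
            raise ChemError(f"duplicate reaction label {rxn.label!r}")
        out[rxn.label] = rxn
    return out


def load_thermo_table(path_or_text) -> dict[str, float]:
    """Load dGf0' (kJ/mol) per species from TSV: species, delta_gf0_kj, citation."""
    return {
        row["species"]: float(row["delta_gf0_kj"])
        for row in _read_tsv(path_or_text)
    }


def _data_text(name: str) -> str:
    return resources.files("ferroleate.data").joinpath(name).read_text("utf-8")


def standard_registry() -> SpeciesRegistry:
    """Species of the bundled anaerobic oleate degradation reaction set."""
    return load_species_registry(_data_text("species.tsv"))


def standard_reactions() -> dict[str, Reaction]:
    """The five elementary reactions plus the explicit acetate-oxidation
    half-reaction, keyed r1..r5 and eq10.

    r1 beta-oxidation of oleate; r2 acetate oxidation on Fe(III); r3
    acetoclastic methanogenesis; r4 H2 oxidation on Fe(III); r5
    hydrogenotrophic methanogenesis; eq10 acetate -> bicarbonate + 8 e-.
    """
    return load_reactions(_data_text("reactions.tsv"))


def standard_recipes(
    reactions: Mapping[str, Reaction] | None = None,
) -> dict[str, CompositionRecipe]:
    """Fully multiplied recipes for the four composite conversions.

    The published shorthand ("6 = 1 + 4" etc.) omits multipliers; only the
    multiplied forms cancel the shared H2/acetate pools:

    r6 = r1 + 15 r4, r7 = r1 + 9 r2 + 15 r4, r8 = r1 + 15 r5,
    r9 = r1 + 9 r3 + 15 r5.
    """
    r = dict(standard_reactions() if reactions is None else reactions)
    return {
        "r6": CompositionRecipe([(r["r1"], 1), (r["r4"], 15)]),
        "r7": CompositionRecipe([(r["r1"], 1), (r["r2"], 9), (r["r4"], 15)]),
        "r8": CompositionRecipe([(r["r1"], 1), (r["r5"], 15)]),
        "r9": CompositionRecipe([(r["r1"], 1), (r["r3"], 9), (r["r5"], 15)]),
    }


_COMPOSITE_LABELS = {
    "r6": ("oleate oxidation to acetate coupled to Fe(III) reduction", "IR"),
    "r7": ("complete oleate oxidation to CO2 coupled to Fe(III) reduction", "IR"),
    "r8": ("oleate oxidation to acetate coupled to hydrogenotrophic methanogenesis", "M"),
    "r9": ("overall oleate oxidation to methane", "M"),
}


def composed_reactions(
    reactions: Mapping[str, Reaction] | None = None,
    with_delta_g: bool = True,
) -> dict[str, Reaction]:
    """Composite reactions r6..r9 with their recipe-combined dG0' attached."""
    out: dict[str, Reaction] = {}
    for key, recipe in standard_recipes(reactions).items():
        label, tag = _COMPOSITE_LABELS[key]
        rxn = compose(recipe, label=label, condition_tag=tag)
        if with_delta_g:
            rxn = Reaction(
                rxn.stoich,
                delta_g0_prime=combined_delta_g(recipe),
                label=rxn.label,
                condition_tag=rxn.condition_tag,
            )
        out[key] = rxn
    return out


def standard_thermo_table() -> dict[str, float]:
    """Bundled transformed formation energies (kJ/mol, 25 degC, pH 7) for the
    methanogenic species, after the classic anaerobe bioenergetics tables."""
    return load_thermo_table(_data_text("thermo.tsv"))
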