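"""Reaction algebra: formula parsing, balance, composition, dG0' bookkeeping."""

from fractions import Fraction

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ferroleate.chem import (
    ChemError,
    CompositionRecipe,
    FormulaError,
    MissingDeltaGError,
    Reaction,
    Species,
    UnknownSpeciesError,
    check_balance,
    combined_delta_g,
    compose,
    delta_g_from_formation,
    electron_content,
    parse_equation,
    parse_formula,
)


class TestParseFormula:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("Fe(OH)3", {"Fe": 1, "O": 3, "H": 3}),
            ("C18H33O2", {"C": 18, "H": 33, "O": 2}),
            ("H", {"H": 1}),
            ("C2H3O2", {"C": 2, "H": 3, "O": 2}),
            ("CHO3", {"C": 1, "H": 1, "O": 3}),
            ("Mg(NO3)2", {"Mg": 1, "N": 2, "O": 6}),
            ("((CH3)2)2", {"C": 4, "H": 12}),
        ],
    )
    def test_exact_counts(self, text, expected):
        assert parse_formula(text) == expected

    @pytest.mark.parametrize("bad", ["", "(", ")H2", "Fe(OH", "2H", "h2o", "H2("])
    def test_malformed_raises_with_context(self, bad):
        with pytest.raises(FormulaError):
            parse_formula(bad)

    def test_error_names_position(self):
        with pytest.raises(FormulaError, match="position"):
            parse_formula("Fe)3")


class TestSpecies:
    def test_rejects_element_free_species(self):
        with pytest.raises(ChemError):
            Species("ghost", {}, 0)

    def test_electron_pseudo_species_allowed(self):
        assert Species("e", {}, -1).charge == -1


class TestBalance:
    def test_all_registered_reactions_balance_exactly(self, reactions, registry):
        for label, rxn in reactions.items():
            report = check_balance(rxn, registry)
            assert report.balanced, f"{label}: residuals {report.nonzero}"
            assert all(r == 0 for r in report.element_residuals.values())
            assert report.charge_residual == 0

    def test_composed_reactions_balance(self, composed, registry):
        for label, rxn in composed.items():
            assert check_balance(rxn, registry).balanced, label

    def test_perturbed_hydrogen_coefficient_breaks_balance(self, reactions, registry):
        r1 = reactions["r1"]
        broken = Reaction({**r1.stoich, "H2": Fraction(14)})
        report = check_balance(broken, registry)
        assert not report.balanced
        assert report.element_residuals["H"] == -2  # 14 instead of 15 H2

    def test_unknown_species_raises(self, registry):
        rxn = Reaction({"unobtainium": Fraction(-1), "H2O": Fraction(1)})
        with pytest.raises(UnknownSpeciesError, match="unobtainium"):
            check_balance(rxn, registry)


class TestCompose:
    def test_iron_coupled_acetogenic_route_matches_printed_equation(self, reactions):
        # 1 x beta-oxidation + 15 x H2-on-Fe(III): H2 cancels entirely
        net = compose([(reactions["r1"], 1), (reactions["r4"], 15)])
        assert net.coeff("FeOH3") == -30
        assert net.coeff("H") == -52
        assert net.coeff("H2O") == 74
        assert net.coeff("acetate") == 9
        assert net.coeff("Fe2") == 30
        assert net.coeff("oleate") == -1
        assert "H2" not in net.stoich

    def test_overall_methanogenic_route_reproduces_fractional_coefficients(
        self, reactions
    ):
        net = compose(
            [(reactions["r1"], 1), (reactions["r3"], 9), (reactions["r5"], 15)]
        )
        assert net.coeff("CH4") == Fraction(51, 4)  # 12.75
        assert net.coeff("HCO3") == Fraction(21, 4)  # 5.25
        assert net.coeff("H2O") == Fraction(-55, 4)  # -13.75
        assert net.coeff("H") == Fraction(17, 4)  # 4.25
        assert "H2" not in net.stoich and "acetate" not in net.stoich

    def test_full_iron_route_cancels_both_intermediates(self, reactions):
        net = compose(
            [(reactions["r1"], 1), (reactions["r2"], 9), (reactions["r4"], 15)]
        )
        assert net.coeff("FeOH3") == -102
        assert net.coeff("H") == -187
        assert net.coeff("HCO3") == 18
        assert net.coeff("Fe2") == 102
        assert net.coeff("H2O") == 254
        assert "H2" not in net.stoich and "acetate" not in net.stoich

    def test_exact_self_cancellation_gives_empty_reaction(self, reactions):
        net = compose([(reactions["r3"], 1), (reactions["r3"], -1)])
        assert net.is_empty()

    def test_empty_recipe_rejected(self):
        with pytest.raises(ChemError):
            compose([])

    def test_zero_multiplier_rejected(self, reactions):
        with pytest.raises(ChemError):
            CompositionRecipe([(reactions["r1"], 0)])


class TestCombinedDeltaG:
    def test_acetogenic_methanogenic_composite(self, reactions):
        dg = combined_delta_g([(reactions["r1"], 1), (reactions["r5"], 15)])
        assert dg == -182.8

    def test_overall_methanogenic_composite(self, reactions):
        dg = combined_delta_g(
            [(reactions["r1"], 1), (reactions["r3"], 9), (reactions["r5"], 15)]
        )
        assert dg == -461.8

    def test_self_cancellation_is_zero(self, reactions):
        assert combined_delta_g([(reactions["r3"], 1), (reactions["r3"], -1)]) == 0.0

    def test_missing_delta_g_names_reaction(self, reactions):
        with pytest.raises(MissingDeltaGError, match="eq10"):
            combined_delta_g([(reactions["eq10"], 1)])

    @given(
        a=st.fractions(min_value=-20, max_value=20),
        b=st.fractions(min_value=-20, max_value=20),
    )
    @settings(deadline=None)
    def test_linearity_in_multipliers(self, a, b, reactions):
        # dG(a r1 + b r4) == a dG(r1) + b dG(r4), up to the 1-decimal report
        r1, r4 = reactions["r1"], reactions["r4"]
        terms = [(r, m) for r, m in ((r1, a), (r4, b)) if m != 0]
        if not terms:
            return
        lhs = combined_delta_g(terms)
        rhs = float(a) * 325.7 + float(b) * -34.4
        assert lhs == pytest.approx(rhs, abs=0.051)

    def test_hess_path_independence_for_methane_on_iron(self, reactions):
        # CH4 + 8 Fe(OH)3 -> HCO3 + 8 Fe2+ via two recipes
        r2, r3, r4, r5 = (reactions[k] for k in ("r2", "r3", "r4", "r5"))
        via_hydrogen = [(r4, 4), (r5, -4)]
        via_acetate = [(r2, 1), (r3, -1)]
        net_h = compose(via_hydrogen)
        net_ac = compose(via_acetate)
        assert net_h.stoich == net_ac.stoich
        dg_h = combined_delta_g(via_hydrogen)
        dg_ac = combined_delta_g(via_acetate)
        assert dg_h == -2.0 and dg_ac == -1.9
        assert abs(dg_h - dg_ac) <= 0.6  # rounding slack of 1-decimal inputs


class TestFormationEnergies:
    def test_acetoclastic_methanogenesis_cross_check(self, reactions, thermo):
        dg = delta_g_from_formation(reactions["r3"], thermo)
        assert dg == pytest.approx(-31.0, abs=1.0)

    def test_hydrogenotrophic_methanogenesis_cross_check(self, reactions, thermo):
        dg = delta_g_from_formation(reactions["r5"], thermo)
        assert dg == pytest.approx(-33.9, abs=1.0)

    def test_empty_reaction_is_zero(self, thermo):
        assert delta_g_from_formation(Reaction({}), thermo) == 0.0

    def test_missing_entry_names_species(self, reactions, thermo):
        with pytest.raises(UnknownSpeciesError, match="FeOH3"):
            delta_g_from_formation(reactions["r4"], thermo)


class TestElectronContent:
    def test_acetate_releases_eight_electrons(self, reactions):
        assert electron_content("acetate", reactions["eq10"]) == 8
        assert electron_content("acetate", reactions["r2"]) == 8

    def test_oleate_releases_102_electrons(self, composed):
        assert electron_content("oleate", composed["r7"]) == 102

    def test_hydrogen_releases_two_electrons(self, reactions):
        assert electron_content("H2", reactions["r4"]) == 2

    def test_electron_closure_identity(self, reactions, composed):
        # full oxidation = H2-borne + acetate-borne electrons of beta-oxidation
        r1 = reactions["r1"]
        h2_yield = r1.coeff("H2")
        acetate_yield = r1.coeff("acetate")
        assert 2 * h2_yield + 8 * acetate_yield == electron_content(
            "oleate", composed["r7"]
        )

    def test_non_oxidizing_reaction_rejected(self, reactions):
        with pytest.raises(ChemError):
            electron_content("acetate", reactions["r3"])


# --- compose against an independent naive summation oracle -----------------

_BASIS_EQUATIONS = [
    "A + 2 B -> C",
    "C -> 2 D",
    "B + D -> E",
    "2 A -> B + 3 E",
]
_BASIS = [parse_equation(eq, label=f"toy{i}") for i, eq in enumerate(_BASIS_EQUATIONS)]


def _naive_sum(terms):
    """Independent oracle: plain dict accumulation of multiplier x coeff."""
    total = {}
    for rxn, mult in terms:
        for sid, c in rxn.stoich.items():
            total[sid] = total.get(sid, Fraction(0)) + mult * c
    return {s: c for s, c in total.items() if c != 0}


@given(
    st.lists(
        st.tuples(
            st.sampled_from(_BASIS),
            st.fractions(min_value=-9, max_value=9).filter(lambda f: f != 0),
        ),
        min_size=1,
        max_size=6,
    )
)
@settings(deadline=None, max_examples=200)
def test_compose_matches_naive_summation_oracle(terms):
    assert dict(compose(terms).stoich) == _naive_sum(terms)


def test_parse_equation_roundtrip_of_decimal_coefficients():
    rxn = parse_equation("H2 + 0.25 HCO3 + 0.25 H -> 0.25 CH4 + 0.75 H2O")
    assert rxn.coeff("CH4") == Fraction(1, 4)
    assert rxn.coeff("H2O") == Fraction(3, 4)
    assert rxn.coeff("H2") == -1
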