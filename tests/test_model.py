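"""Model structure, validation, exchange lookup, knockout propagation."""

import itertools

import pytest

from auxogem.gpr import parse_gpr
from auxogem.model import (
    AmbiguousMatchError,
    GEMModel,
    Metabolite,
    ModelError,
    Reaction,
    UnknownGeneError,
    disabled_reactions,
    find_exchange,
    formula_mass,
    validate_model,
)


@pytest.mark.parametrize(
    "formula,expected",
    [
        ("C6H12O6", 180.156),
        ("H2O", 18.015),
        # ATP^4- style formula: 10*12.011 + 12*1.008 + 5*14.007 + 13*15.999 + 3*30.974
        ("C10H12N5O13P3", 503.150),
    ],
)
def test_formula_mass(formula, expected):
    assert formula_mass(formula) == pytest.approx(expected, abs=0.01)


def test_formula_mass_extensible_and_errors():
    assert formula_mass("X2", {"X": 5.0}) == 10.0
    with pytest.raises(ModelError):
        formula_mass("Xx9")
    with pytest.raises(ModelError):
        formula_mass("")
    with pytest.raises(ModelError):
        formula_mass("C6H12O6)")


def _tiny_model():
    m = GEMModel(id="tiny")
    m.add_metabolite(Metabolite("a_e", "alpha", "e"))
    m.add_metabolite(Metabolite("a_c", "alpha", "c"))
    m.add_metabolite(Metabolite("b_c", "beta", "c"))
    m.add_reaction(Reaction("EX_a", {"a_e": -1.0}, lb=-10, ub=1000, is_exchange=True))
    m.add_reaction(Reaction("T_a", {"a_e": -1.0, "a_c": 1.0}))
    m.add_reaction(Reaction("conv", {"a_c": -1.0, "b_c": 1.0}, lb=0, gpr=parse_gpr("g1 or g2")))
    m.add_reaction(Reaction("complex", {"b_c": -1.0}, lb=0, gpr=parse_gpr("g3 and g4")))
    m.add_reaction(Reaction("solo", {"b_c": -1.0}, lb=0, gpr=parse_gpr("g5")))
    m.objective_reaction_id = "solo"
    m.genes.add("g_orphan")  # gene with no reactions
    return m


def test_validate_clean_model():
    assert validate_model(_tiny_model()) == []


def test_validate_reports_violations():
    m = _tiny_model()
    m.reactions["solo"].lb, m.reactions["solo"].ub = 5.0, 1.0
    m.reactions["complex"].gpr = parse_gpr("ghost")
    m.genes.discard("ghost")
    m.objective_reaction_id = "missing"
    issues = validate_model(m)
    assert any("lb" in v and "solo" in v for v in issues)
    assert any("ghost" in v for v in issues)
    assert any("objective" in v for v in issues)


@pytest.mark.parametrize(
    "deleted,expected",
    [
        ({"g5"}, {"solo"}),
        ({"g1"}, set()),  # isoenzyme survives
        ({"g3"}, {"complex"}),  # complex member kills the reaction
        ({"g1", "g2"}, {"conv"}),
        ({"g_orphan"}, set()),  # valid gene, no reactions
        (set(), set()),
    ],
)
def test_disabled_reactions(deleted, expected):
    assert disabled_reactions(_tiny_model(), deleted) == expected


def test_disabled_reactions_unknown_gene_is_distinct_error():
    with pytest.raises(UnknownGeneError):
        disabled_reactions(_tiny_model(), {"nope"})


def test_disabled_reactions_full_deletion_and_monotonicity():
    m = _tiny_model()
    assert disabled_reactions(m, set(m.genes)) == {"conv", "complex", "solo"}
    genes = sorted(g for g in m.genes)
    for k in range(len(genes)):
        for subset in itertools.combinations(genes, k):
            small = disabled_reactions(m, set(subset))
            big = disabled_reactions(m, set(genes))
            assert small <= big


def test_find_exchange_by_id_name_and_absence():
    m = _tiny_model()
    assert find_exchange(m, "a_e") == "EX_a"
    assert find_exchange(m, "EX_a") == "EX_a"
    assert find_exchange(m, "ALPHA") == "EX_a"  # name, case-insensitive
    assert find_exchange(m, "beta") is None  # no exchange: caller decides


def test_find_exchange_ambiguous():
    m = _tiny_model()
    m.add_reaction(Reaction("EX_a2", {"a_e": -1.0}, lb=0, is_exchange=True))
    with pytest.raises(AmbiguousMatchError) as err:
        find_exchange(m, "a_e")
    assert set(err.value.candidates) == {"EX_a", "EX_a2"}


def test_duplicate_ids_rejected():
    m = _tiny_model()
    with pytest.raises(ModelError):
        m.add_metabolite(Metabolite("a_c"))
    with pytest.raises(ModelError):
        m.add_reaction(Reaction("EX_a", {"a_e": -1.0}))


def test_copy_is_deep_for_bounds_and_stoich():
    m = _tiny_model()
    m2 = m.copy()
    m2.reactions["solo"].lb = -99
    m2.reactions["solo"].stoich["b_c"] = -2.0
    assert m.reactions["solo"].lb == 0
    assert m.reactions["solo"].stoich["b_c"] == -1.0
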