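"""Curation operators, mass-balanced rescaling, and the Yeast9 edit set."""

import random

import pytest

from auxogem import solve_fba
from auxogem.curation import (
    CurationEdit,
    EditApplicationError,
    MassRescaleSpec,
    apply_edits,
    block_reaction,
    edits_from_yaml,
    edits_to_yaml,
    parse_reaction_equation,
    pseudo_append,
    rescale_pseudoreaction,
    set_gpr,
    yeast9_curation_set,
)
from auxogem.model import GEMModel, Metabolite, ModelError, Reaction


# ---------------------------------------------------------------- operators

def test_block_reaction_both_and_reverse(trap_toy):
    model, truth = trap_toy
    bypass = next(e.target for e in truth.repair_edits if e.kind == "block_reaction")
    blocked = block_reaction(model, bypass, "both")
    assert blocked.reactions[bypass].lb == blocked.reactions[bypass].ub == 0.0
    # reverse-block on an irreversible reaction is a no-op
    rev = block_reaction(model, bypass, "reverse")
    assert rev.reactions[bypass].lb == model.reactions[bypass].lb
    assert rev.reactions[bypass].ub == model.reactions[bypass].ub
    # reverse-block clamps a reversible transporter's lower bound only
    rev2 = block_reaction(model, "T_substrate", "reverse")
    assert rev2.reactions["T_substrate"].lb == 0.0
    assert rev2.reactions["T_substrate"].ub == model.reactions["T_substrate"].ub


def test_blocking_zero_flux_reaction_keeps_optimum(basic_toy):
    model, _ = basic_toy
    before = solve_fba(model).objective
    blocked = block_reaction(model, "pseudo_pool", "both")
    assert solve_fba(blocked).objective == pytest.approx(before, abs=1e-9)


def test_blocking_never_increases_optimum(trap_toy):
    model, _ = trap_toy
    base = solve_fba(model).objective
    for rid in list(model.reactions)[:10]:
        blocked = block_reaction(model, rid, "both")
        assert solve_fba(blocked).growth <= base + 1e-6


def test_set_gpr_roundtrip_and_unknown_gene(basic_toy):
    model, _ = basic_toy
    rid = "P1_step1"
    edited = set_gpr(model, rid, "(YGL125W and YPL023C) or YGL125W",
                     new_genes=["YGL125W", "YPL023C"])
    assert edited.reactions[rid].gpr_string == "(YGL125W and YPL023C) or YGL125W"
    with pytest.raises(ModelError, match="unregistered"):
        set_gpr(model, rid, "GHOST1")
    # original untouched (operators are pure)
    assert model.reactions[rid].gpr_string != edited.reactions[rid].gpr_string


# ---------------------------------------------------------------- rescaling

def _pool_model():
    m = GEMModel(id="pool")
    m.add_metabolite(Metabolite("a", mass_override=100.0))
    m.add_metabolite(Metabolite("b", mass_override=100.0))
    m.add_metabolite(Metabolite("new", mass_override=50.0))
    m.add_metabolite(Metabolite("pool"))
    m.add_reaction(Reaction("pseudo", {"a": -1.0, "b": -1.0, "pool": 1.0}, lb=0, ub=0))
    m.add_reaction(Reaction("sink", {"pool": -1.0}, lb=0, ub=0))
    m.objective_reaction_id = "sink"
    return m


def test_rescale_worked_example():
    """Two reactants of mass 100 at coefficient -1 plus a new species of
    mass 50 at raw coefficient -1: f = 200/250 = 0.8 and every reactant
    lands at -0.8, conserving the 200 total."""
    m = _pool_model()
    out = rescale_pseudoreaction(
        m, MassRescaleSpec("pseudo", "new", new_coefficient_raw=-1.0)
    )
    stoich = out.reactions["pseudo"].stoich
    assert stoich["a"] == pytest.approx(-0.8, abs=1e-12)
    assert stoich["b"] == pytest.approx(-0.8, abs=1e-12)
    assert stoich["new"] == pytest.approx(-0.8, abs=1e-12)
    total = 0.8 * 100 + 0.8 * 100 + 0.8 * 50
    assert total == pytest.approx(200.0, abs=1e-9)


def test_rescale_zero_coefficient_is_noop():
    m = _pool_model()
    out = rescale_pseudoreaction(
        m, MassRescaleSpec("pseudo", "new", new_coefficient_raw=0.0)
    )
    assert out.reactions["pseudo"].stoich == m.reactions["pseudo"].stoich


def test_rescale_conserves_mass_and_ratios_randomized():
    rng = random.Random(99)
    for _ in range(50):
        m = GEMModel(id="r")
        n = rng.randint(2, 6)
        coeffs, masses = {}, {}
        for i in range(n):
            mid = f"s{i}"
            masses[mid] = rng.uniform(10, 500)
            coeffs[mid] = -rng.uniform(0.01, 2.0)
            m.add_metabolite(Metabolite(mid, mass_override=masses[mid]))
        m.add_metabolite(Metabolite("new", mass_override=rng.uniform(10, 400)))
        m.add_metabolite(Metabolite("pool"))
        m.add_reaction(Reaction("pseudo", {**coeffs, "pool": 1.0}, lb=0, ub=0))
        m.add_reaction(Reaction("sink", {"pool": -1.0}, lb=0, ub=0))
        m.objective_reaction_id = "sink"
        raw = -rng.uniform(0.01, 1.0)
        out = rescale_pseudoreaction(
            m, MassRescaleSpec("pseudo", "new", new_coefficient_raw=raw)
        )
        new_stoich = out.reactions["pseudo"].stoich
        m0 = sum(abs(c) * masses[s] for s, c in coeffs.items())
        total_after = sum(
            abs(new_stoich[s]) * m.metabolites[s].mass_override
            for s in list(coeffs) + ["new"]
        )
        assert total_after == pytest.approx(m0, abs=1e-9 * max(1.0, m0))
        for s1 in coeffs:
            for s2 in coeffs:
                assert new_stoich[s1] / new_stoich[s2] == pytest.approx(
                    coeffs[s1] / coeffs[s2], abs=1e-9
                )


def test_rescale_final_coefficient_inversion():
    """Specifying the final coefficient reproduces it exactly in the
    rescaled stoichiometry while still conserving total mass."""
    m = _pool_model()
    out = rescale_pseudoreaction(
        m, MassRescaleSpec("pseudo", "new", new_coefficient_final=-0.8)
    )
    stoich = out.reactions["pseudo"].stoich
    assert stoich["new"] == pytest.approx(-0.8, abs=1e-12)
    total = sum(
        abs(c) * m.metabolites[s].mass_override
        for s, c in stoich.items()
        if c < 0
    )
    assert total == pytest.approx(200.0, abs=1e-9)


def test_rescale_missing_mass_names_metabolite():
    m = _pool_model()
    m.metabolites["b"].mass_override = None
    with pytest.raises(ModelError, match="b"):
        rescale_pseudoreaction(
            m, MassRescaleSpec("pseudo", "new", new_coefficient_raw=-1.0)
        )


def test_mass_spec_requires_exactly_one_coefficient():
    with pytest.raises(ValueError):
        MassRescaleSpec("pseudo", "new")
    with pytest.raises(ValueError):
        MassRescaleSpec("pseudo", "new", new_coefficient_raw=-1.0,
                        new_coefficient_final=-0.8)


# ---------------------------------------------------------------- append

def test_pseudo_append_and_degenerate_inputs():
    m = _pool_model()
    out = pseudo_append(m, "pseudo", "new", -1e-06)
    assert out.reactions["pseudo"].stoich["new"] == -1e-06
    # other coefficients untouched (no rescaling)
    assert out.reactions["pseudo"].stoich["a"] == -1.0
    with pytest.raises(ModelError, match="already present"):
        pseudo_append(out, "pseudo", "new", -1e-06)
    with pytest.raises(ModelError, match="nonzero"):
        pseudo_append(m, "pseudo", "new", 0.0)


# ---------------------------------------------------------------- equations

@pytest.mark.parametrize(
    "equation,n_terms,reversible",
    [
        ("a[c] + 2 b[c] => c[c]", 3, False),
        ("heme a[e] =>", 1, False),
        ("x[c] <=> y[c]", 2, True),
        ("0.74851 (1->3)-beta-D-glucan[ce] + 0.13828 trehalose[c] => carbohydrate[c]",
         3, False),
        ("1e-06 heme a[c] => cofactor[c]", 2, False),
    ],
)
def test_equation_parser(equation, n_terms, reversible):
    terms, bounds = parse_reaction_equation(equation)
    assert len(terms) == n_terms
    assert (bounds[0] < 0) == reversible


def test_equation_parser_errors():
    with pytest.raises(ValueError, match="arrow"):
        parse_reaction_equation("a[c] + b[c]")
    with pytest.raises(ValueError, match="term"):
        parse_reaction_equation("a => b")  # missing compartment brackets


# ---------------------------------------------------------------- edit sets

def test_yeast9_set_composition():
    """12 gene-association rewrites, 8 blocks, 2 synthesis reactions,
    1 exchange, 2 pseudoreaction adjustments."""
    edits = yeast9_curation_set()
    kinds = [e.kind for e in edits]
    assert len({e.target for e in edits if e.kind == "set_gpr"}) == 12
    assert kinds.count("block_reaction") + kinds.count("block_reverse") == 8
    assert kinds.count("add_reaction") == 2
    assert kinds.count("add_exchange") == 1
    assert kinds.count("pseudo_add_rescale") + kinds.count("pseudo_append") == 2
    blocked = {e.target for e in edits if e.kind.startswith("block")}
    assert blocked == {"r_0217", "r_0312", "r_4703", "r_0559", "r_1026",
                       "r_2070", "r_2071", "r_0815"}


def test_yeast9_set_applies_to_skeleton(skeleton):
    curated, log = apply_edits(skeleton, yeast9_curation_set())
    # blocked bypasses are pinned to zero flux; reverse block keeps forward
    assert curated.reactions["r_0217"].lb == curated.reactions["r_0217"].ub == 0.0
    assert curated.reactions["r_0815"].lb == 0.0
    assert curated.reactions["r_0815"].ub > 0
    # published coefficients readable from the curated stoichiometry
    assert curated.reactions["r_4048"].stoich["chitin_c"] == pytest.approx(
        -0.02361, abs=1e-12
    )
    assert curated.reactions["r_4598"].stoich["glutathione_c"] == -1e-06
    # carbohydrate reactants shrank proportionally
    before = skeleton.reactions["r_4048"].stoich
    after = curated.reactions["r_4048"].stoich
    ratios = {
        m: after[m] / before[m] for m in before if before[m] < 0
    }
    assert max(ratios.values()) - min(ratios.values()) < 1e-12
    assert 0 < min(ratios.values()) < 1
    # rewritten associations
    assert curated.reactions["r_0250"].gpr_string == "YJL130C or (YJR109C and YOR303W)"
    assert curated.reactions["r_0477"].gpr_string == "YKL104C"
    assert curated.reactions["r_2488"].gpr_string == "YGR157W"
    # additions exist with the new exchange closed for uptake
    assert curated.reactions["r_temp1"].is_exchange
    assert curated.reactions["r_temp1"].lb == 0.0
    assert "r_temp2" in curated.reactions and "r_temp3" in curated.reactions
    assert len(log) == len(yeast9_curation_set())
    # input model untouched
    assert "r_temp1" not in skeleton.reactions


def test_apply_twice_fails_on_duplicate_addition(skeleton):
    curated, _ = apply_edits(skeleton, yeast9_curation_set())
    with pytest.raises(EditApplicationError, match="r_temp1"):
        apply_edits(curated, yeast9_curation_set())


def test_failed_edit_reports_index_and_leaves_model_untouched(basic_toy):
    model, _ = basic_toy
    edits = [
        CurationEdit("block_reaction", "EX_substrate"),
        CurationEdit("block_reaction", "no_such_reaction"),
    ]
    before = model.to_dict()
    with pytest.raises(EditApplicationError) as err:
        apply_edits(model, edits)
    assert err.value.index == 1
    assert model.to_dict() == before


def test_empty_edit_list_is_identity(basic_toy):
    model, _ = basic_toy
    out, log = apply_edits(model, [])
    assert out.to_dict() == model.to_dict()
    assert log == []


def test_edit_yaml_roundtrip(tmp_path):
    edits = yeast9_curation_set()
    path = tmp_path / "edits.yaml"
    edits_to_yaml(edits, path)
    loaded = edits_from_yaml(path)
    assert [e.to_dict() for e in loaded] == [e.to_dict() for e in edits]


def test_unknown_edit_kind_rejected():
    with pytest.raises(ValueError, match="unknown curation edit kind"):
        CurationEdit("transmogrify", "r_1")


def test_replayability_on_reloaded_model(skeleton, tmp_path):
    """save(apply(edits)) equals apply(edits) on the reloaded model."""
    from auxogem.io import load_model, save_model

    edits = yeast9_curation_set()
    curated, _ = apply_edits(skeleton, edits)
    path = tmp_path / "skeleton.json"
    save_model(skeleton, path)
    curated2, _ = apply_edits(load_model(path), edits)
    assert curated2.to_dict() == curated.to_dict()
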