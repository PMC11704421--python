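"""Flux balance analysis: LP correctness, knockouts, uptake, viability."""

import itertools
import random

import pytest

from auxogem import (
    ViabilityPolicy,
    apply_knockout,
    is_viable,
    open_uptake,
    solve_fba,
    wild_type_growth,
)
from auxogem.fba import SolverError
from auxogem.fixtures import (
    PrecursorFlags,
    ToyGemConfig,
    lp_vertex_max,
    make_toy_gem,
    random_tiny_model,
)
from auxogem.model import ModelError


def test_toy_optimum_matches_closed_form(basic_toy):
    model, truth = basic_toy
    sol = solve_fba(model)
    assert sol.status == "optimal"
    assert sol.objective == pytest.approx(truth.wt_growth, abs=1e-8)


def test_flux_solution_satisfies_constraints(basic_toy):
    model, _ = basic_toy
    sol = solve_fba(model)
    for rid, flux in sol.fluxes.items():
        rxn = model.reactions[rid]
        assert rxn.lb - 1e-9 <= flux <= rxn.ub + 1e-9
    # steady state: per-metabolite net production is zero
    balance = {m: 0.0 for m in model.metabolites}
    for rid, flux in sol.fluxes.items():
        for met, coeff in model.reactions[rid].stoich.items():
            balance[met] += coeff * flux
    assert max(abs(v) for v in balance.values()) < 1e-6


def test_blocked_biomass_gives_zero(basic_toy):
    model, _ = basic_toy
    blocked = model.copy()
    blocked.reactions["biomass"].lb = 0.0
    blocked.reactions["biomass"].ub = 0.0
    assert solve_fba(blocked).objective == pytest.approx(0.0, abs=1e-9)


def test_wild_type_growth_caches_and_errors(basic_toy):
    model, truth = basic_toy
    assert wild_type_growth(model) == pytest.approx(truth.wt_growth, abs=1e-8)
    blocked = model.copy()
    blocked.reactions["biomass"].ub = 0.0
    with pytest.raises(ModelError, match="cannot grow"):
        wild_type_growth(blocked)


def test_lp_oracle_equivalence_random_models():
    """HiGHS optimum equals exhaustive vertex enumeration on random tiny
    networks (both report the same infeasibility calls)."""
    rng = random.Random(7)
    for _ in range(60):
        model = random_tiny_model(rng)
        expected = lp_vertex_max(model)
        sol = solve_fba(model)
        got = sol.objective if sol.status == "optimal" else None
        assert (expected is None) == (got is None)
        if expected is not None:
            assert got == pytest.approx(expected, abs=1e-6)


def test_knockout_semantics(trap_toy, trap_policy):
    model, truth = trap_toy
    wt = trap_policy.reference_growth
    for gene in sorted(model.genes):
        ko = apply_knockout(model, {gene})
        growth = solve_fba(ko).growth
        assert growth <= wt + 1e-6  # knockouts only add constraints
        if gene in truth.essential_genes:
            assert not is_viable(growth, trap_policy)


def test_nested_knockouts_monotone(basic_toy):
    model, truth = basic_toy
    genes = sorted(truth.essential_genes)[:3]
    prev = solve_fba(model).growth
    for k in range(1, len(genes) + 1):
        growth = solve_fba(apply_knockout(model, set(genes[:k]))).growth
        assert growth <= prev + 1e-6
        prev = growth


def test_knockout_unknown_gene_errors(basic_toy):
    model, _ = basic_toy
    with pytest.raises(ModelError):
        apply_knockout(model, {"NOT_A_GENE"})


def test_open_uptake_monotone_and_idempotent(basic_toy):
    model, _ = basic_toy
    base = solve_fba(model).growth
    for ex in [r.id for r in model.reactions.values() if r.is_exchange]:
        opened = open_uptake(model, ex, -1000.0)
        assert solve_fba(opened).growth >= base - 1e-6
        again = open_uptake(opened, ex, -1000.0)
        assert again.reactions[ex].lb == opened.reactions[ex].lb


def test_open_uptake_rejects_non_exchange(basic_toy):
    model, _ = basic_toy
    with pytest.raises(ModelError, match="not an exchange"):
        open_uptake(model, "biomass")
    with pytest.raises(ModelError, match="unknown"):
        open_uptake(model, "EX_missing")


@pytest.mark.parametrize(
    "growth,reference,expected",
    [
        (0.0859, 0.0859, True),
        (0.0, 0.0859, False),
        (0.01 * 0.0859, 0.0859, True),  # exactly at the 1% threshold: viable
        (0.000858, 0.0859, False),
    ],
)
def test_viability_threshold(growth, reference, expected):
    policy = ViabilityPolicy(reference_growth=reference, fraction=0.01)
    assert is_viable(growth, policy) is expected


def test_policy_validation():
    with pytest.raises(ValueError):
        ViabilityPolicy(reference_growth=-1.0)
    with pytest.raises(ValueError):
        ViabilityPolicy(reference_growth=1.0, fraction=1.5)


def test_infeasible_maps_to_zero_growth():
    """A model forced to export what it cannot make is infeasible, which
    counts as zero growth and inviable under any policy."""
    from auxogem.model import GEMModel, Metabolite, Reaction

    m = GEMModel(id="infeasible")
    m.add_metabolite(Metabolite("x_c"))
    m.add_reaction(Reaction("sink", {"x_c": -1.0}, lb=5.0, ub=10.0))
    m.add_reaction(Reaction("obj", {"x_c": 1.0}, lb=0.0, ub=1.0))
    m.objective_reaction_id = "obj"
    # x production capped at 1 but sink demands >= 5: infeasible
    sol = solve_fba(m)
    assert sol.status == "infeasible"
    assert sol.growth == 0.0
    assert not is_viable(sol.growth, ViabilityPolicy(reference_growth=1.0))


def test_cross_check_against_cobrapy(trap_toy):
    """Independent implementation check: cobrapy/GLPK reproduces our
    optimum on the trap-laden toy network."""
    cobra = pytest.importorskip("cobra")
    model, _ = trap_toy
    cm = cobra.Model(model.id)
    cm.add_metabolites(
        [cobra.Metabolite(m.id, compartment=m.compartment)
         for m in model.metabolites.values()]
    )
    cm.add_reactions(
        [cobra.Reaction(r.id, lower_bound=r.lb, upper_bound=r.ub)
         for r in model.reactions.values()]
    )
    for r in model.reactions.values():
        cm.reactions.get_by_id(r.id).add_metabolites(
            {cm.metabolites.get_by_id(k): v for k, v in r.stoich.items()}
        )
    cm.objective = model.objective_reaction_id
    assert cm.slim_optimize() == pytest.approx(solve_fba(model).objective, abs=1e-6)
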