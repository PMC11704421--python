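"""Generator determinism, config validation, oracle guards."""

import pytest

from auxogem.fixtures import (
    PrecursorFlags,
    ToyGemConfig,
    lp_vertex_max,
    make_synthetic_dataset,
    make_toy_gem,
    gpr_truthtable,
)
from auxogem.gpr import parse_gpr
from auxogem.io import save_model
from auxogem.model import GEMModel, Metabolite, Reaction, validate_model
from auxogem.pipeline import write_dataset


def test_same_seed_byte_identical_files(tmp_path):
    for sub in ("a", "b"):
        out = tmp_path / sub
        out.mkdir()
        model, truth = make_toy_gem(ToyGemConfig(seed=17))
        records, _ = make_synthetic_dataset(truth, noise=0.25, seed=17)
        save_model(model, out / "model.json")
        write_dataset(records, out / "dataset.tsv")
    assert (tmp_path / "a/model.json").read_bytes() == (tmp_path / "b/model.json").read_bytes()
    assert (tmp_path / "a/dataset.tsv").read_bytes() == (tmp_path / "b/dataset.tsv").read_bytes()


def test_different_seed_changes_labels_not_topology():
    m1, t1 = make_toy_gem(ToyGemConfig(pathway_lengths=2, seed=1))
    m2, t2 = make_toy_gem(ToyGemConfig(pathway_lengths=2, seed=2))
    assert set(m1.reactions) == set(m2.reactions)
    # the label pool is fixed; the seed permutes which gene sits on which step
    assert t1.rescue_pairs != t2.rescue_pairs
    assert t1.wt_growth == t2.wt_growth


def test_no_trap_config_counts(basic_toy):
    from auxogem import Classification

    model, truth = basic_toy
    assert validate_model(model) == []
    assert len(truth.essential_genes) == 3
    assert len(truth.rescue_pairs) == 3
    assert all(c == Classification.CORRECT for c in truth.expected_pre.values())


@pytest.mark.parametrize(
    "features,message",
    [
        ((PrecursorFlags(bypass=True, no_exchange=True),), "contradictory"),
        ((PrecursorFlags(medium_conditional=True, bypass=True),), "bypass"),
        ((PrecursorFlags(isoenzyme=True, complex_step=True),), "collide"),
    ],
)
def test_contradictory_flags_rejected(features, message):
    with pytest.raises(ValueError, match=message):
        make_toy_gem(ToyGemConfig(n_precursors=1, features=features))


def test_noise_bounds_and_counts(trap_toy):
    _, truth = trap_toy
    with pytest.raises(ValueError):
        make_synthetic_dataset(truth, noise=1.0)
    records, flags = make_synthetic_dataset(truth, noise=0.2, seed=0, n_records=20)
    assert len(records) == 20
    assert sum(flags) == 4


def test_multistep_pathways_extend_gene_count():
    model, truth = make_toy_gem(ToyGemConfig(n_precursors=2, pathway_lengths=3, seed=0))
    assert len(truth.essential_genes) == 6
    assert validate_model(model) == []


def test_truthtable_oracle_guard():
    expr = parse_gpr(" or ".join(f"g{i}" for i in range(9)))
    with pytest.raises(ValueError, match="8"):
        gpr_truthtable(expr)


def test_vertex_oracle_guard_and_closed_form():
    m = GEMModel(id="chain")
    m.add_metabolite(Metabolite("x"))
    m.add_reaction(Reaction("in", {"x": 1.0}, lb=0, ub=10))
    m.add_reaction(Reaction("out", {"x": -1.0}, lb=0, ub=1000))
    m.objective_reaction_id = "out"
    assert lp_vertex_max(m) == pytest.approx(10.0)
    big = GEMModel(id="big")
    big.add_metabolite(Metabolite("x"))
    for i in range(9):
        big.add_reaction(Reaction(f"r{i}", {"x": 1.0 if i % 2 else -1.0}, lb=0, ub=1))
    big.objective_reaction_id = "r0"
    with pytest.raises(ValueError, match="8"):
        lp_vertex_max(big)


def test_skeleton_validates_and_carries_published_state(skeleton):
    assert validate_model(skeleton) == []
    assert skeleton.reactions["r_0080"].gpr_string == "YGL125W and YPL023C"
    assert skeleton.reactions["r_4048"].stoich["trehalose_c"] == -0.13828
    assert skeleton.reactions["r_4598"].stoich["heme_a_c"] == -1e-06
    # reversible published reactions round-trip their bounds
    assert skeleton.reactions["r_0815"].lb < 0 < skeleton.reactions["r_0815"].ub
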