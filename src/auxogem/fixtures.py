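"""Deterministic toy models, synthetic datasets, and brute-force oracles.

The toy GEM emulates, at miniature scale, the network motifs behind
auxotrophy mispredictions:

* a substrate exchange feeding linear, gene-labelled biosynthesis
  pathways (one per biomass precursor) plus a small energy loop;
* isoenzyme (OR) and enzyme-complex (AND) gene associations;
* compensatory bypass reactions that keep a knockout viable when the
  experiment says lethal (planted type-I traps, repaired by blocking
  the bypass);
* precursors with no boundary exchange, so the rescue compound cannot be
  supplied (planted type-II traps, repaired by adding the exchange);
* a precursor whose pathway gene also feeds a vitamin demanded by
  biomass, so the rescue only works with the vitamin in the medium.

Topology is fully determined by the configuration; the seed only permutes
the gene labels, which keeps every expected quantity in closed form:
with uptake U, n precursors (unit stoichiometry), one ATP per unit
biomass at two ATP per substrate, and k medium-conditional vitamins, the
wild-type optimum is U / (n + k + 1/2).

The generator's defaults (uptake 10 mmol/gDW/h, three precursors,
single-step pathways, 1% viability threshold downstream) define the
reference test conditions used throughout the suite.

Also here: the brute-force oracles (GPR truth table, LP vertex
enumeration, exhaustive rescue search) and a synthetic Yeast9-shaped
skeleton model for replaying the consensus-model curation set offline.
"""

from __future__ import annotations

import itertools
import random
from dataclasses import dataclass, field

import numpy as np

from .curation import CurationEdit, parse_reaction_equation
from .fba import DEFAULT_UPTAKE_BOUND, ViabilityPolicy, is_viable, open_uptake, solve_fba
from .gpr import GprExpr, gpr_genes, parse_gpr
from .model import GEMModel, Metabolite, Reaction, disabled_reactions
from .pipeline import AuxotrophyRecord, Classification

__all__ = [
    "PrecursorFlags",
    "ToyGemConfig",
    "PlantedTruth",
    "make_toy_gem",
    "make_synthetic_dataset",
    "gpr_truthtable",
    "lp_vertex_max",
    "rescue_bruteforce",
    "random_gpr",
    "random_tiny_model",
    "yeast9_skeleton",
]


@dataclass(frozen=True)
class PrecursorFlags:
    """Structural features planted on one precursor's pathway."""

    isoenzyme: bool = False  # first step carried by an OR pair
    complex_step: bool = False  # last step carried by an AND pair
    bypass: bool = False  # gene-free shortcut: type-I trap
    no_exchange: bool = False  # no boundary exchange: type-II trap
    medium_conditional: bool = False  # rescue needs a vitamin in the medium


@dataclass
class ToyGemConfig:
    n_precursors: int = 3
    pathway_lengths: int | tuple[int, ...] = 1
    features: tuple[PrecursorFlags, ...] | None = None
    substrate_uptake: float = 10.0
    pseudo_masses: dict[str, float] = field(
        default_factory=lambda: {"pool_a": 100.0, "pool_b": 100.0}
    )
    pseudo_new_species: tuple[str, float] = ("pool_new", 50.0)
    alt_carbon_source: bool = False
    seed: int = 0

    def resolved(self) -> tuple[tuple[int, ...], tuple[PrecursorFlags, ...]]:
        if self.n_precursors < 1:
            raise ValueError("need at least one precursor")
        lengths = (
            (self.pathway_lengths,) * self.n_precursors
            if isinstance(self.pathway_lengths, int)
            else tuple(self.pathway_lengths)
        )
        feats = self.features or tuple(
            PrecursorFlags() for _ in range(self.n_precursors)
        )
        if len(lengths) != self.n_precursors or len(feats) != self.n_precursors:
            raise ValueError("pathway_lengths/features length mismatch")
        for i, (L, f) in enumerate(zip(lengths, feats)):
            if L < 1:
                raise ValueError(f"precursor {i}: pathway length must be >= 1")
            if f.bypass and f.no_exchange:
                raise ValueError(
                    f"precursor {i}: bypass and no_exchange are contradictory traps"
                )
            if f.medium_conditional and f.bypass:
                raise ValueError(
                    f"precursor {i}: medium_conditional cannot combine with bypass"
                )
            if f.isoenzyme and f.complex_step and L == 1:
                raise ValueError(
                    f"precursor {i}: isoenzyme and complex collide on a 1-step pathway"
                )
        return lengths, feats


@dataclass
class PlantedTruth:
    """Ground truth wired into a generated toy model."""

    wt_growth: float
    essential_genes: set[str]
    rescue_pairs: dict[str, tuple[str, str]]  # gene -> (exchange id, compound)
    records: list[AuxotrophyRecord]
    expected_pre: dict[str, Classification]
    expected_post: dict[str, Classification]
    repair_edits: list[CurationEdit]


def _gene_labels(count: int, seed: int) -> list[str]:
    pool = [
        f"Y{chr(65 + i // 26 % 26)}{chr(65 + i % 26)}{100 + i}{'WC'[i % 2]}"
        for i in range(count)
    ]
    rng = random.Random(seed)
    rng.shuffle(pool)
    return pool


def make_toy_gem(config: ToyGemConfig) -> tuple[GEMModel, PlantedTruth]:
    """Build the toy model and its planted ground truth."""
    lengths, feats = config.resolved()
    n = config.n_precursors
    n_cond = sum(f.medium_conditional for f in feats)
    n_genes_needed = sum(
        L + f.isoenzyme + f.complex_step for L, f in zip(lengths, feats)
    )
    labels = iter(_gene_labels(n_genes_needed, config.seed))

    model = GEMModel(id=f"toy_gem_seed{config.seed}")

    def met(mid: str, name: str = "", comp: str = "c", mass: float | None = None):
        if mid not in model.metabolites:
            model.add_metabolite(
                Metabolite(id=mid, name=name or mid.rsplit("_", 1)[0],
                           compartment=comp, mass_override=mass)
            )

    met("substrate_e", "substrate", "e")
    met("substrate_c", "substrate", "c")
    met("atp_c", "atp", "c")
    model.add_reaction(
        Reaction("EX_substrate", {"substrate_e": -1.0},
                 lb=-config.substrate_uptake, ub=1000.0, is_exchange=True)
    )
    model.add_reaction(
        Reaction("T_substrate", {"substrate_e": -1.0, "substrate_c": 1.0},
                 lb=-1000.0, ub=1000.0)
    )
    model.add_reaction(
        Reaction("energy", {"substrate_c": -1.0, "atp_c": 2.0}, lb=0.0, ub=1000.0)
    )

    biomass_stoich: dict[str, float] = {"atp_c": -1.0}
    essential: set[str] = set()
    rescue_pairs: dict[str, tuple[str, str]] = {}
    records: list[AuxotrophyRecord] = []
    expected_pre: dict[str, Classification] = {}
    expected_post: dict[str, Classification] = {}
    repair_edits: list[CurationEdit] = []

    for i, (L, f) in enumerate(zip(lengths, feats), start=1):
        prec = f"prec{i}"
        met(f"{prec}_c", prec, "c")
        biomass_stoich[f"{prec}_c"] = -1.0
        chain = ["substrate_c"] + [f"{prec}_m{j}" for j in range(1, L)] + [f"{prec}_c"]
        for mid in chain[1:-1]:
            met(mid, mid, "c")

        step_genes: list[list[str]] = []
        for j in range(L):
            if f.isoenzyme and j == 0:
                step_genes.append([next(labels), next(labels)])
            elif f.complex_step and j == L - 1:
                step_genes.append([next(labels), next(labels)])
            else:
                step_genes.append([next(labels)])
        for j in range(L):
            genes = step_genes[j]
            if len(genes) == 1:
                gpr = genes[0]
            elif f.complex_step and j == L - 1:
                gpr = " and ".join(genes)
            else:
                gpr = " or ".join(genes)
            model.add_reaction(
                Reaction(
                    f"P{i}_step{j + 1}",
                    {chain[j]: -1.0, chain[j + 1]: 1.0},
                    lb=0.0, ub=1000.0, gpr=parse_gpr(gpr),
                )
            )

        # boundary machinery: extracellular species + transporter always,
        # the exchange itself only when the trap flag is off
        met(f"{prec}_e", prec, "e")
        model.add_reaction(
            Reaction(f"T_{prec}", {f"{prec}_e": -1.0, f"{prec}_c": 1.0},
                     lb=-1000.0, ub=1000.0)
        )
        exchange_id = f"EX_{prec}"
        if not f.no_exchange:
            model.add_reaction(
                Reaction(exchange_id, {f"{prec}_e": -1.0},
                         lb=0.0, ub=1000.0, is_exchange=True)
            )
        else:
            repair_edits.append(
                CurationEdit(
                    "add_exchange", exchange_id,
                    payload={"metabolite": f"{prec}_e"},
                    provenance={"trap": "no_exchange", "precursor": prec},
                )
            )

        if f.bypass:
            model.add_reaction(
                Reaction(f"BY_{prec}", {"substrate_c": -1.0, f"{prec}_c": 1.0},
                         lb=0.0, ub=1000.0)
            )
            repair_edits.append(
                CurationEdit(
                    "block_reaction", f"BY_{prec}",
                    provenance={"trap": "bypass", "precursor": prec},
                )
            )

        supplements: tuple[str, ...] = ()
        if f.medium_conditional:
            vit = f"vit{i}"
            met(f"{vit}_c", vit, "c")
            met(f"{vit}_e", vit, "e")
            biomass_stoich[f"{vit}_c"] = -1.0
            # vitamin synthesis shares the first pathway gene
            model.add_reaction(
                Reaction(f"VS_{prec}", {"substrate_c": -1.0, f"{vit}_c": 1.0},
                         lb=0.0, ub=1000.0, gpr=parse_gpr(step_genes[0][0]))
            )
            model.add_reaction(
                Reaction(f"T_{vit}", {f"{vit}_e": -1.0, f"{vit}_c": 1.0},
                         lb=-1000.0, ub=1000.0)
            )
            model.add_reaction(
                Reaction(f"EX_{vit}", {f"{vit}_e": -1.0},
                         lb=0.0, ub=1000.0, is_exchange=True)
            )
            supplements = (vit,)

        # which genes is the deletion experimentally lethal for?
        lethal_genes = [
            gs[0] for j, gs in enumerate(step_genes)
            if not (f.isoenzyme and j == 0)
        ]
        if f.complex_step:
            lethal_genes.extend(step_genes[-1][1:])

        for gene in lethal_genes:
            if not f.bypass:
                essential.add(gene)
                # the shared medium-conditional gene also starves the
                # vitamin, so no single exchange can rescue it
                shared = f.medium_conditional and gene == step_genes[0][0]
                if not f.no_exchange and not shared:
                    rescue_pairs[gene] = (exchange_id, prec)
            record = AuxotrophyRecord(
                knockout_genes=(gene,),
                rescue_spec=((prec,),),
                medium_supplements=supplements,
                strain_background="toy",
                reference=f"planted:{prec}",
            )
            records.append(record)
            if f.bypass:
                expected_pre[record.key] = Classification.TYPE_I
            elif f.no_exchange:
                expected_pre[record.key] = Classification.TYPE_II
            else:
                expected_pre[record.key] = Classification.CORRECT
            expected_post[record.key] = Classification.CORRECT

    if config.alt_carbon_source:
        met("altcarbon_e", "altcarbon", "e")
        met("altcarbon_c", "altcarbon", "c")
        model.add_reaction(
            Reaction("EX_altcarbon", {"altcarbon_e": -1.0},
                     lb=0.0, ub=1000.0, is_exchange=True)
        )
        model.add_reaction(
            Reaction("T_altcarbon", {"altcarbon_e": -1.0, "altcarbon_c": 1.0},
                     lb=-1000.0, ub=1000.0)
        )
        model.add_reaction(
            Reaction("ALT_to_substrate", {"altcarbon_c": -1.0, "substrate_c": 1.0},
                     lb=0.0, ub=1000.0)
        )

    # mass-annotated pseudoreaction for rescale exercises (flux-inert)
    pool_members = list(config.pseudo_masses)
    met("pool_c", "pool", "c")
    for name, mass in config.pseudo_masses.items():
        met(f"{name}_c", name, "c", mass=mass)
    new_name, new_mass = config.pseudo_new_species
    met(f"{new_name}_c", new_name, "c", mass=new_mass)
    model.add_reaction(
        Reaction(
            "pseudo_pool",
            {**{f"{m}_c": -1.0 for m in pool_members}, "pool_c": 1.0},
            lb=0.0, ub=0.0,
        )
    )

    model.add_reaction(Reaction("biomass", biomass_stoich, lb=0.0, ub=1000.0))
    model.objective_reaction_id = "biomass"

    wt = config.substrate_uptake / (n + n_cond + 0.5)
    truth = PlantedTruth(
        wt_growth=wt,
        essential_genes=essential,
        rescue_pairs=rescue_pairs,
        records=records,
        expected_pre=expected_pre,
        expected_post=expected_post,
        repair_edits=repair_edits,
    )
    return model, truth


def make_synthetic_dataset(
    truth: PlantedTruth,
    noise: float = 0.0,
    seed: int = 0,
    n_records: int | None = None,
) -> tuple[list[AuxotrophyRecord], list[bool]]:
    """Dataset records from the planted truth, with a seeded fraction
    corrupted to carry the wrong rescue compound.

    Returns the records and a parallel ``corrupted`` flag list; exactly
    ``round(noise * n)`` records are corrupted.
    """
    if not (0 <= noise < 1):
        raise ValueError("noise must be in [0, 1)")
    base = truth.records
    if not base:
        return [], []
    n = n_records if n_records is not None else len(base)
    records = [base[i % len(base)] for i in range(n)]
    k = round(noise * n)
    rng = random.Random(seed)
    corrupt_idx = set(rng.sample(range(n), k))
    compounds = sorted({r.rescue_spec[0][0] for r in base} | {"substrate"})
    out: list[AuxotrophyRecord] = []
    flags: list[bool] = []
    for i, rec in enumerate(records):
        if i in corrupt_idx:
            right = rec.rescue_spec[0][0]
            wrong = rng.choice([c for c in compounds if c != right] or ["substrate"])
            rec = AuxotrophyRecord(
                knockout_genes=rec.knockout_genes,
                rescue_spec=((wrong,),),
                medium_supplements=rec.medium_supplements,
                strain_background=rec.strain_background,
                reference=rec.reference + ";corrupted",
            )
            flags.append(True)
        else:
            flags.append(False)
        out.append(rec)
    return out, flags


# --------------------------------------------------------------------------
# oracles
# --------------------------------------------------------------------------

def gpr_truthtable(expr: GprExpr) -> dict[frozenset, bool]:
    """Exhaustive truth table over every deletion subset of the rule's
    genes, computed via compiled Python boolean source (an independent
    evaluation route from the tree walker)."""
    genes = sorted(gpr_genes(expr))
    if len(genes) > 8:
        raise ValueError("truth-table oracle limited to 8 genes")
    index = {g: i for i, g in enumerate(genes)}

    def to_source(e: GprExpr) -> str:
        from .gpr import GprAnd, GprEmpty, GprGene, GprOr

        if isinstance(e, GprEmpty):
            return "True"
        if isinstance(e, GprGene):
            return f"s[{index[e.gene]}]"
        op = " and " if isinstance(e, GprAnd) else " or "
        return "(" + op.join(to_source(a) for a in e.args) + ")"

    code = compile(to_source(expr), "<gpr>", "eval")
    table: dict[frozenset, bool] = {}
    for states in itertools.product([True, False], repeat=len(genes)):
        deleted = frozenset(g for g, alive in zip(genes, states) if not alive)
        table[deleted] = bool(eval(code, {"s": states}))
    return table


def lp_vertex_max(model: GEMModel, objective: str | None = None) -> float | None:
    """FBA optimum by exhaustive vertex enumeration (<= 8 reactions).

    Every basic feasible solution fixes exactly n - rank(S) fluxes at a
    bound and solves the remaining square system; the maximum objective
    over all of them is the LP optimum.  Returns None when no vertex is
    feasible (infeasible LP).
    """
    rxn_ids = list(model.reactions)
    nr = len(rxn_ids)
    if nr > 8:
        raise ValueError("vertex-enumeration oracle limited to 8 reactions")
    objective = objective or model.objective_reaction_id
    met_ids = list(model.metabolites)
    S = np.zeros((len(met_ids), nr))
    for j, rid in enumerate(rxn_ids):
        for m, coeff in model.reactions[rid].stoich.items():
            S[met_ids.index(m), j] = coeff
    lb = np.array([model.reactions[r].lb for r in rxn_ids])
    ub = np.array([model.reactions[r].ub for r in rxn_ids])
    c = np.zeros(nr)
    c[rxn_ids.index(objective)] = 1.0
    rank = np.linalg.matrix_rank(S) if S.size else 0
    n_fixed = nr - rank

    best: float | None = None
    for fixed in itertools.combinations(range(nr), n_fixed):
        free = [j for j in range(nr) if j not in fixed]
        S_free = S[:, free]
        if free and np.linalg.matrix_rank(S_free) < len(free):
            continue  # free part not uniquely determined: not a basis
        for choice in itertools.product([0, 1], repeat=n_fixed):
            v = np.zeros(nr)
            for j, pick in zip(fixed, choice):
                v[j] = ub[j] if pick else lb[j]
            if free:
                rhs = -S[:, fixed] @ v[list(fixed)] if fixed else np.zeros(S.shape[0])
                sol, *_ = np.linalg.lstsq(S_free, rhs, rcond=None)
                v[free] = sol
            if np.max(np.abs(S @ v)) > 1e-7:
                continue
            if np.any(v < lb - 1e-9) or np.any(v > ub + 1e-9):
                continue
            value = float(c @ v)
            if best is None or value > best:
                best = value
    return best


def rescue_bruteforce(
    model: GEMModel,
    policy: ViabilityPolicy | None = None,
    uptake_bound: float = DEFAULT_UPTAKE_BOUND,
) -> set[tuple[str, str]]:
    """Exhaustive (gene, exchange) rescue pairs by plain re-enumeration:
    fresh model copies and independent FBA solves for every combination,
    with none of the screen's caching or matrix reuse."""
    if policy is None:
        policy = ViabilityPolicy.from_model(model)
    exchanges = sorted(r.id for r in model.reactions.values() if r.is_exchange)
    pairs: set[tuple[str, str]] = set()
    for gene in sorted(model.genes):
        ko = model.copy()
        for rid in disabled_reactions(model, {gene}):
            ko.reactions[rid].lb = 0.0
            ko.reactions[rid].ub = 0.0
        if is_viable(solve_fba(ko).growth, policy):
            continue
        for ex in exchanges:
            rescued = open_uptake(ko, ex, uptake_bound)
            if is_viable(solve_fba(rescued).growth, policy):
                pairs.add((gene, ex))
    return pairs


# --------------------------------------------------------------------------
# random instances for oracle-equivalence checks
# --------------------------------------------------------------------------

def random_gpr(rng: random.Random, max_genes: int = 8) -> GprExpr:
    """Random boolean rule over at most *max_genes* gene symbols."""
    genes = [f"g{i}" for i in range(rng.randint(1, max_genes))]

    def build(depth: int) -> str:
        if depth >= 3 or rng.random() < 0.4:
            return rng.choice(genes)
        op = rng.choice([" and ", " or "])
        k = rng.randint(2, 3)
        return "(" + op.join(build(depth + 1) for _ in range(k)) + ")"

    return parse_gpr(build(0))


def random_tiny_model(rng: random.Random) -> GEMModel:
    """Random small flux network (<= 6 metabolites, <= 8 reactions) with
    finite bounds containing 0, so the LP always has an optimum."""
    n_mets = rng.randint(1, 6)
    n_rxns = rng.randint(2, 8)
    model = GEMModel(id="tiny")
    for i in range(n_mets):
        model.add_metabolite(Metabolite(id=f"m{i}", name=f"m{i}"))
    for j in range(n_rxns):
        stoich = {}
        for i in rng.sample(range(n_mets), rng.randint(1, min(3, n_mets))):
            coeff = rng.choice([-2, -1, 1, 2])
            stoich[f"m{i}"] = float(coeff)
        lb = rng.choice([-10.0, -5.0, 0.0])
        ub = rng.choice([0.0, 5.0, 10.0])
        model.add_reaction(Reaction(id=f"r{j}", stoich=stoich, lb=lb, ub=ub))
    model.objective_reaction_id = f"r{n_rxns - 1}"
    return model


# --------------------------------------------------------------------------
# synthetic consensus-model skeleton
# --------------------------------------------------------------------------

def yeast9_skeleton() -> GEMModel:
    """Synthetic skeleton of the Yeast9 consensus model.

    A stand-in containing only the reactions targeted by the
    auxotrophy curation set, with their published equations, flux bounds
    and pre-curation gene associations, plus the carbohydrate and
    cofactor pseudoreactions with per-species mass annotations.  It
    exists so the full curation set can be replayed and audited offline;
    it is NOT the consensus model and cannot reproduce its growth
    predictions.
    """
    model = GEMModel(id="yeast9_skeleton_synthetic")

    def add(rid: str, equation: str, gpr: str = "") -> None:
        terms, bounds = parse_reaction_equation(equation)
        stoich: dict[str, float] = {}
        for (name, comp), coeff in terms.items():
            import re as _re

            mid = _re.sub(r"[^A-Za-z0-9]+", "_", name).strip("_").lower() + f"_{comp}"
            if mid not in model.metabolites:
                model.add_metabolite(Metabolite(id=mid, name=name, compartment=comp))
            stoich[mid] = stoich.get(mid, 0.0) + coeff
        model.add_reaction(
            Reaction(rid, stoich, lb=bounds[0], ub=bounds[1], gpr=parse_gpr(gpr))
        )

    add("r_0217", "l-glutamate[m] + oxaloacetate[m] => 2-oxoglutarate[m] + l-aspartate[m]")
    add(
        "r_0172",
        "3-aminopropanal[c] + H2O[c] + NAD[c] => beta-alanine[c] + 2 H+[c] + NADH[c]",
        "YMR110C or YMR169C or YMR170C",
    )
    for n in range(2488, 2496):
        add(
            f"r_{n}",
            "phosphatidylethanolamine[erm] + S-adenosyl-l-methionine[erm] => "
            "H+[erm] + S-adenosyl-l-homocysteine[erm] + "
            "phosphatidyl-N-methylethanolamine[erm]",
            "YGR157W or YJR073C",
        )
    add("r_0312", "hydrogen sulfide[c] + O-acetyl-l-serine[c] => acetate[c] + l-cysteine[c]")
    add(
        "r_4703",
        "TRX1[c] + 3-mercaptopyruvate[c] <=> hydrogen sulfide[c] + pyruvate[c] + "
        "TRX1 disulphide[c]",
    )
    add(
        "r_0559",
        "acetoacetyl-CoA[c] + acetyl-CoA[c] + H2O[c] => "
        "3-hydroxy-3-methylglutaryl-CoA[c] + coenzyme A[c] + H+[c]",
    )
    add(
        "r_4048",
        "0.74851 (1->3)-beta-D-glucan[ce] + 0.25009 (1->6)-beta-D-glucan[ce] + "
        "0.36141 glycogen[c] + 0.71094 mannan[c] + 0.13828 trehalose[c] => "
        "carbohydrate[c]",
    )
    add(
        "r_0477",
        "d-fructose 6-phosphate[c] + l-glutamine[c] => "
        "alpha-d-glucosamine 6-phosphate[c] + l-glutamate[c]",
        "YMR084W or YKL104C",
    )
    add(
        "r_4598",
        "0.00019 coenzyme A[c] + 1e-05 FAD[c] + 0.00265 NAD[c] + 0.00015 NADH[c] + "
        "0.00057 NADP(+)[c] + 0.0027 NADPH[c] + 0.00099 riboflavin[c] + "
        "1.2e-06 TDP[c] + 6.34e-05 THF[c] + 1e-06 heme a[c] => cofactor[c]",
    )
    add(
        "r_1026",
        "ADP[c] + H+[c] + sulfate[c] => 5'-adenylyl sulfate[c] + phosphate[c]",
    )
    add(
        "r_0080",
        "5,10-methylenetetrahydrofolate[c] + H+[c] + NADPH[c] => "
        "5-methyltetrahydrofolate[c] + NADP(+)[c]",
        "YGL125W and YPL023C",
    )
    add(
        "r_0815",
        "l-cysteine[c] + O-succinyl-l-homoserine[c] <=> H+[c] + l-cystathionine[c] + "
        "succinate[c]",
    )
    add(
        "r_2070",
        "H+[c] + l-cysteine[c] + l-glycine[c] + O-acetyl-l-homoserine[c] + "
        "ribose-5-phosphate[c] => 4-methyl-5-(2-phosphonooxyethyl)thiazole[c] + "
        "acetate[c] + ammonium[c] + carbon dioxide[c] + gamma-aminobutyrate[c] + "
        "3 H2O[c] + pyruvate[c]",
    )
    add(
        "r_2071",
        "d-xylulose 5-phosphate[c] + H+[c] + l-cysteine[c] + l-glycine[c] + "
        "O-acetyl-l-homoserine[c] => 4-methyl-5-(2-phosphonooxyethyl)thiazole[c] + "
        "acetate[c] + ammonium[c] + carbon dioxide[c] + gamma-aminobutyrate[c] + "
        "3 H2O[c] + pyruvate[c]",
    )
    add(
        "r_0250",
        "2 ATP[c] + bicarbonate[c] + H2O[c] + l-glutamine[c] => 2 ADP[c] + "
        "carbamoyl phosphate[c] + 2 H+[c] + l-glutamate[c] + phosphate[c]",
        "YJL130C and YJR109C and YOR303W",
    )

    # species referenced only by curation edits
    model.add_metabolite(Metabolite(id="chitin_c", name="chitin", compartment="c"))
    model.add_metabolite(
        Metabolite(id="glutathione_c", name="glutathione", compartment="c")
    )
    # anhydro-monomer mass annotations for the carbohydrate species
    from .curation import CARBOHYDRATE_SPECIES_MASSES

    for mid, mass in CARBOHYDRATE_SPECIES_MASSES.items():
        if mid in model.metabolites:
            model.metabolites[mid].mass_override = mass

    # token biomass objective so the skeleton validates; not for growth runs
    model.add_reaction(
        Reaction("biomass_token", {"carbohydrate_c": -1.0, "cofactor_c": -1.0},
                 lb=0.0, ub=1000.0)
    )
    model.objective_reaction_id = "biomass_token"
    return model
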