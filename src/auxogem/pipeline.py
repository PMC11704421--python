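"""Auxotrophy simulation pipeline.

The core procedure is a two-step growth prediction for a gene–compound
pair (knockout gene(s), rescue compound(s)):

1. delete the gene set and maximize growth; if the knockout is still
   viable the model contradicts the experimentally lethal deletion —
   a **type I** misprediction;
2. otherwise open the rescue compounds' exchange reactions for
   unconstrained uptake (lower bound -1000 mmol/gDW/h) and re-solve;
   if some rescue conjunct restores viability the pair is **correct**,
   and if none does the model cannot realize the experimentally
   sufficient rescue — a **type II** misprediction.

A rescue specification is a disjunction of compound sets (DNF): growth is
restored if *all* compounds of at least one conjunct are supplied (e.g.
homoserine OR (methionine AND threonine)).  Medium supplements (e.g.
thiamine for strains assayed on YNB medium) are opened before both steps.

A rescue compound without a matching exchange reaction simply cannot be
supplied in silico; its conjunct scores zero growth, so heme-like pairs
surface as type II until an exchange is added.  Records explicitly marked
unresolvable in the dataset are excluded from simulation and from the
accuracy denominator, mirroring how compounds with no exchange at all are
excluded during dataset screening.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .fba import (
    DEFAULT_UPTAKE_BOUND,
    ViabilityPolicy,
    apply_knockout,
    build_stoichiometric_matrix,
    is_viable,
    open_uptake,
    solve_fba,
    _solve_lp,
)
from .model import GEMModel, ModelError, disabled_reactions, find_exchange

__all__ = [
    "Classification",
    "AuxotrophyRecord",
    "RescueResult",
    "DatasetSummary",
    "ScreenResult",
    "simulate_rescue",
    "run_dataset",
    "accuracy",
    "essential_genes",
    "substrate_usage",
    "systematic_screen",
    "compare_models",
    "read_dataset",
    "write_dataset",
    "compound_categories",
]


class Classification(str, Enum):
    CORRECT = "CORRECT"
    TYPE_I = "TYPE_I"
    TYPE_II = "TYPE_II"
    UNRESOLVABLE = "UNRESOLVABLE"


@dataclass(frozen=True)
class AuxotrophyRecord:
    """One knockout → rescue observation.

    ``rescue_spec`` is a DNF: a tuple of conjuncts, each a tuple of
    compound names; the strain grows when every compound of at least one
    conjunct is supplied.  ``medium_supplements`` are compounds present in
    the assay medium throughout (both simulation steps).
    """

    knockout_genes: tuple[str, ...]
    rescue_spec: tuple[tuple[str, ...], ...]
    medium_supplements: tuple[str, ...] = ()
    strain_background: str = ""
    reference: str = ""
    unresolvable: bool = False

    def __post_init__(self) -> None:
        if not self.knockout_genes:
            raise ValueError("knockout_genes must be non-empty")
        if not self.rescue_spec or any(not c for c in self.rescue_spec):
            raise ValueError("rescue_spec conjuncts must be non-empty")

    @property
    def key(self) -> str:
        return f"{';'.join(self.knockout_genes)} -> {render_rescue_spec(self.rescue_spec)}"


def render_rescue_spec(spec: tuple[tuple[str, ...], ...]) -> str:
    return " | ".join(" + ".join(conjunct) for conjunct in spec)


def parse_rescue_spec(text: str) -> tuple[tuple[str, ...], ...]:
    conjuncts = []
    for chunk in text.split("|"):
        members = tuple(m.strip() for m in chunk.split("+") if m.strip())
        if members:
            conjuncts.append(members)
    return tuple(conjuncts)


@dataclass
class RescueResult:
    ko_growth: float
    conjunct_growths: dict[str, float]
    classification: Classification
    viable_conjuncts: list[str] = field(default_factory=list)
    unresolved_compounds: list[str] = field(default_factory=list)


def _open_compounds(
    model: GEMModel, compounds: Iterable[str], uptake_bound: float
) -> tuple[GEMModel, list[str]]:
    """Open exchanges for all resolvable compounds; return unresolved ones."""
    unresolved = []
    current = model
    for compound in compounds:
        ex = find_exchange(current, compound)
        if ex is None:
            unresolved.append(compound)
        else:
            current = open_uptake(current, ex, uptake_bound)
    return current, unresolved


def simulate_rescue(
    model: GEMModel,
    record: AuxotrophyRecord,
    policy: ViabilityPolicy | None = None,
    uptake_bound: float = DEFAULT_UPTAKE_BOUND,
) -> RescueResult:
    """Run the two-step knockout → compound-rescue prediction."""
    if record.unresolvable:
        return RescueResult(
            ko_growth=float("nan"),
            conjunct_growths={},
            classification=Classification.UNRESOLVABLE,
        )
    if policy is None:
        policy = ViabilityPolicy.from_model(model)
    for gene in record.knockout_genes:
        if gene not in model.genes:
            raise ModelError(f"knockout gene not in model: {gene!r}")

    base = model
    for compound in record.medium_supplements:
        ex = find_exchange(base, compound)
        if ex is None:
            raise ModelError(f"medium supplement {compound!r} has no exchange")
        base = open_uptake(base, ex, uptake_bound)

    ko = apply_knockout(base, set(record.knockout_genes))
    ko_growth = solve_fba(ko).growth
    if is_viable(ko_growth, policy):
        return RescueResult(
            ko_growth=ko_growth,
            conjunct_growths={},
            classification=Classification.TYPE_I,
        )

    conjunct_growths: dict[str, float] = {}
    viable_conjuncts: list[str] = []
    unresolved_all: list[str] = []
    for conjunct in record.rescue_spec:
        label = " + ".join(conjunct)
        supplied, unresolved = _open_compounds(ko, conjunct, uptake_bound)
        unresolved_all.extend(unresolved)
        if unresolved:
            # the compound cannot be supplied in silico: no rescue possible
            conjunct_growths[label] = 0.0
            continue
        growth = solve_fba(supplied).growth
        conjunct_growths[label] = growth
        if is_viable(growth, policy):
            viable_conjuncts.append(label)

    classification = (
        Classification.CORRECT if viable_conjuncts else Classification.TYPE_II
    )
    return RescueResult(
        ko_growth=ko_growth,
        conjunct_growths=conjunct_growths,
        classification=classification,
        viable_conjuncts=viable_conjuncts,
        unresolved_compounds=unresolved_all,
    )


@dataclass
class DatasetSummary:
    n_records: int = 0
    correct: int = 0
    type_i: int = 0
    type_ii: int = 0
    unresolvable: int = 0

    @property
    def essential_in_silico(self) -> int:
        """Records whose knockout was inviable in step 1."""
        return self.correct + self.type_ii

    @property
    def rescued(self) -> int:
        return self.correct


def run_dataset(
    model: GEMModel,
    records: Sequence[AuxotrophyRecord],
    policy: ViabilityPolicy | None = None,
    uptake_bound: float = DEFAULT_UPTAKE_BOUND,
) -> tuple[list[tuple[AuxotrophyRecord, RescueResult]], DatasetSummary]:
    """Evaluate every record; deterministic iteration in input order."""
    if policy is None:
        policy = ViabilityPolicy.from_model(model)
    results = []
    summary = DatasetSummary()
    counters = {
        Classification.CORRECT: "correct",
        Classification.TYPE_I: "type_i",
        Classification.TYPE_II: "type_ii",
        Classification.UNRESOLVABLE: "unresolvable",
    }
    for record in records:
        result = simulate_rescue(model, record, policy, uptake_bound)
        results.append((record, result))
        summary.n_records += 1
        attr = counters[result.classification]
        setattr(summary, attr, getattr(summary, attr) + 1)
    return results, summary


def accuracy(summary: DatasetSummary) -> float:
    """Fraction of correctly predicted pairs among resolvable records."""
    denom = summary.n_records - summary.unresolvable
    if denom <= 0:
        raise ValueError("accuracy undefined on an empty (or all-unresolvable) dataset")
    return summary.correct / denom


def essential_genes(
    model: GEMModel, policy: ViabilityPolicy | None = None
) -> set[str]:
    """Single-gene deletions over all genes; essential iff KO is inviable.

    A gene whose deletion disables no reaction cannot change the optimum
    and is skipped (the wild type is viable by construction of the
    policy).
    """
    if policy is None:
        policy = ViabilityPolicy.from_model(model)
    essential = set()
    for gene in sorted(model.genes):
        if not disabled_reactions(model, {gene}):
            continue
        growth = solve_fba(apply_knockout(model, {gene})).growth
        if not is_viable(growth, policy):
            essential.add(gene)
    return essential


@dataclass
class ScreenResult:
    """Systematic gene x compound auxotroph screen output.

    ``rescues`` maps each in-silico essential gene to the exchange
    compounds whose individual supplementation restores viability
    (exchange id, compound name, rescue growth).  Every listed pair
    replays as knockout-inviable and rescue-viable under the same policy.
    """

    rescues: dict[str, list[tuple[str, str, float]]]
    essential: list[str]

    def pairs(self) -> list[tuple[str, str]]:
        return [
            (gene, ex) for gene, hits in sorted(self.rescues.items())
            for ex, _name, _g in hits
        ]


def systematic_screen(
    model: GEMModel,
    policy: ViabilityPolicy | None = None,
    compound_filter: Callable[[str], bool] | None = None,
    uptake_bound: float = DEFAULT_UPTAKE_BOUND,
) -> ScreenResult:
    """Knock out every gene; for each inviable knockout, open each
    exchange in turn and record the rescuing compounds.

    Ordering is deterministic (sorted ids).  ``compound_filter`` receives
    an exchange reaction id and may restrict the inner loop (e.g. to amino
    acid exchanges).
    """
    if policy is None:
        policy = ViabilityPolicy.from_model(model)
    exchange_ids = sorted(
        r.id
        for r in model.reactions.values()
        if r.is_exchange and (compound_filter is None or compound_filter(r.id))
    )
    rescues: dict[str, list[tuple[str, str, float]]] = {}
    essential: list[str] = []
    for gene in sorted(model.genes):
        if not disabled_reactions(model, {gene}):
            continue
        ko = apply_knockout(model, {gene})
        S, _mets, rxn_ids = build_stoichiometric_matrix(ko)
        lb = np.array([ko.reactions[r].lb for r in rxn_ids])
        ub = np.array([ko.reactions[r].ub for r in rxn_ids])
        c = np.zeros(len(rxn_ids))
        c[rxn_ids.index(ko.objective_reaction_id)] = 1.0
        status, obj, _ = _solve_lp(c, S, lb, ub)
        ko_growth = obj if status == "optimal" else 0.0
        if is_viable(ko_growth, policy):
            continue
        essential.append(gene)
        hits = []
        for ex in exchange_ids:
            j = rxn_ids.index(ex)
            old = lb[j]
            lb[j] = min(old, uptake_bound)
            status, obj, _ = _solve_lp(c, S, lb, ub)
            lb[j] = old
            growth = obj if status == "optimal" else 0.0
            if is_viable(growth, policy):
                (met_id,) = ko.reactions[ex].stoich.keys()
                hits.append((ex, model.metabolites[met_id].name or met_id, growth))
        if hits:
            rescues[gene] = hits
    return ScreenResult(rescues=rescues, essential=essential)


def substrate_usage(
    model: GEMModel,
    element: str,
    candidates: Sequence[str],
    policy: ViabilityPolicy | None = None,
    default_sources: dict[str, str] | None = None,
    uptake_bound: float = -10.0,
) -> pd.DataFrame:
    """Alternative-substrate viability table for one element (C/N/P/S).

    The element's default source exchange is closed (lb=0), each candidate
    exchange opened at *uptake_bound*, and viability recorded.  Candidates
    without an exchange are marked unresolvable.
    """
    if policy is None:
        policy = ViabilityPolicy.from_model(model)
    sources = default_sources or {
        "C": "glucose",
        "N": "ammonium",
        "P": "phosphate",
        "S": "sulfate",
    }
    if element not in sources:
        raise ValueError(f"no default source configured for element {element!r}")
    default_ex = find_exchange(model, sources[element])
    if default_ex is None:
        raise ModelError(
            f"default {element} source {sources[element]!r} has no exchange"
        )
    closed = model.copy()
    closed.reactions[default_ex].lb = 0.0
    rows = []
    for candidate in candidates:
        ex = find_exchange(closed, candidate)
        if ex is None:
            rows.append(
                {"candidate": candidate, "exchange": None, "growth": float("nan"),
                 "viable": False, "unresolvable": True}
            )
            continue
        growth = solve_fba(open_uptake(closed, ex, uptake_bound)).growth
        rows.append(
            {"candidate": candidate, "exchange": ex, "growth": growth,
             "viable": is_viable(growth, policy), "unresolvable": False}
        )
    return pd.DataFrame(rows)


def compound_categories() -> dict[str, str]:
    """Packaged compound -> category table (amino acids / vitamins /
    purine and pyrimidine bases / others)."""
    text = resources.files("auxogem").joinpath("data/compound_categories.yaml").read_text()
    return yaml.safe_load(text)


def _record_category(record: AuxotrophyRecord, table: dict[str, str]) -> str:
    first = record.rescue_spec[0][0].lower()
    return table.get(first, "others")


def compare_models(
    model_a: GEMModel,
    model_b: GEMModel,
    records: Sequence[AuxotrophyRecord],
    policy_a: ViabilityPolicy | None = None,
    policy_b: ViabilityPolicy | None = None,
    uptake_bound: float = DEFAULT_UPTAKE_BOUND,
) -> tuple[pd.DataFrame, dict]:
    """Classify every record under two models and tabulate the deltas.

    Returns a per-record frame (key, category, classification under each
    model, changed flag) and a summary with per-model counts and
    per-category correct-prediction deltas.
    """
    results_a, summary_a = run_dataset(model_a, records, policy_a, uptake_bound)
    results_b, summary_b = run_dataset(model_b, records, policy_b, uptake_bound)
    table = compound_categories()
    rows = []
    for (record, res_a), (_, res_b) in zip(results_a, results_b):
        rows.append(
            {
                "record": record.key,
                "category": _record_category(record, table),
                "class_a": res_a.classification.value,
                "class_b": res_b.classification.value,
                "changed": res_a.classification != res_b.classification,
            }
        )
    frame = pd.DataFrame(rows)
    per_category = {}
    if not frame.empty:
        for cat, sub in frame.groupby("category"):
            per_category[cat] = {
                "correct_a": int((sub["class_a"] == "CORRECT").sum()),
                "correct_b": int((sub["class_b"] == "CORRECT").sum()),
            }
    summary = {
        "model_a": {
            "correct": summary_a.correct,
            "type_i": summary_a.type_i,
            "type_ii": summary_a.type_ii,
            "unresolvable": summary_a.unresolvable,
            "essential_in_silico": summary_a.essential_in_silico,
        },
        "model_b": {
            "correct": summary_b.correct,
            "type_i": summary_b.type_i,
            "type_ii": summary_b.type_ii,
            "unresolvable": summary_b.unresolvable,
            "essential_in_silico": summary_b.essential_in_silico,
        },
        "per_category": per_category,
        "n_changed": int(frame["changed"].sum()) if not frame.empty else 0,
    }
    return frame, summary


# --------------------------------------------------------------------------
# dataset TSV
# --------------------------------------------------------------------------

_TSV_COLUMNS = [
    "knockout_genes",
    "rescue_spec",
    "medium_supplements",
    "strain_background",
    "reference",
    "unresolvable",
]


def read_dataset(path: str | Path) -> list[AuxotrophyRecord]:
    """Read the tab-separated auxotrophy dataset.

    Columns: knockout_genes (";"-separated), rescue_spec (DNF with "|"
    between conjuncts and "+" between members), medium_supplements
    (";"-separated, optional), strain_background, reference, unresolvable
    (0/1, optional).
    """
    records = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            records.append(
                AuxotrophyRecord(
                    knockout_genes=tuple(
                        g.strip() for g in row["knockout_genes"].split(";") if g.strip()
                    ),
                    rescue_spec=parse_rescue_spec(row["rescue_spec"]),
                    medium_supplements=tuple(
                        s.strip()
                        for s in (row.get("medium_supplements") or "").split(";")
                        if s.strip()
                    ),
                    strain_background=row.get("strain_background", "") or "",
                    reference=row.get("reference", "") or "",
                    unresolvable=(row.get("unresolvable") or "0").strip()
                    in ("1", "true", "True"),
                )
            )
    return records


def write_dataset(records: Sequence[AuxotrophyRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_TSV_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    ";".join(r.knockout_genes),
                    render_rescue_spec(r.rescue_spec),
                    ";".join(r.medium_supplements),
                    r.strain_background,
                    r.reference,
                    "1" if r.unresolvable else "0",
                ]
            )
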