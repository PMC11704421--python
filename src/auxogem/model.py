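"""Core genome-scale metabolic model (GEM) data structures.

A :class:`GEMModel` holds metabolites, reactions (stoichiometry, flux
bounds, GPR rule), the gene list, and the identifier of the biomass
objective reaction.  Stoichiometric coefficients are signed: negative for
consumed species, positive for produced.  Exchange reactions are boundary
reactions touching exactly one metabolite, written in the export direction
(``met =>``) so that negative flux denotes uptake from the environment.

Identifiers are matched exactly and case-sensitively; display-name lookups
(:func:`find_exchange`) are case-insensitive.  Compartments are stored as a
separate metabolite field; the bracket convention ``name[c]`` is rendered
for display only.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass, field, replace

from .gpr import EMPTY_GPR, GprEmpty, GprExpr, eval_gpr, gpr_genes, render_gpr

__all__ = [
    "ATOMIC_MASSES",
    "Metabolite",
    "Reaction",
    "GEMModel",
    "ModelError",
    "UnknownGeneError",
    "AmbiguousMatchError",
    "formula_mass",
    "disabled_reactions",
    "validate_model",
    "find_exchange",
]

# g/mmol (== g/mol / 1000? No: coefficients are mmol-scale, masses are
# conventionally tabulated in g/mol and used as g/mmol * 1e-3 consistently;
# only ratios matter here, so plain atomic weights are used).
ATOMIC_MASSES: dict[str, float] = {
    "C": 12.011,
    "H": 1.008,
    "N": 14.007,
    "O": 15.999,
    "P": 30.974,
    "S": 32.06,
    "Fe": 55.845,
    "Zn": 65.38,
    "Mg": 24.305,
    "Na": 22.990,
    "K": 39.098,
    "Ca": 40.078,
    "Cl": 35.45,
}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class ModelError(ValueError):
    """Structural problem with a model or an operation on it."""


class UnknownGeneError(ModelError):
    def __init__(self, gene: str):
        super().__init__(f"unknown gene: {gene!r}")
        self.gene = gene


class AmbiguousMatchError(ModelError):
    def __init__(self, query: str, candidates: list[str]):
        super().__init__(
            f"ambiguous exchange match for {query!r}: candidates {sorted(candidates)}"
        )
        self.candidates = list(candidates)


def formula_mass(
    formula: str, extra_masses: dict[str, float] | None = None
) -> float:
    """Molar mass of an elemental formula string such as ``C6H12O6``.

    The built-in element table covers the common biochemistry elements;
    *extra_masses* extends or overrides it for exotic element tokens.
    Raises :class:`ModelError` for unparseable text or unknown elements.
    """
    table = ATOMIC_MASSES if extra_masses is None else {**ATOMIC_MASSES, **extra_masses}
    mass = 0.0
    pos = 0
    for m in _FORMULA_TOKEN.finditer(formula):
        if m.start() != pos:
            raise ModelError(f"malformed formula {formula!r} near position {pos}")
        element, count = m.group(1), m.group(2)
        if element not in table:
            raise ModelError(f"unknown element {element!r} in formula {formula!r}")
        mass += table[element] * (int(count) if count else 1)
        pos = m.end()
    if pos != len(formula) or pos == 0:
        raise ModelError(f"malformed formula: {formula!r}")
    return mass


@dataclass
class Metabolite:
    """A chemical species in one compartment.

    ``mass_override`` supplies a molar mass (g/mmol scale) for polymeric
    pseudo-species whose formula is absent or not meaningful per unit
    coefficient.
    """

    id: str
    name: str = ""
    compartment: str = "c"
    formula: str | None = None
    mass_override: float | None = None

    @property
    def display(self) -> str:
        return f"{self.name or self.id}[{self.compartment}]"

    def molar_mass(self, extra_masses: dict[str, float] | None = None) -> float | None:
        if self.mass_override is not None:
            return self.mass_override
        if self.formula:
            return formula_mass(self.formula, extra_masses)
        return None


@dataclass
class Reaction:
    """A stoichiometric reaction with flux bounds and a GPR rule.

    Bounds are in mmol/gDW/h (1/h for the biomass pseudoreaction).
    """

    id: str
    stoich: dict[str, float]
    lb: float = -1000.0
    ub: float = 1000.0
    gpr: GprExpr = EMPTY_GPR
    is_exchange: bool = False
    notes: str = ""

    @property
    def gpr_string(self) -> str:
        return render_gpr(self.gpr)

    def copy(self) -> "Reaction":
        return replace(self, stoich=dict(self.stoich))


@dataclass
class GEMModel:
    metabolites: dict[str, Metabolite] = field(default_factory=dict)
    reactions: dict[str, Reaction] = field(default_factory=dict)
    genes: set[str] = field(default_factory=set)
    objective_reaction_id: str = ""
    id: str = "model"

    # -- construction helpers -------------------------------------------------

    def add_metabolite(self, met: Metabolite) -> None:
        if met.id in self.metabolites:
            raise ModelError(f"duplicate metabolite id: {met.id!r}")
        self.metabolites[met.id] = met

    def add_reaction(self, rxn: Reaction) -> None:
        if rxn.id in self.reactions:
            raise ModelError(f"duplicate reaction id: {rxn.id!r}")
        for met_id in rxn.stoich:
            if met_id not in self.metabolites:
                raise ModelError(
                    f"reaction {rxn.id!r} references unknown metabolite {met_id!r}"
                )
        self.reactions[rxn.id] = rxn
        self.genes.update(gpr_genes(rxn.gpr))

    def copy(self) -> "GEMModel":
        return GEMModel(
            metabolites={k: replace(v) for k, v in self.metabolites.items()},
            reactions={k: r.copy() for k, r in self.reactions.items()},
            genes=set(self.genes),
            objective_reaction_id=self.objective_reaction_id,
            id=self.id,
        )

    # -- canonical form & fingerprint -----------------------------------------

    def to_dict(self) -> dict:
        return {
            "id": self.id,
            "objective": self.objective_reaction_id,
            "genes": sorted(self.genes),
            "metabolites": [
                {
                    "id": m.id,
                    "name": m.name,
                    "compartment": m.compartment,
                    "formula": m.formula,
                    "mass_override": m.mass_override,
                }
                for m in self.metabolites.values()
            ],
            "reactions": [
                {
                    "id": r.id,
                    "stoich": {k: r.stoich[k] for k in sorted(r.stoich)},
                    "lb": r.lb,
                    "ub": r.ub,
                    "gpr": r.gpr_string,
                    "is_exchange": r.is_exchange,
                    "notes": r.notes,
                }
                for r in self.reactions.values()
            ],
        }

    def fingerprint(self) -> str:
        """Content hash of the canonical serialization (used for caching)."""
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()


def disabled_reactions(model: GEMModel, deleted: set[str]) -> set[str]:
    """Reaction ids whose non-empty GPR evaluates false under the deletion.

    A deleted gene with no associated reactions is valid and simply
    disables nothing; a gene absent from the model raises
    :class:`UnknownGeneError`.
    """
    for g in deleted:
        if g not in model.genes:
            raise UnknownGeneError(g)
    deleted = frozenset(deleted)
    out = set()
    for rxn in model.reactions.values():
        if not isinstance(rxn.gpr, GprEmpty) and not eval_gpr(rxn.gpr, deleted):
            out.add(rxn.id)
    return out


def validate_model(model: GEMModel) -> list[str]:
    """Check structural invariants; returns human-readable violations.

    Violations are data, not exceptions: an empty list means the model is
    well-formed.
    """
    violations: list[str] = []
    if not model.objective_reaction_id:
        violations.append("model: no objective reaction set")
    elif model.objective_reaction_id not in model.reactions:
        violations.append(
            f"model: objective reaction {model.objective_reaction_id!r} not present"
        )
    for met in model.metabolites.values():
        if met.mass_override is not None and met.mass_override <= 0:
            violations.append(f"metabolite {met.id}: non-positive mass override")
        if met.formula and met.mass_override is None:
            try:
                formula_mass(met.formula)
            except ModelError as exc:
                violations.append(f"metabolite {met.id}: {exc}")
    for rxn in model.reactions.values():
        if rxn.lb > rxn.ub:
            violations.append(f"reaction {rxn.id}: lb {rxn.lb} > ub {rxn.ub}")
        if not rxn.stoich:
            violations.append(f"reaction {rxn.id}: empty stoichiometry")
        if rxn.is_exchange and len(rxn.stoich) != 1:
            violations.append(
                f"reaction {rxn.id}: exchange must touch exactly one metabolite"
            )
        for met_id, coeff in rxn.stoich.items():
            if met_id not in model.metabolites:
                violations.append(
                    f"reaction {rxn.id}: unknown metabolite {met_id!r}"
                )
            if not (coeff == coeff and abs(coeff) != float("inf")):
                violations.append(
                    f"reaction {rxn.id}: non-finite coefficient for {met_id!r}"
                )
        for gene in gpr_genes(rxn.gpr):
            if gene not in model.genes:
                violations.append(f"reaction {rxn.id}: GPR cites unknown gene {gene!r}")
    return violations


def find_exchange(model: GEMModel, query: str) -> str | None:
    """Locate the exchange reaction for a compound.

    *query* may be a metabolite id (exact) or a display name
    (case-insensitive; extracellular compartments preferred, matching the
    convention that exchanged species live outside the cell).  Returns the
    exchange reaction id, or ``None`` when the compound has no exchange —
    the caller decides how an absent exchange is treated.

    Raises :class:`AmbiguousMatchError` when several exchanges match.
    """
    exchanges = [r for r in model.reactions.values() if r.is_exchange]
    # pass 1: exchange reaction id itself
    if query in model.reactions and model.reactions[query].is_exchange:
        return query
    # pass 2: exact metabolite id
    hits = [r.id for r in exchanges if query in r.stoich]
    if not hits:
        # pass 3: case-insensitive display name
        q = query.lower()
        name_hits = []
        for r in exchanges:
            (met_id,) = r.stoich.keys()
            met = model.metabolites[met_id]
            if q in (met.name.lower(), met.id.lower()):
                name_hits.append((r.id, met.compartment))
        extra = [h for h, comp in name_hits if comp in ("e", "extracellular")]
        hits = extra or [h for h, _ in name_hits]
    if not hits:
        return None
    if len(hits) > 1:
        raise AmbiguousMatchError(query, hits)
    return hits[0]
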