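"""Curation edits for genome-scale metabolic models.

The edit vocabulary covers the operations used in auxotrophy-based model
refinement:

* ``block_reaction`` / ``block_reverse`` — silence a compensatory bypass
  (fully, or only its reverse direction);
* ``set_gpr`` — rewrite a gene-reaction association;
* ``add_reaction`` / ``add_exchange`` — introduce a missing synthesis
  reaction or a boundary exchange for a compound the cell demonstrably
  secretes or takes up;
* ``pseudo_add_rescale`` — add a species to a biomass-style pseudoreaction
  while conserving total reactant mass (all coefficients rescaled);
* ``pseudo_append`` — append a trace cofactor-style species at a stated
  tiny coefficient without rescaling.

Every edit is a serializable, replayable record carrying provenance
(the gene–compound pair(s) that motivated it, the error type, and a
citation string), so a curation set can be audited row by row.

:func:`yeast9_curation_set` returns the full curation set for the yeast
consensus model Yeast9 derived from auxotrophy experiments: 12 GPR
rewrites, 8 reaction blocks, two synthesis reactions, one exchange, and
two pseudoreaction adjustments (chitin into carbohydrate at a final
coefficient of -0.02361; glutathione into cofactor at -1e-06).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable

import yaml

from .gpr import gpr_genes, parse_gpr
from .model import GEMModel, Metabolite, ModelError, Reaction

__all__ = [
    "CurationEdit",
    "MassRescaleSpec",
    "EditApplicationError",
    "EDIT_KINDS",
    "block_reaction",
    "set_gpr",
    "add_reaction",
    "add_exchange",
    "rescale_pseudoreaction",
    "pseudo_append",
    "apply_edits",
    "yeast9_curation_set",
    "parse_reaction_equation",
    "edits_to_yaml",
    "edits_from_yaml",
]

EDIT_KINDS = (
    "block_reaction",
    "block_reverse",
    "set_gpr",
    "add_reaction",
    "add_exchange",
    "pseudo_add_rescale",
    "pseudo_append",
)


@dataclass
class CurationEdit:
    """One replayable model edit with provenance.

    ``payload`` is kind-specific (a GPR string, a reaction equation with
    bounds, a species + coefficient, ...); ``provenance`` records the
    gene–compound pair(s), the misprediction type that motivated the edit,
    and a citation.
    """

    kind: str
    target: str
    payload: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in EDIT_KINDS:
            raise ValueError(f"unknown curation edit kind: {self.kind!r}")

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "target": self.target,
            "payload": self.payload,
            "provenance": self.provenance,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "CurationEdit":
        return cls(
            kind=data["kind"],
            target=data["target"],
            payload=data.get("payload", {}),
            provenance=data.get("provenance", {}),
        )


@dataclass
class MassRescaleSpec:
    """Mass-balanced insertion of a species into a pseudoreaction.

    Exactly one of ``new_coefficient_raw`` / ``new_coefficient_final`` is
    given (negative: the species joins the reactant side).  With a raw
    coefficient, the scale factor is f = M0/(M0 + m_new), applied to every
    reactant including the new one, so total reactant mass is conserved at
    M0.  A final coefficient is first inverted to its raw value via
    |raw| = |final| * M0 / (M0 - |final| * mass_new).

    ``species_masses`` overrides per-unit molar masses (required for
    polymeric pseudo-species with no meaningful elemental formula).
    """

    reaction_id: str
    new_species: str
    new_coefficient_raw: float | None = None
    new_coefficient_final: float | None = None
    species_masses: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.new_coefficient_raw is None) == (self.new_coefficient_final is None):
            raise ValueError(
                "exactly one of new_coefficient_raw / new_coefficient_final required"
            )
        for met, mass in self.species_masses.items():
            if mass <= 0:
                raise ValueError(f"non-positive mass for {met!r}")


class EditApplicationError(ModelError):
    """An edit in a set failed; nothing was applied (the input model is
    untouched)."""

    def __init__(self, index: int, edit: CurationEdit, cause: Exception):
        super().__init__(
            f"edit #{index} ({edit.kind} -> {edit.target}) failed: {cause}"
        )
        self.index = index
        self.edit = edit
        self.cause = cause


# --------------------------------------------------------------------------
# reaction-equation mini-grammar ("a[c] + 2 b[c] => c[c]")
# --------------------------------------------------------------------------

_ARROWS = ("<=>", "=>", "->")
_COEFF_RE = re.compile(r"^(\d+(?:\.\d+)?(?:[eE][+-]?\d+)?)\s+(.+)$")
_TERM_RE = re.compile(r"^(.*)\[([^\[\]]+)\]$")


def _slug(name: str, compartment: str) -> str:
    base = re.sub(r"[^A-Za-z0-9]+", "_", name).strip("_").lower()
    return f"{base}_{compartment}"


def parse_reaction_equation(equation: str) -> tuple[dict, tuple[float, float]]:
    """Parse ``substrates => products`` into term list + default bounds.

    Terms are ``coefficient name[compartment]`` joined by `` + ``; the
    arrow ``<=>`` marks a reversible reaction (bounds (-1000, 1000)),
    ``=>``/``->`` an irreversible one (bounds (0, 1000)).  Returns
    ``({(name, compartment): signed coefficient}, (lb, ub))``.
    """
    # arrows must be whitespace-delimited so names like "(1->3)-beta-D-glucan"
    # are never mistaken for one
    equation = equation.strip()
    for arrow in _ARROWS:
        sep = f" {arrow} "
        if sep in equation:
            lhs, rhs = equation.split(sep, 1)
            reversible = arrow == "<=>"
            break
        if equation.endswith(f" {arrow}"):
            lhs, rhs = equation[: -len(arrow) - 1], ""
            reversible = arrow == "<=>"
            break
    else:
        raise ValueError(f"no reaction arrow in equation: {equation!r}")
    terms: dict[tuple[str, str], float] = {}
    for side, sign in ((lhs, -1.0), (rhs, 1.0)):
        side = side.strip()
        if not side:
            continue
        for raw in side.split(" + "):
            raw = raw.strip()
            coeff = 1.0
            m = _COEFF_RE.match(raw)
            if m:
                coeff, raw = float(m.group(1)), m.group(2).strip()
            tm = _TERM_RE.match(raw)
            if not tm:
                raise ValueError(f"cannot parse term {raw!r} in {equation!r}")
            key = (tm.group(1).strip(), tm.group(2).strip())
            terms[key] = terms.get(key, 0.0) + sign * coeff
    bounds = (-1000.0, 1000.0) if reversible else (0.0, 1000.0)
    return terms, bounds


def _resolve_metabolite(
    model: GEMModel, name: str, compartment: str
) -> str | None:
    """Find a metabolite by display name (case-insensitive) + compartment."""
    lname = name.lower()
    for met in model.metabolites.values():
        if met.compartment == compartment and lname in (
            met.name.lower(),
            met.id.lower(),
        ):
            return met.id
    return None


# --------------------------------------------------------------------------
# operators (pure: each returns a new model)
# --------------------------------------------------------------------------

def block_reaction(model: GEMModel, rxn_id: str, direction: str = "both") -> GEMModel:
    """Silence a reaction: ``both`` forces lb=ub=0; ``reverse`` clamps
    lb to >= 0, preserving forward flux (a no-op on irreversible
    reactions)."""
    if rxn_id not in model.reactions:
        raise ModelError(f"unknown reaction: {rxn_id!r}")
    if direction not in ("both", "reverse"):
        raise ValueError(f"direction must be 'both' or 'reverse', got {direction!r}")
    out = model.copy()
    rxn = out.reactions[rxn_id]
    if direction == "both":
        rxn.lb = 0.0
        rxn.ub = 0.0
    else:
        rxn.lb = max(rxn.lb, 0.0)
    return out


def set_gpr(
    model: GEMModel,
    rxn_id: str,
    gpr_text: str,
    new_genes: Iterable[str] = (),
) -> GEMModel:
    """Replace a reaction's gene association.

    Genes not yet in the model must be registered via *new_genes*; an
    unregistered unknown gene is an error (it usually means a typo).
    """
    if rxn_id not in model.reactions:
        raise ModelError(f"unknown reaction: {rxn_id!r}")
    expr = parse_gpr(gpr_text)
    out = model.copy()
    out.genes.update(new_genes)
    unknown = gpr_genes(expr) - out.genes
    if unknown:
        raise ModelError(
            f"GPR for {rxn_id!r} cites unregistered gene(s): {sorted(unknown)}"
        )
    out.reactions[rxn_id].gpr = expr
    return out


def _add_payload_metabolites(model: GEMModel, payload: dict) -> None:
    for m in payload.get("metabolites", []):
        met = Metabolite(
            id=m.get("id") or _slug(m["name"], m.get("compartment", "c")),
            name=m.get("name", ""),
            compartment=m.get("compartment", "c"),
            formula=m.get("formula"),
            mass_override=m.get("mass_override"),
        )
        if met.id not in model.metabolites:
            model.add_metabolite(met)


def add_reaction(model: GEMModel, rxn_id: str, payload: dict) -> GEMModel:
    """Append a new reaction from an equation string or explicit stoich.

    payload keys: ``equation`` (or ``stoich`` of met-id -> coefficient),
    optional ``lb``/``ub``, ``gpr``, ``new_genes`` and ``metabolites`` (a
    list of metabolite definitions to add atomically).  A term that names
    a metabolite absent from both the model and the payload is an error.
    """
    if rxn_id in model.reactions:
        raise ModelError(f"duplicate reaction id: {rxn_id!r}")
    out = model.copy()
    _add_payload_metabolites(out, payload)
    if "equation" in payload:
        terms, default_bounds = parse_reaction_equation(payload["equation"])
        stoich = {}
        for (name, comp), coeff in terms.items():
            met_id = _resolve_metabolite(out, name, comp)
            if met_id is None:
                raise ModelError(
                    f"reaction {rxn_id!r}: unknown metabolite {name!r}[{comp}] "
                    "and no atomic metabolite payload"
                )
            stoich[met_id] = stoich.get(met_id, 0.0) + coeff
    else:
        stoich = dict(payload["stoich"])
        default_bounds = (0.0, 1000.0)
    out.genes.update(payload.get("new_genes", ()))
    gpr = parse_gpr(payload.get("gpr", ""))
    unknown = gpr_genes(gpr) - out.genes
    if unknown:
        raise ModelError(f"reaction {rxn_id!r}: unknown gene(s) {sorted(unknown)}")
    out.add_reaction(
        Reaction(
            id=rxn_id,
            stoich=stoich,
            lb=payload.get("lb", default_bounds[0]),
            ub=payload.get("ub", default_bounds[1]),
            gpr=gpr,
            is_exchange=len(stoich) == 1,
            notes=payload.get("notes", ""),
        )
    )
    return out


def add_exchange(model: GEMModel, rxn_id: str, payload: dict) -> GEMModel:
    """Create a boundary exchange ``met =>`` for a compound.

    The exchange is created closed for uptake (lb=0) unless the payload
    states otherwise; opening it is a simulation-time decision, not a
    curation decision.  payload: ``metabolite`` (id, or a definition dict
    added atomically), optional ``lb``/``ub``.
    """
    if rxn_id in model.reactions:
        raise ModelError(f"duplicate reaction id: {rxn_id!r}")
    out = model.copy()
    met_spec = payload["metabolite"]
    if isinstance(met_spec, dict):
        _add_payload_metabolites(out, {"metabolites": [met_spec]})
        met_id = met_spec.get("id") or _slug(
            met_spec["name"], met_spec.get("compartment", "c")
        )
    else:
        met_id = met_spec
        if met_id not in out.metabolites:
            resolved = _resolve_metabolite(out, met_id, "e")
            if resolved is None:
                raise ModelError(f"exchange {rxn_id!r}: unknown metabolite {met_id!r}")
            met_id = resolved
    out.add_reaction(
        Reaction(
            id=rxn_id,
            stoich={met_id: -1.0},
            lb=payload.get("lb", 0.0),
            ub=payload.get("ub", 1000.0),
            is_exchange=True,
            notes=payload.get("notes", ""),
        )
    )
    return out


def _species_mass(model: GEMModel, met_id: str, spec: MassRescaleSpec) -> float:
    if met_id in spec.species_masses:
        return spec.species_masses[met_id]
    met = model.metabolites.get(met_id)
    mass = met.molar_mass() if met is not None else None
    if mass is None:
        raise ModelError(
            f"no molar mass for metabolite {met_id!r}: supply a formula or a "
            "species_masses override"
        )
    return mass


def rescale_pseudoreaction(model: GEMModel, spec: MassRescaleSpec) -> GEMModel:
    """Insert a species into a pseudoreaction, conserving reactant mass.

    Reactant masses m_i = |coeff_i| * mass_i give the original total M0.
    With the new species contributing m_new, every reactant coefficient —
    the new species included — is scaled by f = M0 / (M0 + m_new), so the
    total reactant mass after the edit equals M0 and all pre-existing
    coefficient ratios are preserved.  Products (the pooled pseudo-species
    itself) are untouched.
    """
    if spec.reaction_id not in model.reactions:
        raise ModelError(f"unknown reaction: {spec.reaction_id!r}")
    if spec.new_species not in model.metabolites:
        raise ModelError(f"unknown metabolite: {spec.new_species!r}")
    rxn = model.reactions[spec.reaction_id]
    if spec.new_species in rxn.stoich:
        raise ModelError(
            f"species {spec.new_species!r} already in {spec.reaction_id!r}"
        )
    reactants = {m: c for m, c in rxn.stoich.items() if c < 0}
    masses = {m: _species_mass(model, m, spec) for m in reactants}
    mass_new = _species_mass(model, spec.new_species, spec)
    m0 = sum(abs(c) * masses[m] for m, c in reactants.items())
    if m0 <= 0:
        raise ModelError(f"pseudoreaction {spec.reaction_id!r} has no reactant mass")

    if spec.new_coefficient_raw is not None:
        raw = spec.new_coefficient_raw
    else:
        final = spec.new_coefficient_final
        denom = m0 - abs(final) * mass_new
        if denom <= 0:
            raise ModelError("final coefficient implies more than the total mass")
        raw = -abs(final) * m0 / denom
    if raw == 0:
        return model.copy()
    if raw > 0:
        raise ModelError("new species must join the reactant side (coefficient < 0)")

    m_new = abs(raw) * mass_new
    f = m0 / (m0 + m_new)
    out = model.copy()
    new_stoich = out.reactions[spec.reaction_id].stoich
    for m in reactants:
        new_stoich[m] = reactants[m] * f
    new_stoich[spec.new_species] = raw * f
    return out


def pseudo_append(
    model: GEMModel, rxn_id: str, species: str, coefficient: float
) -> GEMModel:
    """Append a species to a pseudoreaction at a stated coefficient,
    with no rescaling (trace cofactor-style terms)."""
    if rxn_id not in model.reactions:
        raise ModelError(f"unknown reaction: {rxn_id!r}")
    if species not in model.metabolites:
        raise ModelError(f"unknown metabolite: {species!r}")
    if coefficient == 0:
        raise ModelError("coefficient must be nonzero")
    if species in model.reactions[rxn_id].stoich:
        raise ModelError(f"species {species!r} already present in {rxn_id!r}")
    out = model.copy()
    out.reactions[rxn_id].stoich[species] = coefficient
    return out


# --------------------------------------------------------------------------
# edit application
# --------------------------------------------------------------------------

def _apply_one(model: GEMModel, edit: CurationEdit) -> GEMModel:
    if edit.kind == "block_reaction":
        return block_reaction(model, edit.target, "both")
    if edit.kind == "block_reverse":
        return block_reaction(model, edit.target, "reverse")
    if edit.kind == "set_gpr":
        return set_gpr(
            model, edit.target, edit.payload["gpr"], edit.payload.get("new_genes", ())
        )
    if edit.kind == "add_reaction":
        return add_reaction(model, edit.target, edit.payload)
    if edit.kind == "add_exchange":
        return add_exchange(model, edit.target, edit.payload)
    if edit.kind == "pseudo_add_rescale":
        spec = MassRescaleSpec(
            reaction_id=edit.target,
            new_species=edit.payload["species"],
            new_coefficient_raw=edit.payload.get("coefficient_raw"),
            new_coefficient_final=edit.payload.get("coefficient_final"),
            species_masses=edit.payload.get("species_masses", {}),
        )
        return rescale_pseudoreaction(model, spec)
    if edit.kind == "pseudo_append":
        return pseudo_append(
            model, edit.target, edit.payload["species"], edit.payload["coefficient"]
        )
    raise ValueError(f"unknown edit kind: {edit.kind!r}")  # pragma: no cover


def _snapshot(model: GEMModel, rxn_id: str) -> dict | None:
    rxn = model.reactions.get(rxn_id)
    if rxn is None:
        return None
    return {
        "stoich": dict(rxn.stoich),
        "lb": rxn.lb,
        "ub": rxn.ub,
        "gpr": rxn.gpr_string,
    }


def apply_edits(
    model: GEMModel, edits: Iterable[CurationEdit]
) -> tuple[GEMModel, list[dict]]:
    """Apply edits in order; returns the curated model and a replay log.

    Deterministic; any failing edit raises :class:`EditApplicationError`
    and leaves the input model untouched (operators are pure, so partial
    application never leaks).  Applying a set twice fails on the first
    duplicate added reaction — curation sets are not idempotent by design.
    """
    log: list[dict] = []
    current = model
    for i, edit in enumerate(edits):
        before = _snapshot(current, edit.target)
        try:
            current = _apply_one(current, edit)
        except (ModelError, ValueError, KeyError) as exc:
            raise EditApplicationError(i, edit, exc) from exc
        log.append(
            {
                "index": i,
                "kind": edit.kind,
                "target": edit.target,
                "before": before,
                "after": _snapshot(current, edit.target),
                "provenance": edit.provenance,
            }
        )
    return current, log


def edits_to_yaml(edits: Iterable[CurationEdit], path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump([e.to_dict() for e in edits], fh, sort_keys=False)


def edits_from_yaml(path) -> list[CurationEdit]:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return [CurationEdit.from_dict(d) for d in data]


# --------------------------------------------------------------------------
# the Yeast9 auxotrophy curation set
# --------------------------------------------------------------------------

# Anhydro-monomer masses (g/mmol scale) for the polymeric carbohydrate
# pseudo-species, used to convert pseudoreaction coefficients to mass
# units; trehalose is a true molecule (C12H22O11).
CARBOHYDRATE_SPECIES_MASSES = {
    "1_3_beta_d_glucan_ce": 162.14,
    "1_6_beta_d_glucan_ce": 162.14,
    "glycogen_c": 162.14,
    "mannan_c": 162.14,
    "trehalose_c": 342.30,
    "chitin_c": 203.19,
}


def _prov(pairs, error_type, citation="") -> dict:
    return {
        "gene_compound_pairs": [
            {"gene": g, "compound": c} for g, c in pairs
        ],
        "error_type": error_type,
        "citation": citation,
    }


def yeast9_curation_set() -> list[CurationEdit]:
    """The auxotrophy-derived curation set for the Yeast9 consensus model.

    12 gene-association rewrites, 8 reaction blocks (one reverse-only),
    two synthesis reactions, one exchange, and two pseudoreaction
    adjustments.  Edits carry the motivating gene–compound pair(s) and
    misprediction type as provenance so reports can group them.
    """
    edits: list[CurationEdit] = []

    # ---- reaction blocks (compensatory bypasses) --------------------------
    edits.append(
        CurationEdit(
            "block_reaction",
            "r_0217",
            provenance=_prov([("AAT2", "aspartate")], "type I",
                             "mitochondrial Aat1p backup; cytosolic AAT2 dominant"),
        )
    )
    edits.append(
        CurationEdit(
            "block_reaction",
            "r_0312",
            provenance=_prov([("CYS3", "cysteine")], "type I"),
        )
    )
    edits.append(
        CurationEdit(
            "block_reaction",
            "r_4703",
            provenance=_prov([("CYS4", "cysteine")], "type I"),
        )
    )
    edits.append(
        CurationEdit(
            "block_reaction",
            "r_0559",
            provenance=_prov([("ERG10", "ergosterol")], "type I"),
        )
    )
    edits.append(
        CurationEdit(
            "block_reaction",
            "r_1026",
            provenance=_prov([("MET3", "methionine")], "type I"),
        )
    )
    thi4_pairs = [
        ("THI4", "thiamine"),
        ("HOM2", "methionine and threonine"),
        ("HOM3", "methionine and threonine"),
        ("HOM6", "methionine and threonine"),
        ("MET2", "methionine"),
    ]
    edits.append(
        CurationEdit(
            "block_reaction",
            "r_2070",
            provenance=_prov(thi4_pairs, "type I/II",
                             "unsupported thiazole route consuming O-acetyl-l-homoserine"),
        )
    )
    edits.append(
        CurationEdit(
            "block_reaction",
            "r_2071",
            provenance=_prov(thi4_pairs, "type I/II",
                             "unsupported thiazole route consuming O-acetyl-l-homoserine"),
        )
    )
    edits.append(
        CurationEdit(
            "block_reverse",
            "r_0815",
            provenance=_prov([("MET17", "methionine")], "type I"),
        )
    )

    # ---- gene-association rewrites ---------------------------------------
    edits.append(
        CurationEdit(
            "set_gpr",
            "r_0172",
            payload={"gpr": "YMR169C or YMR170C"},
            provenance=_prov(
                [("ALD2 and ALD3", "pantothenic acid")],
                "type II",
                'from "YMR110C or YMR169C or YMR170C"',
            ),
        )
    )
    for rid in [f"r_{n}" for n in range(2488, 2496)]:
        edits.append(
            CurationEdit(
                "set_gpr",
                rid,
                payload={"gpr": "YGR157W"},
                provenance=_prov(
                    [("CHO2", "choline")], "type I", 'from "YGR157W or YJR073C"'
                ),
            )
        )
    edits.append(
        CurationEdit(
            "set_gpr",
            "r_0477",
            payload={"gpr": "YKL104C"},
            provenance=_prov(
                [("GFA1", "d-Glucosamine")], "type I", 'from "YMR084W or YKL104C"'
            ),
        )
    )
    edits.append(
        CurationEdit(
            "set_gpr",
            "r_0080",
            payload={"gpr": "(YGL125W and YPL023C) or YGL125W"},
            provenance=_prov(
                [("MET13", "methionine")], "type II", 'from "YGL125W and YPL023C"'
            ),
        )
    )
    edits.append(
        CurationEdit(
            "set_gpr",
            "r_0250",
            payload={"gpr": "YJL130C or (YJR109C and YOR303W)"},
            provenance=_prov(
                [("URA2", "uracil")],
                "type II",
                'from "YJL130C and YJR109C and YOR303W"',
            ),
        )
    )

    # ---- additions --------------------------------------------------------
    heme_pairs = [
        ("ERG13", "ergosterol"),
        ("ERG20", "ergosterol"),
        ("HEM1", "heme"),
        ("HEM12", "heme"),
        ("HEM2", "heme"),
        ("HEM3", "heme"),
        ("HEM4", "heme"),
    ]
    edits.append(
        CurationEdit(
            "add_exchange",
            "r_temp1",
            payload={
                "metabolite": {"name": "heme a", "compartment": "e"},
                "notes": "heme a[e] =>",
            },
            provenance=_prov(heme_pairs, "type II", "add heme a exchange reaction"),
        )
    )
    edits.append(
        CurationEdit(
            "add_reaction",
            "r_temp2",
            payload={
                "equation": (
                    "ADP-5-ethyl-4-methylthiazole-2-carboxylate[c] + H2O[c] -> "
                    "AMP[c] + 4-methyl-5-(2-phosphonooxyethyl)thiazole[c] + "
                    "carbon dioxide[c] + H+[c]"
                ),
                "metabolites": [
                    {"name": "ADP-5-ethyl-4-methylthiazole-2-carboxylate",
                     "compartment": "c"},
                    {"name": "AMP", "compartment": "c"},
                ],
                "notes": "HET-P synthase (thiazole synthase)",
            },
            provenance=_prov([("THI4", "thiamine")], "type II",
                             "HET-P synthase (thiazole synthase)"),
        )
    )
    edits.append(
        CurationEdit(
            "add_reaction",
            "r_temp3",
            payload={
                "equation": (
                    "l-glycine[c] + NAD[c] + hydrogen sulfide[c] -> "
                    "nicotinamide[c] + ADP-5-ethyl-4-methylthiazole-2-carboxylate[c] "
                    "+ 3 H2O[c] + H+[c]"
                ),
                "metabolites": [
                    {"name": "ADP-5-ethyl-4-methylthiazole-2-carboxylate",
                     "compartment": "c"},
                    {"name": "nicotinamide", "compartment": "c"},
                ],
                "gpr": "YGR144W",
                "new_genes": ["YGR144W"],
                "notes": "adenylated thiazole synthase (THI4)",
            },
            provenance=_prov([("THI4", "thiamine")], "type II",
                             "adenylated thiazole synthase"),
        )
    )

    # ---- pseudoreaction adjustments ---------------------------------------
    edits.append(
        CurationEdit(
            "pseudo_add_rescale",
            "r_4048",
            payload={
                "species": "chitin_c",
                "coefficient_final": -0.02361,
                "species_masses": dict(CARBOHYDRATE_SPECIES_MASSES),
            },
            provenance=_prov(
                [("GFA1", "d-Glucosamine")],
                "type I",
                "add chitin to the carbohydrate pseudoreaction; other reactant "
                "coefficients adjusted proportionally",
            ),
        )
    )
    edits.append(
        CurationEdit(
            "pseudo_append",
            "r_4598",
            payload={"species": "glutathione_c", "coefficient": -1e-06},
            provenance=_prov(
                [("GSH1", "glutathione")],
                "type I",
                "add glutathione to the cofactor pseudoreaction at -1e-06",
            ),
        )
    )
    return edits
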