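"""Model I/O: a native JSON dialect and SBML Level 3 + fbc.

The JSON dialect is the canonical fixture format: it round-trips ids,
stoichiometry, bounds and GPR strings bit-equivalently.  SBML documents
use the fbc package for flux bounds (parameter references), gene-product
associations and the active objective; reading an SBML file without fbc
flux bounds is an error ("no flux bounds") rather than a silent default.

Reactions touching exactly one species are flagged as exchanges on load.
"""

from __future__ import annotations

import json
from pathlib import Path

import libsbml

from .gpr import (
    EMPTY_GPR,
    GprAnd,
    GprExpr,
    GprGene,
    GprOr,
    parse_gpr,
    render_gpr,
)
from .model import GEMModel, Metabolite, ModelError, Reaction, validate_model

__all__ = ["load_model", "save_model", "model_from_dict"]


class ModelReadError(ModelError):
    """A file failed structural validation on load; carries all violations."""

    def __init__(self, violations: list[str]):
        super().__init__("; ".join(violations))
        self.violations = violations


# --------------------------------------------------------------------------
# native JSON dialect
# --------------------------------------------------------------------------

def model_from_dict(data: dict) -> GEMModel:
    model = GEMModel(id=data.get("id", "model"))
    for m in data["metabolites"]:
        model.add_metabolite(
            Metabolite(
                id=m["id"],
                name=m.get("name", ""),
                compartment=m.get("compartment", "c"),
                formula=m.get("formula"),
                mass_override=m.get("mass_override"),
            )
        )
    for r in data["reactions"]:
        model.add_reaction(
            Reaction(
                id=r["id"],
                stoich={k: float(v) for k, v in r["stoich"].items()},
                lb=float(r["lb"]),
                ub=float(r["ub"]),
                gpr=parse_gpr(r.get("gpr", "")),
                is_exchange=bool(r.get("is_exchange", len(r["stoich"]) == 1)),
                notes=r.get("notes", ""),
            )
        )
    model.genes.update(data.get("genes", []))
    model.objective_reaction_id = data.get("objective", "")
    violations = validate_model(model)
    if violations:
        raise ModelReadError(violations)
    return model


def _load_json(path: Path) -> GEMModel:
    with open(path) as fh:
        return model_from_dict(json.load(fh))


def _save_json(model: GEMModel, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(model.to_dict(), fh, indent=1, sort_keys=True)
        fh.write("\n")


# --------------------------------------------------------------------------
# SBML Level 3 + fbc
# --------------------------------------------------------------------------

def _sbml_safe(sid: str) -> str:
    """SBML SIds allow [A-Za-z_][A-Za-z0-9_]*; escape everything else."""
    out = []
    for ch in sid:
        if ch.isalnum() or ch == "_":
            out.append(ch)
        else:
            out.append(f"__{ord(ch)}__")
    sid = "".join(out)
    if sid and not (sid[0].isalpha() or sid[0] == "_"):
        sid = "x_" + sid
    return sid


def _sbml_unsafe(sid: str) -> str:
    import re

    if sid.startswith("x_"):
        sid = sid[2:]
    return re.sub(r"__(\d+)__", lambda m: chr(int(m.group(1))), sid)


def _assoc_to_expr(assoc, gene_names: dict[str, str]) -> GprExpr:
    if assoc is None:
        return EMPTY_GPR
    if assoc.isGeneProductRef():
        gp_id = assoc.getGeneProduct()
        return GprGene(gene_names.get(gp_id, _sbml_unsafe(gp_id).removeprefix("G_")))
    node = GprAnd if assoc.isFbcAnd() else GprOr
    children = tuple(
        _assoc_to_expr(assoc.getAssociation(i), gene_names)
        for i in range(assoc.getNumAssociations())
    )
    return node(children)


def _load_sbml(path: Path) -> GEMModel:
    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        errs = [
            doc.getError(i).getMessage()
            for i in range(doc.getNumErrors())
            if doc.getError(i).getSeverity() >= libsbml.LIBSBML_SEV_ERROR
        ]
        raise ModelReadError([f"malformed SBML: {e.strip()}" for e in errs])
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise ModelReadError(["malformed SBML: no model element"])
    fbc = sbml_model.getPlugin("fbc")

    model = GEMModel(id=sbml_model.getId() or "model")
    for i in range(sbml_model.getNumSpecies()):
        sp = sbml_model.getSpecies(i)
        sp_fbc = sp.getPlugin("fbc")
        formula = None
        if sp_fbc is not None and sp_fbc.isSetChemicalFormula():
            formula = sp_fbc.getChemicalFormula() or None
        mass_override = None
        notes = sp.getNotesString() if sp.isSetNotes() else ""
        if "mass_override:" in notes:
            mass_override = float(notes.split("mass_override:")[1].split("<")[0])
        model.add_metabolite(
            Metabolite(
                id=_sbml_unsafe(sp.getId()).removeprefix("M_"),
                name=sp.getName(),
                compartment=sp.getCompartment(),
                formula=formula,
                mass_override=mass_override,
            )
        )

    params = {
        sbml_model.getParameter(i).getId(): sbml_model.getParameter(i).getValue()
        for i in range(sbml_model.getNumParameters())
    }
    gene_names: dict[str, str] = {}
    if fbc is not None:
        for i in range(fbc.getNumGeneProducts()):
            gp = fbc.getGeneProduct(i)
            gene_names[gp.getId()] = (
                gp.getLabel() or _sbml_unsafe(gp.getId()).removeprefix("G_")
            )
    for i in range(sbml_model.getNumReactions()):
        rx = sbml_model.getReaction(i)
        rx_fbc = rx.getPlugin("fbc")
        if (
            rx_fbc is None
            or not rx_fbc.isSetLowerFluxBound()
            or not rx_fbc.isSetUpperFluxBound()
        ):
            raise ModelReadError(
                [f"reaction {rx.getId()}: no flux bounds (fbc bounds required)"]
            )
        stoich: dict[str, float] = {}
        for j in range(rx.getNumReactants()):
            ref = rx.getReactant(j)
            met = _sbml_unsafe(ref.getSpecies()).removeprefix("M_")
            stoich[met] = stoich.get(met, 0.0) - ref.getStoichiometry()
        for j in range(rx.getNumProducts()):
            ref = rx.getProduct(j)
            met = _sbml_unsafe(ref.getSpecies()).removeprefix("M_")
            stoich[met] = stoich.get(met, 0.0) + ref.getStoichiometry()
        gpr = _assoc_to_expr(
            rx_fbc.getGeneProductAssociation().getAssociation()
            if rx_fbc.isSetGeneProductAssociation()
            else None,
            gene_names,
        )
        model.add_reaction(
            Reaction(
                id=_sbml_unsafe(rx.getId()).removeprefix("R_"),
                stoich=stoich,
                lb=params[rx_fbc.getLowerFluxBound()],
                ub=params[rx_fbc.getUpperFluxBound()],
                gpr=gpr,
                is_exchange=len(stoich) == 1,
            )
        )

    model.genes.update(gene_names.values())
    if fbc is not None:
        obj = fbc.getActiveObjective()
        if obj is not None and obj.getNumFluxObjectives() > 0:
            model.objective_reaction_id = _sbml_unsafe(
                obj.getFluxObjective(0).getReaction()
            ).removeprefix("R_")
    violations = validate_model(model)
    if violations:
        raise ModelReadError(violations)
    return model


def _expr_to_assoc(expr: GprExpr, parent, fbc_ns) -> None:
    if isinstance(expr, GprGene):
        ref = parent.createGeneProductRef()
        ref.setGeneProduct("G_" + _sbml_safe(expr.gene))
        return
    if isinstance(expr, GprAnd):
        node = parent.createAnd()
    elif isinstance(expr, GprOr):
        node = parent.createOr()
    else:  # pragma: no cover - callers filter the empty rule
        raise TypeError(f"cannot serialize {expr!r}")
    for child in expr.args:
        _expr_to_assoc(child, node, fbc_ns)


def _save_sbml(model: GEMModel, path: Path) -> None:
    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sbml_model = doc.createModel()
    sbml_model.setId(_sbml_safe(model.id))
    mplug = sbml_model.getPlugin("fbc")
    mplug.setStrict(True)

    compartments = sorted({m.compartment for m in model.metabolites.values()})
    for comp in compartments:
        c = sbml_model.createCompartment()
        c.setId(_sbml_safe(comp))
        c.setConstant(True)

    for met in model.metabolites.values():
        sp = sbml_model.createSpecies()
        sp.setId("M_" + _sbml_safe(met.id))
        sp.setName(met.name)
        sp.setCompartment(_sbml_safe(met.compartment))
        sp.setConstant(False)
        sp.setBoundaryCondition(False)
        sp.setHasOnlySubstanceUnits(False)
        if met.formula:
            sp.getPlugin("fbc").setChemicalFormula(met.formula)
        if met.mass_override is not None:
            sp.setNotes(
                f"<body xmlns='http://www.w3.org/1999/xhtml'>"
                f"<p>mass_override:{met.mass_override!r}</p></body>"
            )

    bound_params: dict[float, str] = {}

    def bound_id(value: float) -> str:
        if value not in bound_params:
            pid = f"fb_{len(bound_params)}"
            p = sbml_model.createParameter()
            p.setId(pid)
            p.setValue(value)
            p.setConstant(True)
            bound_params[value] = pid
        return bound_params[value]

    for gene in sorted(model.genes):
        gp = mplug.createGeneProduct()
        gp.setId("G_" + _sbml_safe(gene))
        gp.setLabel(gene)

    for rxn in model.reactions.values():
        rx = sbml_model.createReaction()
        rx.setId("R_" + _sbml_safe(rxn.id))
        rx.setFast(False)
        rx.setReversible(rxn.lb < 0)
        for met_id, coeff in sorted(rxn.stoich.items()):
            ref = rx.createReactant() if coeff < 0 else rx.createProduct()
            ref.setSpecies("M_" + _sbml_safe(met_id))
            ref.setStoichiometry(abs(coeff))
            ref.setConstant(True)
        rplug = rx.getPlugin("fbc")
        rplug.setLowerFluxBound(bound_id(rxn.lb))
        rplug.setUpperFluxBound(bound_id(rxn.ub))
        if render_gpr(rxn.gpr):
            gpa = rplug.createGeneProductAssociation()
            _expr_to_assoc(rxn.gpr, gpa, ns)

    obj = mplug.createObjective()
    obj.setId("obj")
    obj.setType("maximize")
    flux_obj = obj.createFluxObjective()
    flux_obj.setReaction("R_" + _sbml_safe(model.objective_reaction_id))
    flux_obj.setCoefficient(1.0)
    mplug.setActiveObjectiveId("obj")

    libsbml.writeSBMLToFile(doc, str(path))


# --------------------------------------------------------------------------
# dispatch
# --------------------------------------------------------------------------

def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt:
        return fmt
    return "sbml" if path.suffix.lower() in (".xml", ".sbml") else "json"


def load_model(path: str | Path, format: str | None = None) -> GEMModel:
    """Load a model from SBML (``.xml``) or the native JSON dialect.

    The loaded model is validated; any violation raises
    :class:`ModelReadError` with the full list.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, format)
    if fmt == "sbml":
        return _load_sbml(path)
    if fmt == "json":
        return _load_json(path)
    raise ValueError(f"unknown model format: {fmt!r}")


def save_model(model: GEMModel, path: str | Path, format: str | None = None) -> None:
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "sbml":
        _save_sbml(model, path)
    elif fmt == "json":
        _save_json(model, path)
    else:
        raise ValueError(f"unknown model format: {fmt!r}")
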