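"""Steady-state flux balance analysis (FBA).

FBA solves the linear program

    max  c·v
    s.t. S·v = 0,   lb <= v <= ub

where S is the stoichiometric matrix, v the flux vector (mmol/gDW/h) and c
the indicator of the biomass objective reaction, whose rate is the growth
rate (1/h).  Only the optimal objective value is contract-stable:
alternative optima mean individual fluxes are generally non-unique.

Viability follows the convention used in auxotrophy screens: a knockout is
called viable iff its optimum reaches a fixed fraction (default 1%) of the
wild-type optimum; infeasible problems count as zero growth and therefore
inviable.  Ties at the threshold resolve to viable (>=).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .model import GEMModel, ModelError, disabled_reactions

__all__ = [
    "FluxSolution",
    "ViabilityPolicy",
    "SolverError",
    "solve_fba",
    "wild_type_growth",
    "apply_knockout",
    "open_uptake",
    "is_viable",
    "DEFAULT_UPTAKE_BOUND",
]

DEFAULT_UPTAKE_BOUND = -1000.0  # mmol/gDW/h, the model's default minimum bound

FEASIBILITY_TOL = 1e-9
OPTIMALITY_TOL = 1e-9


class SolverError(RuntimeError):
    """The LP backend failed for a reason other than infeasibility."""

    def __init__(self, status: object, message: str):
        super().__init__(f"solver failure (status {status}): {message}")
        self.status = status


@dataclass
class FluxSolution:
    status: str  # optimal | infeasible | unbounded
    objective: float
    fluxes: dict[str, float] = field(default_factory=dict)

    @property
    def growth(self) -> float:
        """Objective value with infeasible problems mapped to 0 growth."""
        return self.objective if self.status == "optimal" else 0.0


@dataclass
class ViabilityPolicy:
    """Growth threshold: viable iff growth >= fraction * reference_growth."""

    reference_growth: float
    fraction: float = 0.01

    def __post_init__(self) -> None:
        if self.reference_growth < 0:
            raise ValueError("reference growth must be >= 0")
        if not (0 < self.fraction < 1):
            raise ValueError("viability fraction must be in (0, 1)")

    @property
    def threshold(self) -> float:
        return self.fraction * self.reference_growth

    @classmethod
    def from_model(cls, model: GEMModel, fraction: float = 0.01) -> "ViabilityPolicy":
        return cls(reference_growth=wild_type_growth(model), fraction=fraction)


def _solve_lp(c, S, lb, ub):
    """Narrow solver interface: min -c·v s.t. S·v=0, bounds. HiGHS backend."""
    res = linprog(
        -c,
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=np.column_stack([lb, ub]),
        method="highs",
        options={
            "presolve": True,
            "primal_feasibility_tolerance": FEASIBILITY_TOL,
            "dual_feasibility_tolerance": OPTIMALITY_TOL,
        },
    )
    if res.status == 0:
        return "optimal", -res.fun, res.x
    if res.status == 2:
        return "infeasible", 0.0, None
    if res.status == 3:
        return "unbounded", float("inf"), None
    raise SolverError(res.status, res.message)


def build_stoichiometric_matrix(model: GEMModel):
    """Sparse S (metabolites x reactions) plus the row/column id orders."""
    met_ids = list(model.metabolites)
    rxn_ids = list(model.reactions)
    met_index = {m: i for i, m in enumerate(met_ids)}
    rows, cols, vals = [], [], []
    for j, rid in enumerate(rxn_ids):
        for met_id, coeff in model.reactions[rid].stoich.items():
            rows.append(met_index[met_id])
            cols.append(j)
            vals.append(coeff)
    S = sparse.coo_matrix(
        (vals, (rows, cols)), shape=(len(met_ids), len(rxn_ids))
    ).tocsr()
    return S, met_ids, rxn_ids


def solve_fba(
    model: GEMModel, objective: str | None = None, sense: str = "max"
) -> FluxSolution:
    """Maximize the objective reaction's flux at steady state.

    Infeasibility is a valid result (status ``infeasible``, growth 0),
    not an error; genuine backend failures raise :class:`SolverError`.
    """
    if sense != "max":
        raise ValueError("only maximization is supported")
    objective = objective or model.objective_reaction_id
    if objective not in model.reactions:
        raise ModelError(f"objective reaction {objective!r} not in model")
    S, _met_ids, rxn_ids = build_stoichiometric_matrix(model)
    lb = np.array([model.reactions[r].lb for r in rxn_ids])
    ub = np.array([model.reactions[r].ub for r in rxn_ids])
    c = np.zeros(len(rxn_ids))
    c[rxn_ids.index(objective)] = 1.0
    status, obj, x = _solve_lp(c, S, lb, ub)
    fluxes = dict(zip(rxn_ids, x)) if x is not None else {}
    return FluxSolution(status=status, objective=obj, fluxes=fluxes)


_wt_cache: dict[str, float] = {}


def wild_type_growth(model: GEMModel) -> float:
    """FBA optimum of the unmodified model; cached per model fingerprint.

    Raises :class:`ModelError` if the model cannot grow on its default
    medium (no meaningful viability reference exists then).
    """
    key = model.fingerprint()
    if key not in _wt_cache:
        sol = solve_fba(model)
        if sol.status != "optimal" or sol.objective <= 0:
            raise ModelError("model cannot grow on default medium")
        _wt_cache[key] = sol.objective
    return _wt_cache[key]


def apply_knockout(model: GEMModel, genes: set[str]) -> GEMModel:
    """Copy of *model* with every GPR-disabled reaction's bounds set to 0."""
    disabled = disabled_reactions(model, genes)  # validates gene ids
    out = model.copy()
    for rid in disabled:
        rxn = out.reactions[rid]
        rxn.lb = 0.0
        rxn.ub = 0.0
    return out


def open_uptake(
    model: GEMModel, exchange_id: str, lb: float = DEFAULT_UPTAKE_BOUND
) -> GEMModel:
    """Copy of *model* with the exchange's lower bound set (uptake opened).

    The upper bound is untouched; negative flux through the exchange is
    uptake, so ``lb=-1000`` allows unconstrained supplementation.
    """
    if exchange_id not in model.reactions:
        raise ModelError(f"unknown reaction: {exchange_id!r}")
    if not model.reactions[exchange_id].is_exchange:
        raise ModelError(f"reaction {exchange_id!r} is not an exchange")
    out = model.copy()
    out.reactions[exchange_id].lb = lb
    return out


def is_viable(growth: float, policy: ViabilityPolicy) -> bool:
    """True iff growth reaches the policy threshold (ties are viable)."""
    return growth >= policy.threshold
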