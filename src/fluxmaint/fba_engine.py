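"""Linear-programming core: FBA, parsimonious FBA and ATP accounting.

The solver is driven through cobrapy/optlang (GLPK by default).  All
entry points are deterministic: no randomized restarts, no seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import cobra
from optlang.symbolics import Zero

from .errors import EngineError
from .model_core import MetabolicModel

#: LP feasibility/optimality tolerances requested from the solver.
LP_TOLERANCE = 1e-9

#: mass-balance tolerance a reported optimal flux vector must satisfy
MASS_BALANCE_TOL = 1e-6

#: nucleoside triphosphates whose production is summed for the total
#: energy production of a flux state
NTP_IDS = (
    "atp", "gtp", "ctp", "utp", "ttp", "itp",
    "datp", "dgtp", "dctp", "dutp", "dttp", "ditp",
)

#: reactions that only interconvert NTPs (nucleoside-diphosphate
#: kinases and the like); counting them would double-count energy
DEFAULT_NTP_EXCLUSIONS = ("NDPK",)


@dataclass
class FluxVector:
    """A solved flux state of a model."""

    fluxes: dict[str, float]
    objective_value: float
    status: str  # optimal | infeasible | unbounded | ...

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"

    def total_flux(self) -> float:
        return float(sum(abs(v) for v in self.fluxes.values()))

    def __getitem__(self, reaction_id: str) -> float:
        return self.fluxes[reaction_id]


def _as_cobra(model: MetabolicModel | cobra.Model) -> cobra.Model:
    return model.cobra_model if isinstance(model, MetabolicModel) else model


def _configure_solver(cm: cobra.Model) -> None:
    cm.tolerance = LP_TOLERANCE if LP_TOLERANCE >= 1e-9 else 1e-9


def _extract(cm: cobra.Model, solution) -> FluxVector:
    return FluxVector(
        fluxes={r.id: float(solution.fluxes[r.id]) for r in cm.reactions},
        objective_value=float(solution.objective_value),
        status=solution.status,
    )


def fba(
    model: MetabolicModel | cobra.Model,
    objective: str,
    direction: str = "max",
) -> FluxVector:
    """Plain flux balance analysis for one objective reaction."""
    cm = _as_cobra(model)
    with cm:
        _configure_solver(cm)
        cm.objective = cm.reactions.get_by_id(objective)
        cm.objective_direction = direction
        solution = cm.optimize()
        if solution.status != "optimal":
            return FluxVector(fluxes={}, objective_value=float("nan"), status=solution.status)
        return _extract(cm, solution)


def pfba(
    model: MetabolicModel | cobra.Model,
    objective: str,
    direction: str = "max",
) -> FluxVector:
    """Parsimonious FBA: optimize, fix the optimum, minimize total flux.

    Stage 1 optimizes the stated objective.  Stage 2 constrains the
    objective to exactly its stage-1 optimum and minimizes the sum of
    absolute fluxes over all reactions (every reversible reaction is
    represented by its non-negative forward and reverse variables, so
    the stage-2 objective is linear).
    """
    cm = _as_cobra(model)
    with cm:
        _configure_solver(cm)
        cm.objective = cm.reactions.get_by_id(objective)
        cm.objective_direction = direction
        stage1 = cm.optimize()
        if stage1.status != "optimal":
            return FluxVector(fluxes={}, objective_value=float("nan"), status=stage1.status)
        optimum = float(stage1.objective_value)

        cobra.util.solver.fix_objective_as_constraint(cm, fraction=1.0)
        stage2_objective = cm.problem.Objective(Zero, direction="min", sloppy=True)
        cm.objective = stage2_objective
        coefficients = {}
        for rxn in cm.reactions:
            coefficients[rxn.forward_variable] = 1.0
            coefficients[rxn.reverse_variable] = 1.0
        cm.objective.set_linear_coefficients(coefficients)
        stage2 = cm.optimize()
        if stage2.status != "optimal":
            raise EngineError(
                f"pFBA stage 2 returned {stage2.status!r} at fixed optimum "
                f"{optimum}; this indicates a numerical tolerance problem"
            )
        result = _extract(cm, stage2)
        result.objective_value = optimum
        return result


def maximize_atp_hydrolysis(model: MetabolicModel) -> FluxVector:
    """Parsimonious FBA maximizing the maintenance (ATP hydrolysis) flux.

    Used for the experimental determination of maintenance energy after
    exchange and biomass bounds have been applied.
    """
    return pfba(model, objective=model.maintenance_id, direction="max")


def total_ntp_production(
    v: FluxVector,
    model: MetabolicModel | cobra.Model,
    exclude_prefixes: Iterable[str] = DEFAULT_NTP_EXCLUSIONS,
) -> float:
    """Total production flux of nucleoside triphosphates.

    Sums the positive net production contributions of every reaction
    over all NTP species (ATP, GTP, CTP, UTP, TTP, ITP and their deoxy
    forms).  Each species is pooled across compartments before taking
    the positive part, so transporters (which "produce" an NTP on one
    side of a membrane while consuming it on the other) contribute
    nothing.  Reactions matching ``exclude_prefixes`` (NTP-
    interconverting kinases) are skipped so that phosphate transfers
    between NTP pools are not double-counted either.
    """
    cm = _as_cobra(model)
    excluded = tuple(exclude_prefixes)
    total = 0.0
    for rxn in cm.reactions:
        if excluded and rxn.id.startswith(excluded):
            continue
        flux = v.fluxes.get(rxn.id, 0.0)
        if flux == 0.0:
            continue
        pooled: dict[str, float] = {}
        for met, coeff in rxn.metabolites.items():
            species = met.id.rsplit("_", 1)[0]
            if species in NTP_IDS:
                pooled[species] = pooled.get(species, 0.0) + coeff
        for net_coeff in pooled.values():
            total += max(net_coeff * flux, 0.0)
    return float(total)


def mass_balance_residual(v: FluxVector, model: MetabolicModel | cobra.Model) -> float:
    """max |S.v| over metabolites; optimal solutions satisfy <= 1e-6."""
    cm = _as_cobra(model)
    residual: dict[str, float] = {m.id: 0.0 for m in cm.metabolites}
    for rxn in cm.reactions:
        flux = v.fluxes.get(rxn.id, 0.0)
        if flux == 0.0:
            continue
        for met, coeff in rxn.metabolites.items():
            residual[met.id] += coeff * flux
    # boundary metabolites of exchange pseudo-reactions are not balanced
    boundary = {m.id for r in cm.boundary for m in r.metabolites}
    values = [abs(val) for mid, val in residual.items() if mid not in boundary]
    return float(max(values)) if values else 0.0
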