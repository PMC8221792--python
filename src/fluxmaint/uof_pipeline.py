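"""The uptake-objective-function (UOF) protocol.

As an alternative to maximizing biomass, growth and productivity are
fixed to their experimental values and the uptake of one nonessential
nutrient is minimized.  Because measured essential amino-acid uptakes
are sometimes too low to sustain the measured growth, the protocol
first computes, one amino acid at a time, the minimal uptake that
supports growth, and replaces any measured value whose magnitude falls
short of that minimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .fba_engine import FluxVector, fba, pfba
from .model_core import ExchangeDataset, MetabolicModel, apply_exchange_constraints


@dataclass
class UofResult:
    objective_species: str
    minimal_uptake: float  # mmol gDW^-1 h^-1, <= 0
    fluxes: FluxVector
    adjusted_constraints: list[tuple[str, float, float]] = field(default_factory=list)


def _fix_growth_and_product(
    model: MetabolicModel, data: ExchangeDataset, biomass_id: str
) -> None:
    cm = model.cobra_model
    mu = data.growth_rate[0]
    for bid in model.biomass_ids:
        cm.reactions.get_by_id(bid).bounds = (mu, mu) if bid == biomass_id else (0.0, 0.0)
    if data.productivity[0] > 0:
        if model.product_exchange_id is None:
            raise ValidationError(
                "dataset declares a productivity but the model has no product exchange"
            )
        cm.reactions.get_by_id(model.product_exchange_id).bounds = (
            data.productivity[0],
            data.productivity[0],
        )


def minimal_essential_uptakes(
    model: MetabolicModel,
    data: ExchangeDataset,
    essential_ids: list[str] | None = None,
    biomass_id: str | None = None,
) -> dict[str, float]:
    """Minimal uptake of each essential amino acid sustaining growth.

    With growth rate and productivity point-fixed and all other
    nutrient uptakes unconstrained, each essential amino acid's uptake
    is minimized in magnitude one at a time.  Returned values are
    negative (uptake) or zero.
    """
    essential_ids = essential_ids or model.essential_aa_ids
    biomass_id = biomass_id or model.biomass_ids[0]
    work = model.copy()
    cm = work.cobra_model
    _fix_growth_and_product(work, data, biomass_id)
    # nutrients freely available while probing the requirement
    for rxn in cm.boundary:
        rxn.lower_bound = -1000.0

    out: dict[str, float] = {}
    for aa in essential_ids:
        ex = work.exchange_for(aa)
        v = fba(work, objective=ex.id, direction="max")
        if not v.optimal:
            raise ValidationError(
                "model cannot sustain the experimental growth rate even with "
                "all uptakes free; data and model are inconsistent"
            )
        out[aa] = min(float(v.objective_value), 0.0)
    return out


def reconcile_uptakes(
    measured: dict[str, float], minimal: dict[str, float]
) -> tuple[dict[str, float], list[tuple[str, float, float]]]:
    """Replace measured uptakes that cannot sustain growth by the minimal ones.

    For each species, if |measured| < |minimal| the computed minimal
    uptake is used and the adjustment is logged; otherwise the measured
    value is kept.
    """
    reconciled: dict[str, float] = {}
    log: list[tuple[str, float, float]] = []
    for aa, minimum in minimal.items():
        if aa not in measured:
            reconciled[aa] = minimum
            log.append((aa, float("nan"), minimum))
            continue
        meas = measured[aa]
        if abs(meas) < abs(minimum):
            reconciled[aa] = minimum
            log.append((aa, meas, minimum))
        else:
            reconciled[aa] = meas
    return reconciled, log


def uof_pfba(
    model: MetabolicModel,
    data: ExchangeDataset,
    objective_species: str,
    reconciled: dict[str, float] | None = None,
    biomass_id: str | None = None,
) -> UofResult:
    """pFBA minimizing the uptake magnitude of one nonessential nutrient.

    All measured exchanges, growth and productivity are point-fixed to
    the experimental values; essential amino acids use the reconciled
    uptakes; the objective species' uptake is left free (secretion
    closed) and minimized in magnitude, i.e. its negative exchange flux
    is maximized toward zero.
    """
    biomass_id = biomass_id or model.biomass_ids[0]
    if reconciled is None:
        minimal = minimal_essential_uptakes(model, data, biomass_id=biomass_id)
        measured = {aa: data.rates[aa][0] for aa in minimal if aa in data.rates}
        reconciled, log = reconcile_uptakes(measured, minimal)
    else:
        log = []

    work = model.copy()
    apply_exchange_constraints(work, data)
    for aa, value in reconciled.items():
        work.exchange_for(aa).bounds = (value, value)
    _fix_growth_and_product(work, data, biomass_id)
    obj_ex = work.exchange_for(objective_species)
    obj_ex.bounds = (-1000.0, 0.0)

    v = pfba(work, objective=obj_ex.id, direction="max")
    if not v.optimal:
        blocking = _relaxation_probe(work, obj_ex.id, data)
        raise ValidationError(
            f"uptake minimization infeasible; blocking constraint family: {blocking}"
        )
    return UofResult(
        objective_species=objective_species,
        minimal_uptake=float(v.fluxes[obj_ex.id]),
        fluxes=v,
        adjusted_constraints=log,
    )


def _relaxation_probe(model: MetabolicModel, objective_rxn: str, data: ExchangeDataset) -> str:
    """Identify which constraint family blocks feasibility.

    Constraint families are relaxed in turn (secretions, then
    nonessential uptakes, then growth); the first relaxation that
    restores feasibility names the blocking family.
    """
    cm = model.cobra_model
    families = {
        "secretions": [
            model.exchange_for(sid).id for sid, (v, _) in data.rates.items() if v > 0
        ],
        "nonessential uptakes": [
            model.exchange_for(sid).id
            for sid, (v, _) in data.rates.items()
            if v < 0 and sid not in model.essential_aa_ids
        ],
        "growth": list(model.biomass_ids),
    }
    for name, rxn_ids in families.items():
        with cm:
            for rid in rxn_ids:
                cm.reactions.get_by_id(rid).bounds = (
                    (0.0, 1000.0) if name == "secretions" else (-1000.0, 1000.0)
                )
            v = fba(model, objective=objective_rxn, direction="max")
            if v.optimal:
                return name
    return "unidentified (multiple families)"
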