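"""Experimental-style determination of maintenance energy and Y_ATP^max.

For each chemostat steady state the measured exchange rates and growth
rate are applied as interval constraints (value +/- SD), minimal
essential-amino-acid requirements are reconciled, ATP hydrolysis is
maximized by pFBA and the total nucleoside-triphosphate production of
the solution is recorded.  An ordinary least-squares line of total ATP
production against growth rate then yields the non-growth-associated
maintenance (intercept) and the maximal biomass yield per ATP
(1000/slope, g mol^-1).  Infeasible states are repaired by stepwise
relaxation of secretion lower bounds only (upper bounds stay at the
measured values).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

from .errors import EstimationError, ValidationError
from .fba_engine import FluxVector, maximize_atp_hydrolysis, total_ntp_production
from .chemostat_rates import SteadyStateRates
from .model_core import ExchangeDataset, MetabolicModel, set_po_ratio
from .uof_pipeline import minimal_essential_uptakes, reconcile_uptakes


@dataclass
class RelaxPolicy:
    """Stepwise relaxation of secretion lower bounds."""

    step_percent: float = 5.0
    cap_percent: float = 40.0


@dataclass
class AtpCurvePoint:
    mu: float  # h^-1
    atp_total: float  # mmol gDW^-1 h^-1
    dataset_id: str
    relaxations: list[tuple[str, float]] = field(default_factory=list)
    fluxes: FluxVector | None = None

    def __post_init__(self) -> None:
        if self.atp_total < -1e-9:
            raise ValidationError("total ATP production cannot be negative")


@dataclass
class MaintenanceFit:
    matp: float  # mmol gDW^-1 h^-1
    matp_se: float
    yatp_max: float  # g mol^-1 (1000 / slope)
    yatp_se: float
    slope: float  # mmol ATP per gDW
    slope_se: float
    r_squared: float
    ci95: tuple[float, float]  # 95% CI of the intercept
    n_points: int


def _rates_to_exchange_dataset(rates: SteadyStateRates) -> ExchangeDataset:
    return ExchangeDataset(
        dataset_id=rates.record_id,
        rates={sid: (v, sd) for sid, (v, sd) in rates.q.items()},
        growth_rate=rates.growth_rate,
    )


def atp_curve_point(
    model: MetabolicModel,
    rates: SteadyStateRates,
    relax_policy: RelaxPolicy | None = None,
    biomass_id: str | None = None,
    constrain: list[str] | None = None,
) -> AtpCurvePoint:
    """One total-ATP-production point at one measured steady state.

    Exchange and growth bounds are fixed to value +/- SD; gas exchanges
    (oxygen, CO2) are never constrained.  Essential amino-acid uptakes
    whose measured magnitude cannot sustain the measured growth are
    widened to the model's minimal requirement (this does not affect
    the ATP accounting: in the model those amino acids are used for
    biomass only once their catabolism cannot run).  If the constrained
    LP is infeasible, secretion lower bounds are relaxed in steps until
    the cap; each relaxation is logged.
    """
    relax_policy = relax_policy or RelaxPolicy()
    biomass_id = biomass_id or model.biomass_ids[0]
    work = model.copy()
    cm = work.cobra_model

    mu, mu_sd = rates.growth_rate
    skip = {work.oxygen_id, "co2"}
    measured = {sid: vs for sid, vs in rates.q.items() if sid not in skip}
    for sid, (value, sd) in measured.items():
        work.exchange_for(sid).bounds = (value - sd, value + sd)
    for bid in work.biomass_ids:
        cm.reactions.get_by_id(bid).bounds = (
            (mu - mu_sd, mu + mu_sd) if bid == biomass_id else (0.0, 0.0)
        )
    # maintenance is the free objective
    cm.reactions.get_by_id(work.maintenance_id).bounds = (0.0, 1000.0)

    # reconcile essential amino-acid requirements
    exchange_data = _rates_to_exchange_dataset(rates)
    minimal = minimal_essential_uptakes(
        model, exchange_data, biomass_id=biomass_id
    )
    measured_aa = {aa: measured[aa][0] for aa in minimal if aa in measured}
    reconciled, adjustments = reconcile_uptakes(measured_aa, minimal)
    for aa, _, new_value in adjustments:
        ex = work.exchange_for(aa)
        sd = measured[aa][1] if aa in measured else 0.0
        ex.bounds = (new_value - sd, new_value + sd)

    relaxations: list[tuple[str, float]] = []
    secretion_lbs = {
        work.exchange_for(sid).id: work.exchange_for(sid).lower_bound
        for sid, (value, _) in measured.items()
        if value > 0
    }
    percent = 0.0
    while True:
        v = maximize_atp_hydrolysis(work)
        if v.optimal:
            break
        percent += relax_policy.step_percent
        if percent > relax_policy.cap_percent:
            raise EstimationError(
                f"{rates.record_id}: infeasible even after relaxing secretion "
                f"lower bounds by {relax_policy.cap_percent}%"
            )
        relaxations = []
        for rid, lb in secretion_lbs.items():
            cm.reactions.get_by_id(rid).lower_bound = lb * (1.0 - percent / 100.0)
            relaxations.append((rid, percent))

    return AtpCurvePoint(
        mu=mu,
        atp_total=total_ntp_production(v, work),
        dataset_id=rates.record_id,
        relaxations=relaxations,
        fluxes=v,
    )


def fit_maintenance(points: list[AtpCurvePoint]) -> MaintenanceFit:
    """OLS of total ATP production on growth rate.

    The intercept is the non-growth-associated maintenance mATP and
    1000/slope the maximal biomass yield per mole of ATP in g mol^-1.
    """
    if len(points) < 3:
        raise EstimationError("need at least 3 points for a maintenance fit")
    mus = np.array([p.mu for p in points])
    atps = np.array([p.atp_total for p in points])
    if np.ptp(mus) <= 1e-12:
        raise EstimationError("growth rates are degenerate; cannot fit a line")
    fit = sm.OLS(atps, sm.add_constant(mus)).fit()
    intercept, slope = (float(x) for x in fit.params)
    intercept_se, slope_se = (float(x) for x in fit.bse)
    ci = fit.conf_int(alpha=0.05)
    if slope <= 0:
        raise EstimationError(
            "non-positive ATP-vs-growth slope; yield per ATP undefined"
        )
    yatp = 1000.0 / slope
    yatp_se = 1000.0 * slope_se / slope**2  # first-order (delta-method) error
    return MaintenanceFit(
        matp=intercept,
        matp_se=intercept_se,
        yatp_max=yatp,
        yatp_se=yatp_se,
        slope=slope,
        slope_se=slope_se,
        r_squared=float(fit.rsquared),
        ci95=(float(ci[0][0]), float(ci[0][1])),
        n_points=len(points),
    )


def maintenance_curve(
    model: MetabolicModel,
    rates_list: list[SteadyStateRates],
    relax_policy: RelaxPolicy | None = None,
    biomass_id: str | None = None,
) -> tuple[list[AtpCurvePoint], list[str]]:
    """ATP curve points for all steady states; infeasible ones are reported."""
    points: list[AtpCurvePoint] = []
    excluded: list[str] = []
    for rates in rates_list:
        try:
            points.append(atp_curve_point(model, rates, relax_policy, biomass_id))
        except EstimationError:
            excluded.append(rates.record_id)
    return points, excluded


def po_sensitivity(
    model: MetabolicModel,
    rates_list: list[SteadyStateRates],
    po_values: list[float],
    relax_policy: RelaxPolicy | None = None,
    biomass_id: str | None = None,
) -> dict[float, MaintenanceFit]:
    """Repeat the full curve-and-fit for each P/O ratio."""
    out: dict[float, MaintenanceFit] = {}
    for po in po_values:
        work = model.copy()
        set_po_ratio(work, po)
        points, _ = maintenance_curve(work, rates_list, relax_policy, biomass_id)
        out[po] = fit_maintenance(points)
    return out
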