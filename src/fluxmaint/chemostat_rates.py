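"""Steady-state rate computation from continuous-culture raw data.

Implements the standard chemostat bookkeeping: dilution rate D = F/V
from the feed-mass balance, growth rate mu = D * Nt/Nv (at steady state
dead cells are washed out, so growth must exceed dilution whenever
viability is below 100%), specific exchange rates
q = (Cout - Cin) * D / X with uptake negative, Gaussian error
propagation for products/quotients and sums/differences, a
stability check on the slope of each monitored parameter, and a carbon
recovery balance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import InsufficientDataError, ValidationError
from .model_core import (
    DRY_MASS_PG_DEFAULT,
    MetabolicModel,
    carbon_count,
    cells_per_ml_to_gdw_per_l,
)

#: feed medium density used to convert balance readings (g) to volume (mL)
MEDIUM_DENSITY_G_PER_ML = 1.0


@dataclass
class ChemostatRecord:
    """Raw time series of one steady-state window of a continuous culture."""

    record_id: str
    times: np.ndarray  # h
    feed_mass: np.ndarray  # cumulative g of fresh medium pumped in
    volume_ml: float
    viable_density: np.ndarray  # cells mL^-1
    total_density: np.ndarray  # cells mL^-1
    concentrations: dict[str, np.ndarray]  # mM per species
    feed_concentrations: dict[str, float]  # mM
    dry_mass: float = DRY_MASS_PG_DEFAULT  # pg cell^-1

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError(f"{self.record_id}: times must be strictly increasing")
        if self.volume_ml <= 0:
            raise ValidationError(f"{self.record_id}: volume must be positive")
        nv = np.asarray(self.viable_density, dtype=float)
        nt = np.asarray(self.total_density, dtype=float)
        if np.any(nv <= 0) or np.any(nt + 1e-9 < nv):
            raise ValidationError(f"{self.record_id}: need Nt >= Nv > 0")

    def to_tsv(self, path: str | Path) -> None:
        rows = []
        for i, t in enumerate(self.times):
            rows.append({"time_h": t, "parameter": "feed_mass_g", "value": self.feed_mass[i]})
            rows.append({"time_h": t, "parameter": "viable_density", "value": self.viable_density[i]})
            rows.append({"time_h": t, "parameter": "total_density", "value": self.total_density[i]})
            for sid, series in self.concentrations.items():
                rows.append({"time_h": t, "parameter": f"conc_{sid}", "value": series[i]})
        df = pd.DataFrame(rows)
        df.insert(0, "record_id", self.record_id)
        meta = [
            {"record_id": self.record_id, "time_h": -1, "parameter": "volume_ml", "value": self.volume_ml},
            {"record_id": self.record_id, "time_h": -1, "parameter": "dry_mass_pg", "value": self.dry_mass},
        ] + [
            {"record_id": self.record_id, "time_h": -1, "parameter": f"feed_{sid}", "value": c}
            for sid, c in self.feed_concentrations.items()
        ]
        pd.concat([pd.DataFrame(meta), df]).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ChemostatRecord":
        df = pd.read_csv(path, sep="\t")
        meta = df[df["time_h"] < 0]
        data = df[df["time_h"] >= 0]
        times = np.array(sorted(data["time_h"].unique()))

        def series(param: str) -> np.ndarray:
            sub = data[data["parameter"] == param].sort_values("time_h")
            return sub["value"].to_numpy(dtype=float)

        conc_params = sorted(
            p for p in data["parameter"].unique() if str(p).startswith("conc_")
        )
        feed = {
            str(r["parameter"])[5:]: float(r["value"])
            for _, r in meta.iterrows()
            if str(r["parameter"]).startswith("feed_")
        }
        return cls(
            record_id=str(df["record_id"].iloc[0]),
            times=times,
            feed_mass=series("feed_mass_g"),
            volume_ml=float(meta[meta["parameter"] == "volume_ml"]["value"].iloc[0]),
            viable_density=series("viable_density"),
            total_density=series("total_density"),
            concentrations={p[5:]: series(p) for p in conc_params},
            feed_concentrations=feed,
            dry_mass=float(meta[meta["parameter"] == "dry_mass_pg"]["value"].iloc[0]),
        )


@dataclass
class StabilityResult:
    stable: bool | None  # None when too few points for a confidence interval
    slope: float
    ci95: tuple[float, float]
    insufficient_data: bool = False
    within_instrument_error: bool = False


@dataclass
class SteadyStateRates:
    """Derived steady-state quantities of one dilution rate."""

    record_id: str
    dilution_rate: tuple[float, float]  # h^-1
    growth_rate: tuple[float, float]  # h^-1
    biomass_conc: tuple[float, float]  # gDW L^-1
    viable_density: float  # cells mL^-1
    q: dict[str, tuple[float, float]]  # mmol gDW^-1 h^-1, uptake negative
    carbon_recovery: float | None = None
    stability: dict[str, StabilityResult] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.growth_rate[0] + 1e-12 < self.dilution_rate[0]:
            raise ValidationError(
                f"{self.record_id}: growth rate below dilution rate "
                "(requires Nt >= Nv)"
            )


# -- elementary operations -----------------------------------------------------


def propagate_sd(op: str, values: tuple[float, float], sds: tuple[float, float]) -> float:
    """Standard deviation of C = A op B by Gaussian error propagation.

    ``product_quotient``: sigma_C = |C| sqrt((sA/A)^2 + (sB/B)^2);
    ``sum_difference``:  sigma_C = sqrt(sA^2 + sB^2).
    """
    a, b = values
    sa, sb = sds
    if sa < 0 or sb < 0:
        raise ValidationError("standard deviations must be non-negative")
    if op == "sum_difference":
        return float(np.hypot(sa, sb))
    if op == "product_quotient":
        if a == 0 or b == 0:
            raise ValidationError(
                "relative error propagation undefined for zero values; "
                "use sum_difference on the underlying terms instead"
            )
        c = a * b
        return float(abs(c) * np.hypot(sa / a, sb / b))
    raise ValidationError(f"unknown propagation op {op!r}")


def dilution_rate(
    record: ChemostatRecord, medium_density: float = MEDIUM_DENSITY_G_PER_ML
) -> tuple[float, float]:
    """D = F/V with F from the slope of the feed-mass curve (mL h^-1)."""
    if len(record.times) < 2:
        raise InsufficientDataError(
            f"{record.record_id}: need >=2 feed-mass points for a flow rate"
        )
    X = sm.add_constant(record.times)
    fit = sm.OLS(np.asarray(record.feed_mass, dtype=float) / medium_density, X).fit()
    F, F_se = float(fit.params[1]), float(fit.bse[1])
    D = F / record.volume_ml
    return D, F_se / record.volume_ml


def growth_rate(
    D: tuple[float, float], Nt: tuple[float, float], Nv: tuple[float, float]
) -> tuple[float, float]:
    """mu = D * Nt / Nv; always >= D because Nt >= Nv."""
    if Nv[0] <= 0:
        raise ValidationError("viable density must be positive")
    ratio = Nt[0] / Nv[0]
    ratio_sd = (
        propagate_sd("product_quotient", (Nt[0], 1.0 / Nv[0]), (Nt[1], Nv[1] / Nv[0] ** 2))
        if Nt[0] != 0
        else 0.0
    )
    mu = D[0] * ratio
    if mu == 0.0:
        return 0.0, 0.0
    sd = propagate_sd("product_quotient", (D[0], ratio), (D[1], ratio_sd)) if D[0] != 0 else 0.0
    return mu, sd


def exchange_rate(
    cin: float,
    cout: tuple[float, float],
    D: tuple[float, float],
    biomass_conc: tuple[float, float],
) -> tuple[float, float]:
    """q = (Cout - Cin) * D / X in mmol gDW^-1 h^-1 (uptake negative).

    ``cin`` is the (known) feed concentration in mM, ``cout`` the
    averaged steady-state concentration in the vessel.
    """
    if biomass_conc[0] <= 0:
        raise ValidationError("biomass concentration must be positive")
    if cin < 0 or cout[0] < 0:
        raise ValidationError("concentrations must be non-negative")
    delta = cout[0] - cin
    delta_sd = cout[1]  # feed concentration is a known formulation value
    q = delta * D[0] / biomass_conc[0]
    if delta == 0.0 or D[0] == 0.0:
        return 0.0, 0.0
    factor_sd = propagate_sd(
        "product_quotient",
        (D[0], 1.0 / biomass_conc[0]),
        (D[1], biomass_conc[1] / biomass_conc[0] ** 2),
    )
    sd = propagate_sd("product_quotient", (delta, D[0] / biomass_conc[0]), (delta_sd, factor_sd))
    return q, sd


def stability_check(
    times: np.ndarray,
    series: np.ndarray,
    instrument_error: float | None = None,
) -> StabilityResult:
    """OLS slope of value vs time; stable iff the 95% CI contains zero.

    With fewer than 3 points no confidence interval exists and the
    result is flagged as insufficient rather than silently stable.  If
    the fitted total change over the window is below
    ``instrument_error`` the instability is additionally flagged as
    within measurement error.
    """
    times = np.asarray(times, dtype=float)
    series = np.asarray(series, dtype=float)
    if len(times) < 3:
        return StabilityResult(
            stable=None, slope=float("nan"), ci95=(float("nan"), float("nan")),
            insufficient_data=True,
        )
    fit = sm.OLS(series, sm.add_constant(times)).fit()
    slope = float(fit.params[1])
    lo, hi = (float(x) for x in fit.conf_int(alpha=0.05)[1])
    stable = lo <= 0.0 <= hi
    within = False
    if not stable and instrument_error is not None:
        total_change = abs(slope) * (times[-1] - times[0])
        within = total_change <= instrument_error
    return StabilityResult(stable=stable, slope=slope, ci95=(lo, hi), within_instrument_error=within)


# -- aggregation ---------------------------------------------------------------


def biomass_carbon_content(model: MetabolicModel, biomass_id: str | None = None) -> float:
    """Net mmol of carbon drawn into biomass per gDW, from the biomass reaction."""
    biomass_id = biomass_id or model.biomass_ids[0]
    rxn = model.cobra_model.reactions.get_by_id(biomass_id)
    return -sum(coeff * carbon_count(met) for met, coeff in rxn.metabolites.items())


def carbon_recovery(
    q: dict[str, tuple[float, float]],
    model: MetabolicModel,
    mu: float,
    biomass_carbon: float,
) -> float:
    """(C secreted + C into biomass) / C taken up, all per gDW and hour."""
    uptake_c = 0.0
    secreted_c = 0.0
    for sid, (value, _) in q.items():
        met = model.cobra_model.metabolites.get_by_id(f"{sid}_e")
        n_c = carbon_count(met)
        if value < 0:
            uptake_c += -value * n_c
        else:
            secreted_c += value * n_c
    if uptake_c == 0.0:
        raise ValidationError("no carbon uptake; recovery undefined")
    return (secreted_c + mu * biomass_carbon) / uptake_c


def steady_state_rates(
    record: ChemostatRecord,
    model: MetabolicModel | None = None,
    biomass_id: str | None = None,
    instrument_errors: dict[str, float] | None = None,
) -> SteadyStateRates:
    """Derive all steady-state rates of one dilution-rate window.

    Samples within the window are averaged; their standard deviations
    feed the error propagation.  Carbon recovery is computed when a
    model is supplied (its biomass reaction provides the carbon content
    of biomass).
    """
    instrument_errors = instrument_errors or {}
    D = dilution_rate(record)
    nv = record.viable_density.mean(), record.viable_density.std(ddof=1) if len(record.viable_density) > 1 else 0.0
    nt = record.total_density.mean(), record.total_density.std(ddof=1) if len(record.total_density) > 1 else 0.0
    mu = growth_rate(D, nt, nv)

    X = cells_per_ml_to_gdw_per_l(nv[0], record.dry_mass)
    X_sd = cells_per_ml_to_gdw_per_l(nv[1], record.dry_mass)

    q: dict[str, tuple[float, float]] = {}
    stability: dict[str, StabilityResult] = {}
    for sid, series in record.concentrations.items():
        cin = record.feed_concentrations.get(sid, 0.0)
        cout = (float(series.mean()), float(series.std(ddof=1)) if len(series) > 1 else 0.0)
        q[sid] = exchange_rate(cin, cout, D, (X, X_sd))
        stability[sid] = stability_check(record.times, series, instrument_errors.get(sid))
    stability["viable_density"] = stability_check(
        record.times, record.viable_density, instrument_errors.get("viable_density")
    )

    recovery = None
    if model is not None:
        recovery = carbon_recovery(
            q, model, mu[0], biomass_carbon_content(model, biomass_id)
        )
    return SteadyStateRates(
        record_id=record.record_id,
        dilution_rate=D,
        growth_rate=mu,
        biomass_conc=(X, X_sd),
        viable_density=nv[0],
        q=q,
        carbon_recovery=recovery,
        stability=stability,
    )


def rates_table(rates: list[SteadyStateRates]) -> pd.DataFrame:
    """Tabular overview mirroring a chemostat summary table."""
    rows = []
    for r in rates:
        row = {
            "ID": r.record_id,
            "dilution_rate": r.dilution_rate[0],
            "growth_rate": r.growth_rate[0],
            "viable_cells_per_ml": r.viable_density,
        }
        for sid, (v, sd) in sorted(r.q.items()):
            row[f"q_{sid}"] = v
            row[f"q_{sid}_sd"] = sd
        row["carbon_recovery"] = r.carbon_recovery
        rows.append(row)
    return pd.DataFrame(rows)
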