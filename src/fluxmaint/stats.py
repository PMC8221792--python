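"""Error metrics and regression machinery shared by all comparisons.

The central error metric is the per-reaction relative error
|v_p - v_e| / |v_e| between predicted and experimentally determined
fluxes; agreement is additionally summarized by (weighted) linear fits
of predicted on experimental fluxes, where the inverses of the
experimental confidence-interval widths serve as weights.  Whether
adding a maintenance constraint significantly changes the fit is
assessed by a categorical group predictor with an interaction term and
by a likelihood-ratio test between the nested models.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .errors import ValidationError


@dataclass
class RelativeErrors:
    errors: dict[str, float]
    mean: float
    median: float


@dataclass
class RegressionResult:
    slope: float
    slope_se: float
    intercept: float
    intercept_se: float
    r_squared: float
    p_interaction: float | None = None
    lr_chi2: float | None = None
    lr_df: int | None = None
    lr_p: float | None = None


def relative_errors(vp: Mapping[str, float], ve: Mapping[str, float]) -> RelativeErrors:
    """Per-entry relative error |v_p - v_e| / |v_e| over the shared keys.

    Entries with v_e = 0 must have been removed upstream (by the
    small-flux filter); encountering one here is a contract breach.
    """
    shared = [k for k in ve if k in vp]
    if not shared:
        raise ValidationError("no shared keys between predictions and measurements")
    errors: dict[str, float] = {}
    for k in shared:
        if ve[k] == 0:
            raise ValidationError(
                f"experimental flux {k!r} is zero; apply the small-flux filter first"
            )
        errors[k] = abs(vp[k] - ve[k]) / abs(ve[k])
    values = np.array(list(errors.values()))
    return RelativeErrors(errors=errors, mean=float(values.mean()), median=float(np.median(values)))


def _weights_from_ci(ci_widths: Sequence[float]) -> np.ndarray:
    """Inverse-CI-width weights with capping for zero/missing widths.

    Zero widths would give infinite leverage and missing widths none;
    zero widths are capped at the largest finite weight of the dataset
    and missing widths receive the median weight.
    """
    widths = np.asarray(ci_widths, dtype=float)
    raw = np.full(widths.shape, np.nan)
    positive = widths > 0
    raw[positive] = 1.0 / widths[positive]
    finite = raw[np.isfinite(raw)]
    if finite.size == 0:
        # no informative widths at all (e.g. noise-free synthetic data):
        # fall back to equal weights
        return np.ones_like(widths)
    cap = float(finite.max())
    median = float(np.median(finite))
    out = np.where(np.isnan(widths), median, np.where(positive, raw, cap))
    out = np.where(np.isfinite(out), out, median)
    return out


def weighted_fit(
    x: Sequence[float], y: Sequence[float], ci_widths: Sequence[float] | None = None
) -> RegressionResult:
    """Weighted least squares of predicted (y) on experimental (x) fluxes."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("x and y must have the same length")
    if ci_widths is None:
        w = np.ones_like(x)
    else:
        w = _weights_from_ci(ci_widths)
    fit = sm.WLS(y, sm.add_constant(x), weights=w).fit()
    return RegressionResult(
        slope=float(fit.params[1]),
        slope_se=float(fit.bse[1]),
        intercept=float(fit.params[0]),
        intercept_se=float(fit.bse[0]),
        r_squared=float(fit.rsquared),
    )


def matp_effect_test(
    ve: Sequence[float],
    vp_without: Sequence[float],
    vp_with: Sequence[float],
) -> RegressionResult:
    """Does a maintenance constraint change the experimental-vs-predicted fit?

    The two prediction sets (same experimental fluxes) are stacked with
    a categorical group indicator g (0 = without, 1 = with) and the
    model vp ~ ve + g + ve:g is fitted; the p-value of the interaction
    coefficient tests for a slope change.  A likelihood-ratio chi2
    between vp ~ ve and the full model (2 df) tests the overall effect
    of the group terms.  Returned slope/intercept describe the full
    model's g = 1 group.
    """
    ve = np.asarray(ve, dtype=float)
    vp0 = np.asarray(vp_without, dtype=float)
    vp1 = np.asarray(vp_with, dtype=float)
    if not (len(ve) == len(vp0) == len(vp1)):
        raise ValidationError("prediction sets must cover the same experimental fluxes")
    if len(ve) < 4:
        raise ValidationError("too few points for an interaction model")
    x = np.concatenate([ve, ve])
    g = np.concatenate([np.zeros_like(ve), np.ones_like(ve)])
    y = np.concatenate([vp0, vp1])
    design_full = sm.add_constant(np.column_stack([x, g, x * g]))
    full = sm.OLS(y, design_full).fit()
    reduced = sm.OLS(y, sm.add_constant(x)).fit()
    lr = 2.0 * (full.llf - reduced.llf)
    lr = max(lr, 0.0)
    df = 2
    return RegressionResult(
        slope=float(full.params[1] + full.params[3]),
        slope_se=float(np.hypot(full.bse[1], full.bse[3])),
        intercept=float(full.params[0] + full.params[2]),
        intercept_se=float(np.hypot(full.bse[0], full.bse[2])),
        r_squared=float(full.rsquared),
        p_interaction=float(full.pvalues[3]),
        lr_chi2=float(lr),
        lr_df=df,
        lr_p=float(sps.chi2.sf(lr, df)),
    )


def subsystem_report(
    ve: Mapping[str, float],
    vp: Mapping[str, float],
    ci_widths: Mapping[str, float],
    subsystem: Mapping[str, str],
) -> pd.DataFrame:
    """Per-subsystem R^2 (weighted fit) and median relative error.

    One row per subsystem plus an overall ``All`` row.  Subsystems with
    fewer than 3 scored entries are reported with NaN R^2 (a two-point
    fit is meaningless) but still get a median relative error; empty
    subsystems are omitted.
    """
    keys = [k for k in ve if k in vp]
    if not keys:
        raise ValidationError("no shared entries to report on")
    rel = relative_errors(vp, ve)

    def one_row(name: str, ks: list[str]) -> dict:
        errs = [rel.errors[k] for k in ks]
        if len(ks) >= 3:
            fit = weighted_fit(
                [ve[k] for k in ks], [vp[k] for k in ks], [ci_widths.get(k, np.nan) for k in ks]
            )
            r2 = fit.r_squared
        else:
            r2 = math.nan
        return {
            "subsystem": name,
            "n": len(ks),
            "r_squared": r2,
            "median_re": float(np.median(errs)),
        }

    groups: dict[str, list[str]] = {}
    for k in keys:
        groups.setdefault(subsystem.get(k, "unassigned"), []).append(k)
    rows = [one_row(name, ks) for name, ks in sorted(groups.items()) if ks]
    rows.append(one_row("All", keys))
    return pd.DataFrame(rows)
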