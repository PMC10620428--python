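"""Heterogeneity, influence and plot-data diagnostics.

Cochran's Q measures dispersion of the per-variant effects around the
fixed-effect IVW slope (one fitted parameter, so k − 1 degrees of
freedom).  Influence diagnostics are leave-one-out IVW estimates and
Cook's distance from the weighted through-origin regression, with the
whole estimator battery re-run on the Cook's-excluded set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import (
    MREstimate,
    instrument_arrays,
    ivw_random_effects,
    mr_egger,
)
from .exceptions import DegenerateInstrumentError, MethodNotApplicableError
from .harmonize import HarmonizedInstrument


@dataclass
class HeterogeneityResult:
    q: float
    df: int
    pval: float


@dataclass
class InfluenceResult:
    loo_estimates: dict = field(default_factory=dict)
    cooks_d: dict = field(default_factory=dict)
    excluded_rsids: list = field(default_factory=list)
    rerun: dict = field(default_factory=dict)


def _fe_slope(bx, by, sy):
    w = 1.0 / sy**2
    return float(np.sum(w * bx * by) / np.sum(w * bx**2))


def cochran_q(instruments: list[HarmonizedInstrument],
              theta: float | None = None) -> HeterogeneityResult:
    """Cochran's Q around the (fixed-effect IVW) slope ``theta``."""
    if len(instruments) < 2:
        raise MethodNotApplicableError(
            "Cochran's Q needs at least 2 instruments")
    bx, _, by, sy = instrument_arrays(instruments)
    if theta is None:
        theta = _fe_slope(bx, by, sy)
    q = float(np.sum((by - theta * bx) ** 2 / sy**2))
    df = len(instruments) - 1
    return HeterogeneityResult(q=q, df=df, pval=float(stats.chi2.sf(q, df)))


def leave_one_out(instruments: list[HarmonizedInstrument]
                  ) -> dict[str, MREstimate]:
    """IVW estimate with each variant removed in turn."""
    if len(instruments) < 3:
        raise MethodNotApplicableError(
            "leave-one-out needs at least 3 instruments")
    out = {}
    for j, ins in enumerate(instruments):
        rest = instruments[:j] + instruments[j + 1:]
        out[ins.rsid] = ivw_random_effects(rest)
    return out


def cooks_distance(instruments: list[HarmonizedInstrument]) -> np.ndarray:
    """Cook's distance from the weighted through-origin IVW fit.

    D_j = r_j² · h_j / (p·(1 − h_j)) with p = 1 parameter, leverage
    h_j = w_j β_Xj² / Σ w β_X² and internally studentized residual r_j.
    """
    bx, _, by, sy = instrument_arrays(instruments)
    k = bx.size
    w = 1.0 / sy**2
    theta = _fe_slope(bx, by, sy)
    h = w * bx**2 / np.sum(w * bx**2)
    e = by - theta * bx
    s2 = np.sum(w * e**2) / (k - 1)
    r2 = w * e**2 / (s2 * (1 - h))
    return r2 * h / (1 - h)


def cooks_outliers(instruments: list[HarmonizedInstrument],
                   threshold: float | None = None,
                   rerun_battery: bool = True,
                   **battery_kwargs) -> InfluenceResult:
    """Flag variants with Cook's distance over the threshold (4/k).

    The full estimator battery is re-run on the surviving set so the
    analysis can be compared before and after exclusion.
    """
    k = len(instruments)
    if k < 4:
        raise MethodNotApplicableError(
            "Cook's-distance screening needs at least 4 instruments")
    if threshold is None:
        threshold = 4.0 / k
    d = cooks_distance(instruments)
    excluded = [ins.rsid for ins, dj in zip(instruments, d)
                if dj > threshold]
    if len(excluded) == k:
        raise DegenerateInstrumentError(
            "every instrument exceeds the Cook's threshold")
    survivors = [ins for ins in instruments if ins.rsid not in excluded]
    rerun = {}
    if rerun_battery:
        from .battery import estimate_all
        rerun = estimate_all(survivors, **battery_kwargs)
    loo = leave_one_out(instruments) if k >= 3 else {}
    return InfluenceResult(
        loo_estimates=loo,
        cooks_d={ins.rsid: float(dj) for ins, dj in zip(instruments, d)},
        excluded_rsids=excluded,
        rerun=rerun,
    )


def plot_data(instruments: list[HarmonizedInstrument],
              estimates: list[MREstimate] | None = None
              ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Underlying tables for scatter and funnel plots.

    Scatter: per-variant (β_X, β_Y, σ_Y) plus one fitted-line record
    per supplied estimate.  Funnel: per-variant ratio estimates against
    their precision, with each method's slope as a reference line.
    """
    bx, _, by, sy = instrument_arrays(instruments)
    scatter = pd.DataFrame({
        "rsid": [i.rsid for i in instruments],
        "beta_exposure": bx,
        "beta_outcome": by,
        "se_outcome": sy,
    })
    ratios = by / bx
    ratio_se = sy / np.abs(bx)
    funnel = pd.DataFrame({
        "rsid": [i.rsid for i in instruments],
        "ratio": ratios,
        "precision": 1.0 / ratio_se,
    })
    if estimates:
        for est in estimates:
            scatter[f"fit_{est.method}"] = est.theta * bx
            funnel[f"ref_{est.method}"] = est.theta
    return scatter, funnel


def funnel_asymmetry_pval(instruments: list[HarmonizedInstrument]) -> float:
    """Egger-intercept p-value as a funnel-asymmetry screen."""
    return mr_egger(instruments).intercept_pval
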