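"""MR-PRESSO: pleiotropy residual sum of squares and outlier test.

Three simulation-based steps: (1) a global test comparing the observed
leave-one-out residual sum of squares against a parametric null; (2)
per-variant outlier detection with Bonferroni-adjusted empirical
p-values and an outlier-corrected IVW estimate; (3) a distortion test
asking whether removing the flagged outliers changed the causal
estimate more than removing random subsets of the same size would.

All empirical p-values use the (1 + exceedances)/(n_sim + 1)
correction so they are never zero; everything is deterministic given
the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .estimators import MREstimate, instrument_arrays, ivw_random_effects
from .exceptions import (
    ConfigurationError,
    DegenerateInstrumentError,
    MethodNotApplicableError,
)
from .harmonize import HarmonizedInstrument


@dataclass
class PressoResult:
    rss_observed: float
    global_pval: float
    outlier_pvals: dict = field(default_factory=dict)
    outlier_rsids: list = field(default_factory=list)
    corrected_estimate: MREstimate | None = None
    distortion_pval: float | None = None


def _loo_slopes(bx, by, sy):
    """Leave-one-out IVW (fixed-effect) slopes, vectorised.

    Works on 1-D arrays (k,) or stacked simulations (n_sim, k); the
    last axis indexes variants.
    """
    w = 1.0 / sy**2
    num = np.sum(w * bx * by, axis=-1, keepdims=True)
    den = np.sum(w * bx**2, axis=-1, keepdims=True)
    return (num - w * bx * by) / (den - w * bx**2)


def _rss_and_residuals(bx, by, sy):
    """Weighted squared LOO residuals and their sum along variants."""
    theta_loo = _loo_slopes(bx, by, sy)
    resid2 = (by - theta_loo * bx) ** 2 / sy**2
    return resid2, np.sum(resid2, axis=-1)


def _simulate_null(bx, sx, by, sy, n_sim, rng):
    theta_loo = _loo_slopes(bx, by, sy)
    k = bx.size
    bx_star = bx + sx * rng.standard_normal((n_sim, k))
    by_star = theta_loo * bx + sy * rng.standard_normal((n_sim, k))
    return _rss_and_residuals(bx_star, by_star, sy)


def _check(instruments, n_sim):
    if len(instruments) < 4:
        raise MethodNotApplicableError(
            f"MR-PRESSO needs at least 4 instruments, got {len(instruments)}")
    if n_sim < 1:
        raise ConfigurationError("n_sim must be a positive integer")


def presso_global(instruments: list[HarmonizedInstrument],
                  n_sim: int = 1000,
                  seed: int | None = None) -> tuple[float, float]:
    """Global horizontal-pleiotropy test.

    Returns the observed residual sum of squares and its Monte-Carlo
    p-value under the no-pleiotropy parametric null.
    """
    _check(instruments, n_sim)
    bx, sx, by, sy = instrument_arrays(instruments)
    rng = np.random.default_rng(seed)
    _, rss_obs = _rss_and_residuals(bx, by, sy)
    _, rss_star = _simulate_null(bx, sx, by, sy, n_sim, rng)
    pval = (1 + np.sum(rss_star >= rss_obs)) / (n_sim + 1)
    return float(rss_obs), float(pval)


def presso_outliers_and_correction(
        instruments: list[HarmonizedInstrument],
        n_sim: int = 1000, seed: int | None = None,
        alpha: float = 0.05) -> tuple[dict, list, MREstimate | None]:
    """Per-variant outlier p-values and the outlier-corrected estimate.

    Each variant's observed weighted squared residual is ranked within
    its own simulated null distribution; p-values are Bonferroni
    multiplied by k.  Flagged variants are removed and IVW re-run on
    the remainder.
    """
    _check(instruments, n_sim)
    bx, sx, by, sy = instrument_arrays(instruments)
    k = bx.size
    rng = np.random.default_rng(seed)
    resid_obs, _ = _rss_and_residuals(bx, by, sy)
    resid_star, _ = _simulate_null(bx, sx, by, sy, n_sim, rng)
    raw = (1 + np.sum(resid_star >= resid_obs, axis=0)) / (n_sim + 1)
    adj = np.minimum(1.0, raw * k)
    pvals = {ins.rsid: float(p) for ins, p in zip(instruments, adj)}
    outliers = [ins.rsid for ins, p in zip(instruments, adj) if p < alpha]
    if len(outliers) == k:
        raise DegenerateInstrumentError(
            "every instrument flagged as an outlier; no corrected estimate")
    corrected = None
    if outliers:
        keep = [ins for ins in instruments if ins.rsid not in outliers]
        corrected = ivw_random_effects(keep, min_snps=1)
    return pvals, outliers, corrected


def presso_distortion(full_estimate: MREstimate,
                      corrected_estimate: MREstimate,
                      instruments: list[HarmonizedInstrument],
                      outliers: list[str],
                      n_sim: int = 1000,
                      seed: int | None = None) -> float | None:
    """Distortion test: did outlier removal change the estimate?

    The observed distortion (θ_corrected − θ_full)/|θ_full| is compared
    two-sidedly against distortions from removing random same-size
    subsets of the non-flagged variants (the expected fluctuation when
    discarding ordinary instruments).  Returns None when there are no
    outliers (the test is not applicable, not an error).
    """
    if not outliers:
        return None
    _check(instruments, n_sim)
    m = len(outliers)
    pool = [j for j, ins in enumerate(instruments)
            if ins.rsid not in outliers]
    if len(pool) < max(m, 1) + 1:
        raise DegenerateInstrumentError(
            "too few non-outlier instruments for the distortion null")
    d_obs = (corrected_estimate.theta - full_estimate.theta) \
        / abs(full_estimate.theta)
    rng = np.random.default_rng(seed)
    d_null = np.empty(n_sim)
    for b in range(n_sim):
        drop = set(rng.choice(pool, size=m, replace=False))
        keep = [ins for j, ins in enumerate(instruments) if j not in drop]
        theta_b = ivw_random_effects(keep, min_snps=1).theta
        d_null[b] = (theta_b - full_estimate.theta) / abs(full_estimate.theta)
    pval = (1 + np.sum(np.abs(d_null) >= abs(d_obs))) / (n_sim + 1)
    return float(pval)


def mr_presso(instruments: list[HarmonizedInstrument],
              n_sim: int = 1000, seed: int | None = None,
              alpha: float = 0.05) -> PressoResult:
    """Run all three steps and assemble a single result record."""
    rss_obs, global_p = presso_global(instruments, n_sim=n_sim, seed=seed)
    pvals, outliers, corrected = presso_outliers_and_correction(
        instruments, n_sim=n_sim, seed=seed, alpha=alpha)
    distortion = None
    if outliers:
        full = ivw_random_effects(instruments)
        distortion = presso_distortion(
            full, corrected, instruments, outliers, n_sim=n_sim, seed=seed)
    return PressoResult(
        rss_observed=rss_obs, global_pval=global_p, outlier_pvals=pvals,
        outlier_rsids=outliers, corrected_estimate=corrected,
        distortion_pval=distortion)
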