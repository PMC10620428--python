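"""Two-sample MR causal estimators.

Every estimator regresses per-variant outcome effects β_Yj on exposure
effects β_Xj and is exposed in two equivalent forms:

* scikit-learn style classes (``fit`` / ``predict`` / ``get_params``)
  whose X is the vector of exposure betas, y the outcome betas, and the
  per-variant standard errors are passed to ``fit`` like sample
  weights.  Fitted attributes carry a trailing underscore (``theta_``,
  ``se_``, ``ci_low_``, ``ci_high_``, ``pval_``).
* thin module-level functions operating on ``HarmonizedInstrument``
  collections and returning :class:`MREstimate` records, which is what
  the pipeline consumes.

Methods implemented: single-instrument Wald ratio; inverse-variance
weighted (IVW) with multiplicative random effects; weighted median;
weighted mode; MR-Egger regression (slope + average-pleiotropy
intercept); and the robust adjusted profile score (RAPS) with an
overdispersion parameter and a choice of l2 or Huber loss.

Conventions shared by all methods: weights are first-order
(1/σ_Yj² for regression-style estimators, 1/se(β_Yj/β_Xj)² for
ratio-based ones, ignoring σ_Xj except in RAPS); confidence intervals
are normal 95% (±1.96·SE); the reporting transform to an odds ratio per
unit biomarker decrease is exp(−θ).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin

from .exceptions import (
    ConvergenceError,
    DegenerateInstrumentError,
    MethodNotApplicableError,
)
from .harmonize import Z95, HarmonizedInstrument, to_or_per_unit_decrease

HUBER_C = 1.345  # tuning constant: 95% efficiency at the normal


@dataclass
class MREstimate:
    """One method's causal estimate on the log scale plus the OR view."""

    method: str
    theta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_snps: int
    or_per_decrease: float
    or_ci_low: float
    or_ci_high: float

    @classmethod
    def from_theta(cls, method: str, theta: float, se: float,
                   n_snps: int) -> "MREstimate":
        ci_low, ci_high = theta - Z95 * se, theta + Z95 * se
        z = theta / se if se > 0 else math.inf * np.sign(theta)
        pval = 2 * stats.norm.sf(abs(z)) if se > 0 else 0.0
        orr, olo, ohi = to_or_per_unit_decrease(theta, se, ci_low, ci_high)
        return cls(method=method, theta=theta, se=se, ci_low=ci_low,
                   ci_high=ci_high, pval=float(pval), n_snps=n_snps,
                   or_per_decrease=orr, or_ci_low=olo, or_ci_high=ohi)


@dataclass
class EggerResult:
    """Egger slope plus the intercept-based average-pleiotropy test."""

    slope: MREstimate
    intercept: float
    intercept_se: float
    intercept_pval: float


@dataclass
class RapsResult:
    estimate: MREstimate
    tau2: float
    loss: str


# ---------------------------------------------------------------------------
# array plumbing

def instrument_arrays(instruments: list[HarmonizedInstrument]):
    """(β_X, σ_X, β_Y, σ_Y) arrays from a harmonized collection."""
    bx = np.array([i.beta_exposure for i in instruments], dtype=float)
    sx = np.array([i.se_exposure for i in instruments], dtype=float)
    by = np.array([i.beta_outcome for i in instruments], dtype=float)
    sy = np.array([i.se_outcome for i in instruments], dtype=float)
    return bx, sx, by, sy


def _validate_fit_inputs(X, y, se_exposure, se_outcome, min_snps, method):
    bx = np.asarray(X, dtype=float).reshape(-1)
    by = np.asarray(y, dtype=float).reshape(-1)
    if bx.shape != by.shape:
        raise ValueError("X and y must have the same length")
    k = bx.size
    if k < min_snps:
        raise MethodNotApplicableError(
            f"{method} needs at least {min_snps} instruments, got {k}"
            + (": use the Wald ratio" if min_snps == 2 else ""))
    sy = np.asarray(se_outcome, dtype=float).reshape(-1)
    if sy.shape != by.shape or np.any(sy <= 0) or not np.all(np.isfinite(sy)):
        raise ValueError("se_outcome must be positive, finite, length k")
    if se_exposure is None:
        sx = np.zeros(k)
    else:
        sx = np.asarray(se_exposure, dtype=float).reshape(-1)
        if sx.shape != by.shape or np.any(sx < 0):
            raise ValueError("se_exposure must be non-negative, length k")
    if not (np.all(np.isfinite(bx)) and np.all(np.isfinite(by))):
        raise ValueError("betas must be finite")
    return bx, sx, by, sy


class _BaseMREstimator(RegressorMixin, BaseEstimator):
    """Shared scaffolding: validation, CI/p attributes, predict."""

    _method = "base"
    _min_snps = 2

    def _finalize(self, theta, se, k):
        self.theta_ = float(theta)
        self.se_ = float(se)
        self.ci_low_ = self.theta_ - Z95 * self.se_
        self.ci_high_ = self.theta_ + Z95 * self.se_
        self.pval_ = float(2 * stats.norm.sf(abs(self.theta_ / self.se_))) \
            if self.se_ > 0 else 0.0
        self.n_snps_ = int(k)
        return self

    def predict(self, X):
        x = np.asarray(X, dtype=float).reshape(-1)
        return getattr(self, "intercept_", 0.0) + self.theta_ * x

    def to_estimate(self) -> MREstimate:
        est = MREstimate.from_theta(self._method, self.theta_, self.se_,
                                    self.n_snps_)
        return est


class WaldRatio(_BaseMREstimator):
    """Single-instrument causal estimate β_Y/β_X.

    The SE is first-order delta method, σ_Y/|β_X| (exposure uncertainty
    ignored, as is standard for strong instruments).
    """

    _method = "wald"
    _min_snps = 1

    def fit(self, X, y, se_exposure=None, se_outcome=None):
        bx, sx, by, sy = _validate_fit_inputs(
            X, y, se_exposure, se_outcome, 1, "wald_ratio")
        if bx.size != 1:
            raise MethodNotApplicableError(
                "the Wald ratio is defined for a single instrument")
        if bx[0] == 0:
            raise DegenerateInstrumentError(
                "zero exposure effect: Wald ratio undefined")
        return self._finalize(by[0] / bx[0], sy[0] / abs(bx[0]), 1)


class IVWEstimator(_BaseMREstimator):
    """Inverse-variance weighted estimate, multiplicative random effects.

    Weighted regression of β_Y on β_X through the origin with weights
    1/σ_Y².  Under heterogeneity the fixed-effect SE is inflated by
    sqrt(Q/(k−1)), floored at 1 so the SE never drops below the
    fixed-effect value.

    Parameters
    ----------
    random_effects : bool
        Apply the multiplicative inflation (default True).
    min_snps : int
        Guard against too few instruments; 2 by default, may be set to
        1 in which case the estimate reduces exactly to the Wald ratio.
    """

    _method = "ivw_re"

    def __init__(self, random_effects: bool = True, min_snps: int = 2):
        self.random_effects = random_effects
        self.min_snps = min_snps

    def fit(self, X, y, se_exposure=None, se_outcome=None):
        bx, sx, by, sy = _validate_fit_inputs(
            X, y, se_exposure, se_outcome, self.min_snps,
            "ivw_random_effects")
        k = bx.size
        w = 1.0 / sy**2
        denom = np.sum(w * bx**2)
        theta = np.sum(w * bx * by) / denom
        se_fe = denom**-0.5
        q = float(np.sum(w * (by - theta * bx) ** 2))
        self.q_ = q
        self.inflation_ = max(1.0, math.sqrt(q / (k - 1))) if k >= 2 else 1.0
        se = se_fe * (self.inflation_ if self.random_effects else 1.0)
        self.se_fixed_ = se_fe
        return self._finalize(theta, se, k)


class WeightedMedian(_BaseMREstimator):
    """Weighted median of per-variant ratio estimates.

    Consistent when instruments carrying at least half the weight are
    valid.  Point estimate by weighted-percentile interpolation at 50%;
    SE by parametric bootstrap (betas resampled at their SEs).  Ratio
    weights are first-order delta method (exposure uncertainty
    ignored) unless ``second_order_weights`` is set, which adds the
    β_Y²σ_X²/β_X⁴ term.
    """

    _method = "weighted_median"
    _min_snps = 3

    def __init__(self, n_boot: int = 1000,
                 second_order_weights: bool = False,
                 random_state: int | None = None):
        self.n_boot = n_boot
        self.second_order_weights = second_order_weights
        self.random_state = random_state

    @staticmethod
    def _point(bx, by, sy, sx=None):
        ratios = by / bx
        if sx is None:
            w = (bx / sy) ** 2  # 1 / se(ratio)^2, first-order
        else:
            w = 1.0 / (sy**2 / bx**2 + by**2 * sx**2 / bx**4)
        order = np.argsort(ratios)
        r, w = ratios[order], w[order]
        s = np.cumsum(w)
        p = (s - w / 2) / s[-1]
        if p[0] >= 0.5:
            return float(r[0])
        if p[-1] <= 0.5:
            return float(r[-1])
        return float(np.interp(0.5, p, r))

    def fit(self, X, y, se_exposure=None, se_outcome=None):
        bx, sx, by, sy = _validate_fit_inputs(
            X, y, se_exposure, se_outcome, 3, "weighted_median")
        sx_w = sx if self.second_order_weights else None

        def point(bx_, by_, sy_):
            return self._point(bx_, by_, sy_, sx=sx_w)

        theta = point(bx, by, sy)
        se = _bootstrap_se(point, bx, sx, by, sy,
                           self.n_boot, self.random_state)
        return self._finalize(theta, se, bx.size)


class WeightedMode(_BaseMREstimator):
    """Mode of the weighted kernel density over ratio estimates.

    Consistent when the largest weight-homogeneous group of instruments
    is valid (zero modal pleiotropy).  Bandwidth is ``phi`` times a
    robust Silverman-type rule built on the median absolute deviation;
    the mode is located on a 512-point grid spanning the ratio range
    plus three bandwidths.  SE by parametric bootstrap.
    """

    _method = "weighted_mode"
    _min_snps = 3

    def __init__(self, phi: float = 1.0, n_boot: int = 1000,
                 grid_size: int = 512, random_state: int | None = None):
        self.phi = phi
        self.n_boot = n_boot
        self.grid_size = grid_size
        self.random_state = random_state

    def _point(self, bx, by, sy):
        ratios = by / bx
        w = (bx / sy) ** 2
        mad = np.median(np.abs(ratios - np.median(ratios))) / 0.6744897501
        spread = mad if mad > 0 else np.std(ratios)
        if spread == 0:  # all ratios identical: point mass
            return float(ratios[0])
        h = self.phi * 0.9 * spread * ratios.size ** (-1 / 5)
        grid = np.linspace(ratios.min() - 3 * h, ratios.max() + 3 * h,
                           self.grid_size)
        dens = np.exp(-0.5 * ((grid[:, None] - ratios[None, :]) / h) ** 2)
        f = dens @ w
        return float(grid[np.argmax(f)])

    def fit(self, X, y, se_exposure=None, se_outcome=None):
        bx, sx, by, sy = _validate_fit_inputs(
            X, y, se_exposure, se_outcome, 3, "weighted_mode")
        theta = self._point(bx, by, sy)
        se = _bootstrap_se(self._point, bx, sx, by, sy,
                           self.n_boot, self.random_state)
        return self._finalize(theta, se, bx.size)


def _bootstrap_se(point_fn, bx, sx, by, sy, n_boot, random_state):
    """Parametric bootstrap: betas resampled at their stated SEs."""
    rng = np.random.default_rng(random_state)
    k = bx.size
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bxb = bx + sx * rng.standard_normal(k)
        byb = by + sy * rng.standard_normal(k)
        bxb = np.where(bxb == 0, 1e-300, bxb)
        boots[b] = point_fn(bxb, byb, sy)
    return float(np.std(boots, ddof=1))


class EggerRegression(_BaseMREstimator):
    """MR-Egger: weighted regression of β_Y on β_X with an intercept.

    Under the InSIDE assumption the intercept estimates the average
    direct (pleiotropic) effect and its two-sided p-value is the
    pleiotropy test; the slope is the pleiotropy-adjusted causal
    estimate.  Instruments are oriented exposure-increasing internally
    (the fit is not invariant to per-variant sign flips).  Both SEs are
    inflated by the residual scale, floored at 1.
    """

    _method = "egger"
    _min_snps = 3

    def fit(self, X, y, se_exposure=None, se_outcome=None):
        bx, sx, by, sy = _validate_fit_inputs(
            X, y, se_exposure, se_outcome, 3, "mr_egger")
        flip = np.sign(bx)
        flip[flip == 0] = 1.0
        bx, by = bx * flip, by * flip
        k = bx.size
        w = 1.0 / sy**2
        xmat = np.column_stack([np.ones(k), bx])
        xtw = xmat.T * w
        try:
            cov_fe = np.linalg.inv(xtw @ xmat)
        except np.linalg.LinAlgError:
            raise DegenerateInstrumentError(
                "exposure effects have no spread: Egger design is "
                "collinear") from None
        coef = cov_fe @ (xtw @ by)
        resid = by - xmat @ coef
        scale2 = float(np.sum(w * resid**2) / (k - 2)) if k > 2 else 1.0
        self.scale_ = max(1.0, math.sqrt(scale2))
        ses = np.sqrt(np.diag(cov_fe)) * self.scale_
        self.intercept_ = float(coef[0])
        self.intercept_se_ = float(ses[0])
        self.intercept_pval_ = float(
            2 * stats.norm.sf(abs(self.intercept_ / self.intercept_se_)))
        return self._finalize(coef[1], ses[1], k)

    def to_result(self) -> EggerResult:
        return EggerResult(
            slope=self.to_estimate(),
            intercept=self.intercept_,
            intercept_se=self.intercept_se_,
            intercept_pval=self.intercept_pval_,
        )


class RAPSEstimator(_BaseMREstimator):
    """Robust adjusted profile score with overdispersion.

    Solves the profile estimating equations in (θ, τ²) for the model
    β_Yj ~ N(θ·β_Xj + α_j, σ_Yj²) with systematic pleiotropy
    α_j ~ N(0, τ²) and exposure effects measured with error σ_Xj:
    standardized residuals t_j = (β_Yj − θβ_Xj)/√(σ_Yj² + θ²σ_Xj² + τ²)
    enter through the loss's influence function ψ (identity for l2,
    clipped at 1.345 for Huber), making the fit tolerant of weak
    instruments and idiosyncratic outliers.  SE by the sandwich formula;
    ``random_state`` only perturbs the multi-start initialisation.
    """

    _method = "raps"
    _min_snps = 3

    def __init__(self, loss: str = "huber", huber_c: float = HUBER_C,
                 random_state: int | None = None):
        self.loss = loss
        self.huber_c = huber_c
        self.random_state = random_state

    def _psi(self, t):
        if self.loss == "l2":
            return t
        return np.clip(t, -self.huber_c, self.huber_c)

    def _delta(self):
        # E[psi(Z) Z] for Z ~ N(0,1): 1 for l2, 2*Phi(c)-1 for Huber
        if self.loss == "l2":
            return 1.0
        return float(2 * stats.norm.cdf(self.huber_c) - 1)

    def _score_theta(self, theta, tau2, bx, sx, by, sy):
        s2 = sy**2 + theta**2 * sx**2 + tau2
        s = np.sqrt(s2)
        t = (by - theta * bx) / s
        dt = bx / s + t * theta * sx**2 / s2  # = -∂t/∂θ
        return float(np.sum(self._psi(t) * dt))

    def _moment_tau(self, tau2, theta, bx, sx, by, sy):
        s2 = sy**2 + theta**2 * sx**2 + tau2
        t = (by - theta * bx) / np.sqrt(s2)
        return float(np.sum((self._psi(t) * t - self._delta()) / s2))

    def _solve_tau(self, theta, bx, sx, by, sy):
        if self._moment_tau(0.0, theta, bx, sx, by, sy) <= 0:
            return 0.0
        hi = float(np.max(sy**2))
        while self._moment_tau(hi, theta, bx, sx, by, sy) > 0:
            hi *= 4
            if hi > 1e12:
                raise ConvergenceError("overdispersion moment has no root")
        return float(optimize.brentq(
            self._moment_tau, 0.0, hi, args=(theta, bx, sx, by, sy),
            xtol=1e-14))

    def _solve_theta(self, theta0, tau2, bx, sx, by, sy):
        span = 1.0 + abs(theta0)
        for _ in range(60):
            lo, hi = theta0 - span, theta0 + span
            flo = self._score_theta(lo, tau2, bx, sx, by, sy)
            fhi = self._score_theta(hi, tau2, bx, sx, by, sy)
            if flo == 0.0:
                return lo
            if fhi == 0.0:
                return hi
            if flo * fhi < 0:
                return float(optimize.brentq(
                    self._score_theta, lo, hi,
                    args=(tau2, bx, sx, by, sy), xtol=1e-13))
            span *= 2
        raise ConvergenceError("profile score has no bracketed root")

    def fit(self, X, y, se_exposure=None, se_outcome=None):
        bx, sx, by, sy = _validate_fit_inputs(
            X, y, se_exposure, se_outcome, 3, "mr_raps")
        if se_exposure is None:
            sx = np.zeros_like(bx)
        k = bx.size
        rng = np.random.default_rng(self.random_state)
        ivw0 = float(np.sum(bx * by / sy**2) / np.sum(bx**2 / sy**2))
        starts = [ivw0, 0.0] + [
            ivw0 + (1 + abs(ivw0)) * rng.standard_normal() for _ in range(4)]
        last_err = None
        for theta in starts:
            try:
                tau2 = 0.0
                for _ in range(200):
                    theta_new = self._solve_theta(theta, tau2, bx, sx, by, sy)
                    tau2_new = self._solve_tau(theta_new, bx, sx, by, sy)
                    if (abs(theta_new - theta) < 1e-12
                            and abs(tau2_new - tau2) < 1e-12):
                        theta, tau2 = theta_new, tau2_new
                        break
                    theta, tau2 = theta_new, tau2_new
                else:
                    raise ConvergenceError(
                        "theta/tau2 alternation did not converge")
                break
            except ConvergenceError as e:
                last_err = e
        else:
            raise ConvergenceError(
                f"MR-RAPS failed from all starts: {last_err}")
        self.tau2_ = float(tau2)
        se = self._sandwich_se(theta, tau2, bx, sx, by, sy)
        return self._finalize(theta, se, k)

    def _per_unit_scores(self, theta, tau2, bx, sx, by, sy):
        s2 = sy**2 + theta**2 * sx**2 + tau2
        s = np.sqrt(s2)
        t = (by - theta * bx) / s
        g1 = self._psi(t) * (bx / s + t * theta * sx**2 / s2)
        g2 = (self._psi(t) * t - self._delta()) / s2
        return g1, g2

    def _sandwich_se(self, theta, tau2, bx, sx, by, sy):
        # HC1-style small-sample correction k/(k - p) on the meat
        g1, g2 = self._per_unit_scores(theta, tau2, bx, sx, by, sy)
        interior = tau2 > 0
        k = bx.size
        hc1 = k / (k - 2) if interior else k / (k - 1)
        h_t = 1e-6 * (1 + abs(theta))
        h_v = 1e-6 * (1 + tau2)

        def total(th, tv):
            a, b = self._per_unit_scores(th, tv, bx, sx, by, sy)
            return np.array([a.sum(), b.sum()])

        if interior:
            col_t = (total(theta + h_t, tau2) - total(theta - h_t, tau2)) \
                / (2 * h_t)
            col_v = (total(theta, tau2 + h_v) - total(theta, tau2 - h_v)) \
                / (2 * h_v)
            a_mat = np.column_stack([col_t, col_v])
            g = np.column_stack([g1, g2])
            b_mat = hc1 * (g.T @ g)
            try:
                a_inv = np.linalg.inv(a_mat)
                v = a_inv @ b_mat @ a_inv.T
                return float(np.sqrt(max(v[0, 0], 0.0)))
            except np.linalg.LinAlgError:
                pass
        # boundary (tau2 = 0) or singular: 1-D sandwich in theta
        a11 = (total(theta + h_t, tau2)[0]
               - total(theta - h_t, tau2)[0]) / (2 * h_t)
        return float(np.sqrt(hc1 * np.sum(g1**2)) / abs(a11))

    def to_result(self) -> RapsResult:
        return RapsResult(estimate=self.to_estimate(), tau2=self.tau2_,
                          loss=self.loss)


# ---------------------------------------------------------------------------
# instrument-collection wrappers

def wald_ratio(instrument: HarmonizedInstrument) -> MREstimate:
    est = WaldRatio().fit([instrument.beta_exposure],
                          [instrument.beta_outcome],
                          se_exposure=[instrument.se_exposure],
                          se_outcome=[instrument.se_outcome])
    return est.to_estimate()


def ivw_random_effects(instruments: list[HarmonizedInstrument],
                       min_snps: int = 2) -> MREstimate:
    bx, sx, by, sy = instrument_arrays(instruments)
    est = IVWEstimator(min_snps=min_snps).fit(
        bx, by, se_exposure=sx, se_outcome=sy)
    return est.to_estimate()


def weighted_median(instruments: list[HarmonizedInstrument],
                    n_boot: int = 1000,
                    seed: int | None = None) -> MREstimate:
    bx, sx, by, sy = instrument_arrays(instruments)
    est = WeightedMedian(n_boot=n_boot, random_state=seed).fit(
        bx, by, se_exposure=sx, se_outcome=sy)
    return est.to_estimate()


def weighted_mode(instruments: list[HarmonizedInstrument],
                  phi: float = 1.0, n_boot: int = 1000,
                  seed: int | None = None) -> MREstimate:
    bx, sx, by, sy = instrument_arrays(instruments)
    est = WeightedMode(phi=phi, n_boot=n_boot, random_state=seed).fit(
        bx, by, se_exposure=sx, se_outcome=sy)
    return est.to_estimate()


def mr_egger(instruments: list[HarmonizedInstrument]) -> EggerResult:
    bx, sx, by, sy = instrument_arrays(instruments)
    est = EggerRegression().fit(bx, by, se_exposure=sx, se_outcome=sy)
    return est.to_result()


def mr_raps(instruments: list[HarmonizedInstrument], loss: str = "huber",
            seed: int | None = None) -> RapsResult:
    bx, sx, by, sy = instrument_arrays(instruments)
    est = RAPSEstimator(loss=loss, random_state=seed).fit(
        bx, by, se_exposure=sx, se_outcome=sy)
    return est.to_result()
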