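import math

import numpy as np
import pytest
from sklearn.base import clone

from dtmr.estimators import (
    EggerRegression,
    IVWEstimator,
    RAPSEstimator,
    WaldRatio,
    WeightedMedian,
    WeightedMode,
    ivw_random_effects,
    mr_egger,
    mr_raps,
    wald_ratio,
    weighted_median,
    weighted_mode,
)
from dtmr.exceptions import (
    DegenerateInstrumentError,
    MethodNotApplicableError,
)
from helpers import make_instruments, simulate_instruments


def random_instance(rng, k=None):
    k = k or rng.integers(3, 11)
    bx = rng.uniform(0.02, 0.2, k) * rng.choice([-1, 1], k)
    sy = rng.uniform(0.01, 0.08, k)
    by = 0.4 * bx + rng.normal(0, sy)
    return bx, by, sy


class TestWaldRatio:
    @pytest.mark.parametrize("bx, by, sy, theta, se", [
        (1.0, 0.5, 0.1, 0.5, 0.1),
        (-1.0, 0.5, 0.1, -0.5, 0.1),
        (0.5, 0.25, 0.05, 0.5, 0.1),
    ])
    def test_ratio_and_delta_se(self, bx, by, sy, theta, se):
        ins, = make_instruments([bx], [by], sy)
        est = wald_ratio(ins)
        assert est.theta == pytest.approx(theta)
        assert est.se == pytest.approx(se)
        assert est.n_snps == 1

    def test_single_variant_proxy_reporting_scale(self):
        """A strongly protective-looking single variant: with
        beta_Y/beta_X = -3.537 the OR per unit biomarker decrease is
        exp(3.537) = 34.4 with a wide CI — the arithmetic of the
        single-SNP drug-proxy analysis."""
        ins, = make_instruments([0.02], [-0.07074], 0.0292)
        est = wald_ratio(ins)
        assert est.theta == pytest.approx(-3.537)
        assert est.or_per_decrease == pytest.approx(34.37, abs=0.05)
        assert est.or_ci_low < 2.1 and est.or_ci_high > 500

    def test_zero_exposure_effect_degenerate(self):
        with pytest.raises(DegenerateInstrumentError):
            WaldRatio().fit([0.0], [0.1], se_outcome=[0.1])


class TestIVW:
    def test_hand_worked_triple(self, toy_triple):
        est = ivw_random_effects(toy_triple)
        assert est.theta == pytest.approx(0.5)
        assert est.se == pytest.approx(0.1 / math.sqrt(3), rel=1e-6)

    def test_q_at_inflation_boundary(self, toy_triple):
        fit = IVWEstimator().fit(
            [1, 1, 1], [0.4, 0.5, 0.6], se_outcome=[0.1, 0.1, 0.1])
        assert fit.q_ == pytest.approx(2.0)
        assert fit.inflation_ == 1.0  # sqrt(2/2) = 1, floored at 1

    def test_reduces_to_wald_with_guard_off(self):
        ins, = make_instruments([0.08], [0.05], 0.02)
        fit = IVWEstimator(min_snps=1).fit([0.08], [0.05],
                                           se_outcome=[0.02])
        assert fit.theta_ == pytest.approx(wald_ratio(ins).theta)
        assert fit.se_ == pytest.approx(wald_ratio(ins).se)

    def test_single_instrument_directs_to_wald(self):
        with pytest.raises(MethodNotApplicableError, match="Wald"):
            ivw_random_effects(make_instruments([0.1], [0.05], 0.02))

    def test_matches_wls_oracle_on_random_instances(self):
        """Weighted least squares through the origin, via statsmodels."""
        import statsmodels.api as sm
        rng = np.random.default_rng(42)
        for _ in range(200):
            bx, by, sy = random_instance(rng)
            fit = IVWEstimator().fit(bx, by, se_outcome=sy)
            wls = sm.WLS(by, bx, weights=1.0 / sy**2).fit()
            assert abs(fit.theta_ - wls.params[0]) < 1e-10

    def test_random_effects_never_deflates_se(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            bx, by, sy = random_instance(rng)
            re = IVWEstimator().fit(bx, by, se_outcome=sy)
            fe = IVWEstimator(random_effects=False).fit(bx, by,
                                                        se_outcome=sy)
            assert re.se_ >= fe.se_ - 1e-15


class TestWeightedMedian:
    def test_interpolation_gives_middle_ratio(self):
        ins = make_instruments([1.0, 1.0, 1.0], [0.1, 0.2, 0.3], 0.1)
        est = weighted_median(ins, n_boot=100, seed=0)
        assert est.theta == pytest.approx(0.2)

    def test_identical_ratios_degenerate(self):
        ins = make_instruments([0.1, 0.2, 0.3], [0.05, 0.10, 0.15], 0.01)
        est = weighted_median(ins, n_boot=200, seed=0)
        assert est.theta == pytest.approx(0.5)
        assert 0 < est.se < 0.2  # bootstrap spread consistent with noise

    def test_weight_shifts_percentile(self):
        # one very precise variant dominates the weight
        ins = make_instruments([1.0, 1.0, 1.0], [0.1, 0.2, 0.9],
                               [0.5, 0.5, 0.01])
        est = weighted_median(ins, n_boot=50, seed=0)
        assert est.theta > 0.5

    def test_needs_three(self):
        with pytest.raises(MethodNotApplicableError):
            weighted_median(make_instruments([1, 1], [0.1, 0.2], 0.1))

    def test_second_order_weights_account_for_exposure_noise(self):
        bx = np.array([0.05, 0.10, 0.15, 0.20])
        by = np.array([0.02, 0.05, 0.09, 0.30])
        sy = np.full(4, 0.02)
        sx = np.full(4, 0.04)  # exposure noise comparable to effects
        first = WeightedMedian(n_boot=10, random_state=0).fit(
            bx, by, se_exposure=sx, se_outcome=sy)
        second = WeightedMedian(n_boot=10, second_order_weights=True,
                                random_state=0).fit(
            bx, by, se_exposure=sx, se_outcome=sy)
        assert first.theta_ != second.theta_
        # with negligible exposure noise the two weightings agree
        tiny = np.full(4, 1e-9)
        a = WeightedMedian(n_boot=10, random_state=0).fit(
            bx, by, se_exposure=tiny, se_outcome=sy).theta_
        b = WeightedMedian(n_boot=10, second_order_weights=True,
                           random_state=0).fit(
            bx, by, se_exposure=tiny, se_outcome=sy).theta_
        assert a == pytest.approx(b, rel=1e-9)


class TestWeightedMode:
    def test_point_mass(self):
        ins = make_instruments([0.1, 0.2, 0.4], [0.07, 0.14, 0.28], 0.01)
        est = weighted_mode(ins, n_boot=100, seed=0)
        assert est.theta == pytest.approx(0.7)

    def test_downweighted_outlier_ignored(self):
        rng = np.random.default_rng(5)
        ratios = np.concatenate([0.5 + 0.02 * rng.standard_normal(9), [5.0]])
        bx = np.full(10, 0.1)
        sy = np.concatenate([np.full(9, 0.01), [0.05]])
        ins = make_instruments(bx, ratios * bx, sy)
        est = weighted_mode(ins, n_boot=100, seed=0)
        assert 0.4 < est.theta < 0.6

    def test_phi_scales_bandwidth(self):
        rng = np.random.default_rng(8)
        bx = rng.uniform(0.05, 0.15, 12)
        by = 0.5 * bx + rng.normal(0, 0.02, 12)
        ins = make_instruments(bx, by, 0.02)
        wide = weighted_mode(ins, phi=5.0, n_boot=50, seed=0).theta
        narrow = weighted_mode(ins, phi=0.2, n_boot=50, seed=0).theta
        assert wide != narrow  # bandwidth genuinely enters


class TestEgger:
    def test_exact_line_recovered(self):
        bx = np.array([0.05, 0.08, 0.11, 0.15])
        by = 0.1 + 0.5 * bx
        ins = make_instruments(bx, by, 0.02)
        res = mr_egger(ins)
        assert res.slope.theta == pytest.approx(0.5, abs=1e-10)
        assert res.intercept == pytest.approx(0.1, abs=1e-10)

    def test_matches_wls_oracle_with_intercept(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(11)
        for _ in range(200):
            bx, by, sy = random_instance(rng)
            bx = np.abs(bx)  # oriented
            fit = EggerRegression().fit(bx, by, se_outcome=sy)
            wls = sm.WLS(by, sm.add_constant(bx), weights=1.0 / sy**2).fit()
            assert abs(fit.theta_ - wls.params[1]) < 1e-10
            assert abs(fit.intercept_ - wls.params[0]) < 1e-10

    def test_intercept_calibrated_under_inside(self):
        """Balanced pleiotropy satisfies InSIDE: the intercept test
        should reject at close to its nominal 5% level."""
        rej = 0
        n = 2000
        for s in range(n):
            ins, _ = simulate_instruments(
                s, theta_true=0.3, pleiotropy="balanced",
                pleiotropy_scale=0.02)
            rej += mr_egger(ins).intercept_pval < 0.05
        assert 0.03 <= rej / n <= 0.07

    def test_directional_pleiotropy_recovered_in_ci(self):
        hits = 0
        n = 400
        for s in range(n):
            ins, _ = simulate_instruments(
                s, theta_true=0.3, pleiotropy="directional",
                pleiotropy_scale=0.1)
            res = mr_egger(ins)
            lo = res.intercept - 1.96 * res.intercept_se
            hi = res.intercept + 1.96 * res.intercept_se
            hits += lo <= 0.1 <= hi
        assert hits / n >= 0.90


class TestRAPS:
    def test_l2_no_exposure_error_equals_fixed_effect_ivw(self):
        rng = np.random.default_rng(3)
        bx = rng.uniform(0.05, 0.15, 10)
        sy = np.full(10, 0.04)
        by = 0.5 * bx + rng.normal(0, 0.04, 10)
        fit = RAPSEstimator(loss="l2", random_state=0).fit(
            bx, by, se_outcome=sy)
        ivw = IVWEstimator(random_effects=False).fit(bx, by, se_outcome=sy)
        assert abs(fit.theta_ - ivw.theta_) < 1e-6

    def test_null_coverage(self):
        hits = 0
        n = 1000
        for s in range(n):
            ins, _ = simulate_instruments(s, theta_true=0.0)
            res = mr_raps(ins, seed=s)
            hits += res.estimate.ci_low <= 0.0 <= res.estimate.ci_high
        assert hits / n >= 0.93

    def test_overdispersion_nonnegative_and_detected(self):
        ins, _ = simulate_instruments(
            2, theta_true=0.5, pleiotropy="balanced", pleiotropy_scale=0.08)
        res = mr_raps(ins, seed=0)
        assert res.tau2 > 0

    def test_huber_resists_single_outlier(self):
        rng = np.random.default_rng(9)
        bx = rng.uniform(0.05, 0.15, 15)
        sy = np.full(15, 0.02)
        by = 0.5 * bx + rng.normal(0, 0.02, 15)
        by[0] += 0.5  # gross outlier
        ins = make_instruments(bx, by, sy)
        hub = mr_raps(ins, loss="huber", seed=0).estimate.theta
        l2 = mr_raps(ins, loss="l2", seed=0).estimate.theta
        assert abs(hub - 0.5) < abs(l2 - 0.5)

    def test_deterministic_given_seed(self):
        ins, _ = simulate_instruments(4, theta_true=0.4)
        a = mr_raps(ins, seed=7)
        b = mr_raps(ins, seed=7)
        assert a.estimate.theta == b.estimate.theta
        assert a.estimate.se == b.estimate.se


class TestSharedContracts:
    def test_scale_equivariance(self):
        """Multiplying all beta_X and sigma_X by c divides theta by c."""
        rng = np.random.default_rng(13)
        bx = rng.uniform(0.05, 0.15, 8)
        sx = np.full(8, 0.005)
        sy = np.full(8, 0.03)
        by = 0.5 * bx + rng.normal(0, 0.03, 8)
        c = 3.7
        for make in (
            lambda x, s: IVWEstimator().fit(x, by, se_exposure=s,
                                            se_outcome=sy),
            lambda x, s: EggerRegression().fit(x, by, se_exposure=s,
                                               se_outcome=sy),
            lambda x, s: WeightedMedian(n_boot=10, random_state=0).fit(
                x, by, se_exposure=s, se_outcome=sy),
            lambda x, s: RAPSEstimator(random_state=0).fit(
                x, by, se_exposure=s, se_outcome=sy),
        ):
            base = make(bx, sx).theta_
            scaled = make(c * bx, c * sx).theta_
            assert scaled == pytest.approx(base / c, rel=1e-6)

    def test_sklearn_params_round_trip_and_clone(self):
        est = WeightedMode(phi=2.0, n_boot=77, random_state=5)
        params = est.get_params()
        assert params["phi"] == 2.0 and params["n_boot"] == 77
        cloned = clone(est)
        assert cloned.get_params() == params
        est.set_params(phi=1.5)
        assert est.phi == 1.5

    def test_predict_returns_fitted_line(self, toy_triple):
        fit = IVWEstimator().fit([1, 1, 1], [0.4, 0.5, 0.6],
                                 se_outcome=[0.1] * 3)
        np.testing.assert_allclose(fit.predict([2.0]), [1.0])

    def test_estimate_records_are_consistent(self, toy_triple):
        est = ivw_random_effects(toy_triple)
        assert est.ci_low <= est.theta <= est.ci_high
        assert est.or_per_decrease == pytest.approx(math.exp(-est.theta))
        assert est.or_ci_low <= est.or_per_decrease <= est.or_ci_high
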