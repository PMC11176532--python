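"""Causal estimators: closed-form oracles, invariances, diagnostics."""

import numpy as np
import pytest
import statsmodels.api as sm
from scipy import stats

from mrkit.estimators import (
    IVW,
    MREgger,
    MRPresso,
    MultivariableIVW,
    WeightedMedian,
    cochran_q,
    ivw,
    wald_ratio,
)
from mrkit.exceptions import EstimationError, InsufficientInstrumentsError
from mrkit.instruments import MultiHarmonizedSet
from mrkit.simulate import ScenarioTruth, generate_harmonized


def _arrays(bx, by, sy, sx=None):
    bx, by, sy = (np.asarray(v, float) for v in (bx, by, sy))
    sx = np.full_like(bx, 0.01) if sx is None else np.asarray(sx, float)
    return bx, sx, by, sy


class TestWaldRatio:
    def test_ratio_and_first_order_se(self):
        est = wald_ratio(0.2, 0.01, 0.04, 0.01)
        assert est.beta == pytest.approx(0.2)
        assert est.se == pytest.approx(0.05)

    def test_null_outcome_effect(self):
        est = wald_ratio(0.2, 0.01, 0.0, 0.01)
        assert est.beta == 0.0 and est.pval == pytest.approx(1.0)

    def test_zero_exposure_beta_is_error(self):
        with pytest.raises(EstimationError):
            wald_ratio(0.0, 0.01, 0.04, 0.01)

    def test_single_instrument_ivw_reduces_to_wald_ratio(self):
        est, q, _ = ivw(_arrays([0.2], [0.04], [0.01]))
        ref = wald_ratio(0.2, 0.01, 0.04, 0.01)
        assert est.beta == pytest.approx(ref.beta)
        assert est.se == pytest.approx(ref.se)
        assert np.isnan(q)


class TestIVW:
    def test_identical_ratios_give_zero_q(self):
        res = IVW(_arrays([0.1, 0.2, 0.4], [0.02, 0.04, 0.08],
                          [0.01] * 3)).fit()
        assert res.beta == pytest.approx(0.2)
        assert res.q == pytest.approx(0.0, abs=1e-20)

    def test_frozen_closed_form_example(self):
        # hand-computed weighted least squares through the origin
        res = IVW(_arrays([0.10, 0.20, 0.30], [0.025, 0.035, 0.070],
                          [0.01] * 3)).fit()
        assert res.beta == pytest.approx(0.21786, abs=5e-6)
        assert res.se_fixed == pytest.approx(0.026726, abs=5e-6)
        assert res.q == pytest.approx(1.0536, abs=5e-4)
        # Q/(k-1) < 1 here, so the random-effects SE floors at fixed
        assert res.se == res.se_fixed

    def test_equals_generic_wls_through_origin(self, rng):
        for _ in range(50):
            k = int(rng.integers(3, 30))
            bx = rng.normal(0.05, 0.02, k)
            bx[np.abs(bx) < 1e-3] = 0.05
            by = rng.normal(0.0, 0.05, k)
            sy = rng.uniform(0.005, 0.05, k)
            res = IVW(_arrays(bx, by, sy)).fit()
            wls = sm.WLS(by, bx[:, None], weights=1.0 / sy ** 2).fit()
            assert abs(res.beta - wls.params[0]) < 1e-10

    def test_point_estimate_invariant_to_weight_scaling(self):
        bx = np.array([0.1, 0.2, 0.3])
        by = np.array([0.03, 0.05, 0.07])
        sy = np.array([0.01, 0.02, 0.015])
        a = IVW(_arrays(bx, by, sy)).fit().beta
        b = IVW(_arrays(bx, by, sy * 7.0)).fit().beta  # all weights / 49
        assert a == pytest.approx(b, rel=1e-12)

    def test_ci_width_shrinks_as_inverse_sqrt_k(self):
        rng = np.random.default_rng(5)
        widths = {}
        for k in (25, 100):
            bx = rng.uniform(0.04, 0.06, k)
            by = 0.2 * bx + rng.normal(0, 0.005, k)
            res = IVW(_arrays(bx, by, np.full(k, 0.005))).fit()
            widths[k] = res.ci_high - res.ci_low
        assert widths[100] == pytest.approx(widths[25] / 2, rel=0.35)

    def test_too_few_instruments_raises(self):
        with pytest.raises(InsufficientInstrumentsError):
            IVW(_arrays([0.1], [0.02], [0.01])).fit()


class TestEgger:
    def test_exact_affine_data_recovered_to_machine_precision(self):
        bx = np.array([0.10, 0.15, 0.20, 0.30])
        by = 0.05 + 0.2 * bx
        res = MREgger(_arrays(bx, by, [0.01] * 4)).fit()
        assert res.beta == pytest.approx(0.2, abs=1e-12)
        assert res.intercept == pytest.approx(0.05, abs=1e-12)
        assert res.q == pytest.approx(0.0, abs=1e-18)

    def test_orientation_invariance(self):
        bx = np.array([0.10, 0.15, 0.20, 0.30])
        by = 0.05 + 0.2 * bx + np.array([0.001, -0.002, 0.0, 0.001])
        flipped_bx, flipped_by = bx.copy(), by.copy()
        flipped_bx[1] *= -1
        flipped_by[1] *= -1
        a = MREgger(_arrays(bx, by, [0.01] * 4)).fit()
        b = MREgger(_arrays(flipped_bx, flipped_by, [0.01] * 4)).fit()
        assert a.beta == pytest.approx(b.beta, rel=1e-12)
        assert a.intercept == pytest.approx(b.intercept, rel=1e-12)

    def test_intercept_type_one_error_near_nominal(self):
        # no pleiotropy, exposure betas measured without error: the
        # intercept test should reject ~5% at alpha=0.05
        rng = np.random.default_rng(17)
        reps, k = 2000, 30
        rejections = 0
        intercepts = []
        for _ in range(reps):
            bx = rng.uniform(0.03, 0.15, k)
            sy = np.full(k, 0.01)
            by = 0.2 * bx + rng.normal(0, sy)
            res = MREgger(_arrays(bx, by, sy)).fit()
            rejections += res.intercept_pval < 0.05
            intercepts.append(res.intercept)
        assert np.mean(intercepts) == pytest.approx(0.0, abs=0.001)
        assert rejections / reps == pytest.approx(0.05, abs=0.02)

    def test_zero_intercept_limit_matches_constrained_wls(self, rng):
        # constraining the intercept to zero must reproduce the
        # fixed-effect IVW slope (checked against the library WLS fit)
        bx = rng.uniform(0.03, 0.1, 10)
        by = 0.3 * bx + rng.normal(0, 0.01, 10)
        sy = np.full(10, 0.01)
        constrained = sm.WLS(by, bx[:, None], weights=1 / sy ** 2).fit()
        assert IVW(_arrays(bx, by, sy)).fit().beta == pytest.approx(
            constrained.params[0], rel=1e-10)

    def test_too_few_instruments_raises(self):
        with pytest.raises(InsufficientInstrumentsError):
            MREgger(_arrays([0.1, 0.2], [0.02, 0.04], [0.01] * 2)).fit()


class TestWeightedMedian:
    def test_equal_weight_interpolation_hits_middle_ratio(self):
        # cumulative midpoint of the middle ratio is exactly 0.5
        bx = np.array([1.0, 1.0, 1.0])
        by = np.array([0.1, 0.2, 0.9])
        est = WeightedMedian(_arrays(bx, by, [0.01] * 3)).point_estimate()
        assert est == pytest.approx(0.2)

    def test_degenerate_identical_ratios(self):
        bx = np.array([0.1, 0.2, 0.3])
        by = 0.25 * bx
        res = WeightedMedian(_arrays(bx, by, [1e-6] * 3,
                                     sx=[1e-6] * 3)).fit(
            n_boot=200, seed=1)
        assert res.beta == pytest.approx(0.25)
        assert res.se < 1e-3

    def test_estimate_within_ratio_range(self, rng):
        for _ in range(20):
            k = int(rng.integers(3, 25))
            bx = rng.uniform(0.02, 0.2, k)
            by = rng.normal(0, 0.05, k)
            sy = rng.uniform(0.005, 0.05, k)
            est = WeightedMedian(_arrays(bx, by, sy)).point_estimate()
            ratios = by / bx
            assert ratios.min() - 1e-12 <= est <= ratios.max() + 1e-12

    def test_seed_required_and_reproducible(self):
        data = _arrays([0.1, 0.2, 0.3], [0.03, 0.05, 0.08], [0.01] * 3)
        with pytest.raises(EstimationError):
            WeightedMedian(data).fit(n_boot=50)
        a = WeightedMedian(data).fit(n_boot=50, seed=3)
        b = WeightedMedian(data).fit(n_boot=50, seed=3)
        assert a.se == b.se


class TestMRPresso:
    def test_no_outliers_corrected_equals_raw(self):
        truth = ScenarioTruth(theta=0.2, n_snp=15, seed=42)
        hset, _ = generate_harmonized(truth)
        res = MRPresso(hset).fit(n_sim=300, seed=7)
        if not res.outliers:  # clean simulated data: the typical case
            assert res.corrected.beta == res.raw.beta
            assert res.distortion_pval is None

    def test_planted_outlier_flagged_and_corrected(self):
        truth = ScenarioTruth(theta=0.3, n_snp=20, n_outlier=1,
                              outlier_ratio_scale=10.0, seed=11)
        hset, info = generate_harmonized(truth)
        planted = [hset.variant_ids[j]
                   for j in np.nonzero(info["outlier"])[0]]
        res = MRPresso(hset).fit(n_sim=500, seed=5)
        assert set(planted) <= set(res.outliers)
        assert abs(res.corrected.beta - 0.3) < abs(res.raw.beta - 0.3)
        assert res.distortion_pval is not None

    def test_too_few_instruments_raises(self):
        with pytest.raises(InsufficientInstrumentsError):
            MRPresso(_arrays([0.1] * 3, [0.02] * 3, [0.01] * 3)).fit(
                n_sim=10, seed=0)


class TestMultivariableIVW:
    def _mhset(self, X, by, sy, names=("e1", "e2")):
        X = np.asarray(X, float)
        return MultiHarmonizedSet(
            exposure_names=list(names), outcome_name="out",
            variant_ids=[f"v{i}" for i in range(len(X))],
            exposure_betas=X, exposure_ses=np.full_like(X, 0.01),
            beta_out=np.asarray(by, float), se_out=np.asarray(sy, float))

    def test_exact_two_exposure_recovery(self, rng):
        X = rng.uniform(0.02, 0.2, size=(12, 2))
        by = 0.3 * X[:, 0] + 0.0 * X[:, 1]
        res = MultivariableIVW(self._mhset(X, by, [0.01] * 12)).fit()
        assert res.params[0] == pytest.approx(0.3, abs=1e-12)
        assert res.params[1] == pytest.approx(0.0, abs=1e-12)

    def test_single_exposure_reduces_to_ivw(self, rng):
        bx = rng.uniform(0.02, 0.2, 10)
        by = 0.25 * bx + rng.normal(0, 0.01, 10)
        sy = np.full(10, 0.01)
        mv = MultivariableIVW(
            self._mhset(bx[:, None], by, sy, names=("e1",))).fit()
        uni = IVW(_arrays(bx, by, sy)).fit()
        assert abs(mv.params[0] - uni.beta) < 1e-10

    def test_collinear_exposures_rejected(self):
        X = np.array([[0.1, 0.2], [0.2, 0.4], [0.3, 0.6], [0.15, 0.3]])
        with pytest.raises(EstimationError, match="e1"):
            MultivariableIVW(self._mhset(X, [0.01] * 4, [0.01] * 4)).fit()

    def test_direct_effect_recovery_with_noise(self):
        # planted direct effects recovered within the 95% CI most of the
        # time under the generative model
        rng = np.random.default_rng(23)
        hits = 0
        for _ in range(100):
            X = rng.uniform(0.02, 0.15, size=(40, 2))
            sy = np.full(40, 0.01)
            by = 0.25 * X[:, 0] - 0.1 * X[:, 1] + rng.normal(0, sy)
            res = MultivariableIVW(self._mhset(X, by, sy)).fit()
            est = res.estimates()[1]
            hits += est.ci_low <= -0.1 <= est.ci_high
        assert hits >= 90


class TestCochranQ:
    def test_identical_ratios(self):
        q, df, pval = cochran_q([0.2, 0.2, 0.2], [1.0, 2.0, 3.0], 0.2)
        assert q == 0.0 and df == 2 and pval == pytest.approx(1.0)

    def test_matches_direct_evaluation_on_heterogeneous_set(self, rng):
        ratios = rng.normal(0.2, 0.1, 12)
        weights = rng.uniform(0.5, 5.0, 12)
        center = np.sum(weights * ratios) / weights.sum()
        q, df, pval = cochran_q(ratios, weights, center)
        assert q == pytest.approx(
            float(np.sum(weights * (ratios - center) ** 2)), rel=1e-14)
        assert pval == pytest.approx(float(stats.chi2.sf(q, 11)), rel=1e-12)

    def test_duplicating_a_ratio_never_decreases_q(self, rng):
        ratios = list(rng.normal(0.2, 0.1, 8))
        weights = list(rng.uniform(0.5, 5.0, 8))
        q1, _, _ = cochran_q(ratios, weights, 0.2)
        q2, _, _ = cochran_q(ratios + [ratios[0]], weights + [weights[0]],
                             0.2)
        assert q2 >= q1
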