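import numpy as np
import pytest

import bilispec.model as hm
from bilispec.preprocess import minmax_normalize
from bilispec.spectra import Spectrum


@pytest.mark.parametrize(
    "x, n, expected",
    [
        (0.01246, 3, 0.0125),
        (0.04074, 3, 0.0407),
        (-3.6952e-4, 3, -3.70e-4),
        (0.00135, 2, 0.0014),
        (7.30125e-4, 2, 0.00073),
        (0.00322, 2, 0.0032),
        (0.0, 3, 0.0),
    ],
)
def test_round_to_sig_figs(x, n, expected):
    assert hm.round_to_sig_figs(x, n) == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize(
    "c, label",
    [(9.99, hm.LOW), (10.0, hm.MEDIUM), (15.0, hm.MEDIUM), (15.01, hm.HIGH), (4.0, hm.LOW)],
)
def test_label_from_concentration(c, label):
    assert hm.label_from_concentration(c) == label


class TestSlopeStatistics:
    def test_alpha_direct_evaluation(self, banded_nspec_factory):
        nspec = banded_nspec_factory({(640.0, 650.0): 0.8,
                                      (655.0, 665.0): 1.0,
                                      (670.0, 680.0): 0.9})
        assert hm.compute_alpha(nspec) == pytest.approx(0.1, abs=1e-12)

    def test_alpha_zero_for_symmetric_bands(self, banded_nspec_factory):
        nspec = banded_nspec_factory({(640.0, 650.0): 0.7, (670.0, 680.0): 0.7})
        assert hm.compute_alpha(nspec) == pytest.approx(0.0, abs=1e-12)

    def test_alpha_scale_invariant_through_pipeline(self):
        wl = np.arange(340.0, 1061.0, 1.0)
        rng = np.random.default_rng(17)
        it = rng.uniform(10.0, 900.0, wl.size)
        a1 = hm.compute_alpha(minmax_normalize(Spectrum("a", 0, wl, it)))
        a3 = hm.compute_alpha(minmax_normalize(Spectrum("a", 0, wl, 3.0 * it)))
        assert a1 == pytest.approx(a3, rel=1e-12)

    def test_alpha_undefined_when_660_band_zero(self, banded_nspec_factory):
        nspec = banded_nspec_factory({(655.0, 665.0): 0.0})
        with pytest.raises(hm.UndefinedStatisticError):
            hm.compute_alpha(nspec)

    def test_beta_direct_evaluation(self, banded_nspec_factory):
        nspec = banded_nspec_factory({(495.0, 505.0): 0.30, (555.0, 565.0): 0.42})
        assert hm.compute_beta(nspec) == pytest.approx(0.002, abs=1e-12)

    def test_beta_zero_on_flat_region(self, banded_nspec_factory):
        nspec = banded_nspec_factory({(490.0, 570.0): 0.5})
        assert hm.compute_beta(nspec) == pytest.approx(0.0, abs=1e-12)

    def test_beta_scales_with_spectrum(self, banded_nspec_factory):
        lo = banded_nspec_factory({(495.0, 505.0): 0.3, (555.0, 565.0): 0.42})
        hi = banded_nspec_factory({(495.0, 505.0): 0.6, (555.0, 565.0): 0.84})
        assert hm.compute_beta(hi) == pytest.approx(2 * hm.compute_beta(lo), rel=1e-12)


class TestThresholdRouting:
    strict = hm.ModelParams.published_defaults(hm.STRICT)
    rounded = hm.ModelParams.published_defaults(hm.ROUND)

    @pytest.mark.parametrize("alpha, branch", [(-0.0476, hm.LOW), (0.04826, hm.GE10)])
    def test_stage1_clear_cases(self, alpha, branch):
        assert hm.classify_stage1(alpha, self.strict) == branch
        assert hm.classify_stage1(alpha, self.rounded) == branch

    def test_stage1_borderline_depends_on_mode(self):
        # 0.01246 < 0.0125 strictly, but rounds to the threshold at 3 sig figs
        assert hm.classify_stage1(0.01246, self.strict) == hm.LOW
        assert hm.classify_stage1(0.01246, self.rounded) == hm.GE10

    @pytest.mark.parametrize("beta, branch", [(0.00214, hm.HIGH), (7.30125e-4, hm.MEDIUM)])
    def test_stage2_clear_cases(self, beta, branch):
        assert hm.classify_stage2(beta, self.strict) == branch
        assert hm.classify_stage2(beta, self.rounded) == branch

    def test_stage2_borderline_depends_on_mode(self):
        # 0.00135 < 0.0014 strictly, but rounds to the threshold at 2 sig figs
        assert hm.classify_stage2(0.00135, self.strict) == hm.MEDIUM
        assert hm.classify_stage2(0.00135, self.rounded) == hm.HIGH
        # the exact threshold value is not strictly above it
        assert hm.classify_stage2(0.0014, self.strict) == hm.MEDIUM
        assert hm.classify_stage2(0.0014, self.rounded) == hm.HIGH


class TestQuadratic:
    low = hm.ModelParams.published_defaults().low_model

    @pytest.mark.parametrize("x, expected", [(0.05157, 6.61), (0.12161, 8.86)])
    def test_low_curve_printed_points(self, x, expected):
        assert round(hm.predict_quadratic(x, self.low), 2) == expected

    def test_intercept(self):
        assert hm.predict_quadratic(0.0, self.low) == self.low.a0 == 4.4615

    def test_agrees_with_horner(self):
        rng = np.random.default_rng(3)
        for x in rng.uniform(0, 0.3, 50):
            horner = (self.low.a2 * x + self.low.a1) * x + self.low.a0
            assert hm.predict_quadratic(x, self.low) == pytest.approx(horner, rel=1e-15)


class TestPredictSample:
    params = hm.ModelParams.published_defaults()

    def test_low_path_reproduces_published_prediction(self, banded_nspec_factory):
        nspec = banded_nspec_factory({(640.0, 650.0): 1.0, (670.0, 680.0): 0.95,
                                      (487.0, 497.0): 0.12161})
        pred = hm.predict_sample(nspec, self.params)
        assert pred.cohort == hm.LOW
        assert round(pred.concentration_mgdl, 2) == 8.86
        assert len(pred.trace) == 1
        assert pred.trace[0].statistic == "alpha"

    def test_medium_path_intercept(self, banded_nspec_factory):
        nspec = banded_nspec_factory({(640.0, 650.0): 0.9, (670.0, 680.0): 0.95,
                                      (495.0, 505.0): 1.0, (555.0, 565.0): 1.03,
                                      (463.0, 473.0): 0.0})
        pred = hm.predict_sample(nspec, self.params)
        assert pred.cohort == hm.MEDIUM
        assert pred.concentration_mgdl == pytest.approx(7.4801)
        assert [s.statistic for s in pred.trace] == ["alpha", "beta"]

    def test_high_path_has_no_concentration(self, banded_nspec_factory):
        nspec = banded_nspec_factory({(640.0, 650.0): 0.9, (670.0, 680.0): 0.95,
                                      (495.0, 505.0): 0.8, (555.0, 565.0): 1.0})
        pred = hm.predict_sample(nspec, self.params)
        assert pred.cohort == hm.HIGH
        assert pred.concentration_mgdl is None
        assert len(pred.trace) == 2


class TestFitCohortModel:
    def test_exact_interpolation_through_three_points(self):
        pts = [(0.0, 1.0), (1.0, 2.0), (2.0, 5.0)]
        m = hm.fit_cohort_model(pts, 492.0)
        for x, y in pts:
            assert hm.predict_quadratic(x, m) == pytest.approx(y, abs=1e-9)
        assert m.r_squared == pytest.approx(1.0)

    def test_recovers_published_low_curve_from_noiseless_points(self):
        low = hm.ModelParams.published_defaults().low_model
        xs = np.linspace(0.02, 0.25, 20)
        pts = [(x, hm.predict_quadratic(x, low)) for x in xs]
        m = hm.fit_cohort_model(pts, 492.0)
        assert m.a2 == pytest.approx(low.a2, abs=1e-6)
        assert m.a1 == pytest.approx(low.a1, abs=1e-6)
        assert m.a0 == pytest.approx(low.a0, abs=1e-6)
        assert m.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_matches_independent_lstsq_route(self):
        rng = np.random.default_rng(11)
        xs = rng.uniform(0, 1, 30)
        ys = 2.0 - 3.0 * xs + 0.5 * xs**2 + rng.normal(0, 0.1, 30)
        m = hm.fit_cohort_model(list(zip(xs, ys)), 468.0)
        V = np.vander(xs, 3)  # columns x^2, x, 1
        coef, *_ = np.linalg.lstsq(V, ys, rcond=None)
        assert m.a2 == pytest.approx(coef[0], rel=1e-8)
        assert m.a1 == pytest.approx(coef[1], rel=1e-8)
        assert m.a0 == pytest.approx(coef[2], rel=1e-8)

    def test_constant_y_r2_convention(self):
        m = hm.fit_cohort_model([(0.0, 3.0), (1.0, 3.0), (2.0, 3.0)], 492.0)
        assert m.r_squared == 1.0  # perfect fit of a constant

    def test_underdetermined_fit_raises(self):
        with pytest.raises(hm.UnderdeterminedFitError):
            hm.fit_cohort_model([(0.0, 1.0), (0.0, 2.0), (0.0, 3.0)], 492.0)
        with pytest.raises(hm.UnderdeterminedFitError):
            hm.fit_cohort_model([(0.0, 1.0), (1.0, 2.0)], 492.0)


class TestCalibrateThreshold:
    def test_perfect_split_midpoint(self):
        assert hm.calibrate_threshold([1, 2, 8, 9], [False, False, True, True]) == 5.0

    def test_order_independent(self):
        assert hm.calibrate_threshold([1, 9, 2, 8], [False, True, False, True]) == 5.0

    def test_separable_data_classified_perfectly(self):
        rng = np.random.default_rng(2)
        lo = rng.uniform(-1, 0, 20)
        hi = rng.uniform(0.5, 2, 20)
        v = np.concatenate([lo, hi])
        lab = np.array([False] * 20 + [True] * 20)
        t = hm.calibrate_threshold(v, lab)
        assert np.all((v > t) == lab)

    def test_identical_values_warn(self):
        with pytest.warns(hm.NonSeparableWarning):
            t = hm.calibrate_threshold([3.0, 3.0, 3.0], [True, False, True])
        assert t == 3.0

    def test_agrees_with_exhaustive_search(self):
        rng = np.random.default_rng(7)
        for _ in range(40):
            n = int(rng.integers(2, 13))
            v = np.round(rng.normal(0, 1, n), 2)
            lab = rng.random(n) < 0.5
            if lab.all() or not lab.any():
                continue
            t = hm.calibrate_threshold(v, lab)
            best = max(
                float(((v > c) == lab).mean())
                for c in np.concatenate([(np.sort(v)[:-1] + np.sort(v)[1:]) / 2,
                                         [v.min() - 1, v.max() + 1]])
            )
            assert float(((v > t) == lab).mean()) == pytest.approx(best)


def test_model_params_validation():
    with pytest.raises(ValueError):
        hm.ModelParams(comparison_mode="fuzzy")
    with pytest.raises(ValueError):
        hm.ModelParams(alpha_threshold=float("nan"))
    with pytest.raises(ValueError):
        hm.ModelParams(ref_center_nm=2000.0)
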