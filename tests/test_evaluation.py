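"""Segmentation, window-averaged curves, error surfaces and exponent fits."""

import math

import numpy as np
import pytest

import reference as ref
from msentropy import (
    ExponentModel,
    SegmentationScheme,
    averaged_curve,
    curve_error,
    error_surface,
    fit_exponent_curve,
    gen_pink_noise,
    multiscale_curve,
    optimal_exponents,
    predict_exponent,
    segment_series,
)
from msentropy.evaluation import ErrorSurface


class TestSegmentation:
    def test_whole_series_is_one_window(self, rng):
        u = rng.normal(size=250)
        windows = segment_series(u, 250)
        assert len(windows) == 1
        np.testing.assert_array_equal(windows[0], u)

    def test_ninety_percent_overlap_window_count(self):
        windows = segment_series(np.zeros(1000), 400, overlap=0.9)
        scheme = SegmentationScheme(400, 0.9)
        assert scheme.step == 40
        assert len(windows) == 16  # floor((1000-400)/40) + 1

    def test_disjoint_windows_at_zero_overlap(self):
        windows = segment_series(np.arange(800.0), 400, overlap=0.0)
        assert len(windows) == 2
        assert windows[1][0] == 400.0

    def test_window_longer_than_series_raises(self):
        with pytest.raises(ValueError, match="exceeds"):
            segment_series(np.zeros(100), 200)

    def test_every_window_fully_contained(self, rng):
        u = rng.normal(size=777)
        for w in segment_series(u, 100, overlap=0.65):
            assert w.size == 100


class TestAveragedCurve:
    def test_single_window_equals_plain_curve(self, rng):
        u = rng.normal(size=300)
        avg = averaged_curve(u, "MFE", L=300, tau_max=3)
        plain = multiscale_curve(u, "MFE", tau_max=3)
        np.testing.assert_allclose(avg.values, plain.values, atol=1e-12)

    def test_equals_explicit_loop_over_windows(self, rng):
        u = rng.normal(size=300)
        L, tau_max = 150, 3
        avg = averaged_curve(u, "MFE", L=L, tau_max=tau_max, n=1.1)
        step = round(0.1 * L)
        acc = []
        for i in range((u.size - L) // step + 1):
            w = u[i * step : i * step + L]
            r = 0.15 * np.std(w)
            acc.append(
                ref.curve_naive(w, "MFE", m=2, r=r, n=1.1, tau_max=tau_max)
            )
        np.testing.assert_allclose(avg.values, np.mean(acc, axis=0), atol=1e-12)

    def test_full_series_r_policy_uses_global_tolerance(self, rng):
        u = rng.normal(size=300)
        avg = averaged_curve(u, "MFE", L=150, tau_max=2, r_policy="full")
        r = 0.15 * np.std(u)
        step = 15
        acc = []
        for i in range((u.size - 150) // step + 1):
            w = u[i * step : i * step + 150]
            acc.append(ref.curve_naive(w, "MFE", m=2, r=r, n=1.0, tau_max=2))
        np.testing.assert_allclose(avg.values, np.mean(acc, axis=0), atol=1e-12)


class TestCurveError:
    def test_identical_curves_have_zero_error(self, rng):
        u = rng.normal(size=300)
        c = multiscale_curve(u, "MSE", tau_max=5)
        assert curve_error(c, c) == 0.0

    def test_constant_offset_and_worked_example(self, rng):
        u = rng.normal(size=300)
        c = multiscale_curve(u, "MSE", tau_max=2)
        import dataclasses

        shifted = dataclasses.replace(c, values=c.values + 0.5)
        assert curve_error(shifted, c) == pytest.approx(0.25, abs=1e-12)
        a = dataclasses.replace(c, values=np.array([1.0, 2.0]))
        b = dataclasses.replace(c, values=np.array([2.0, 4.0]))
        assert curve_error(b, a) == pytest.approx(2.5, abs=1e-12)

    def test_undefined_scale_propagates_as_nan(self, rng):
        import dataclasses

        u = rng.normal(size=300)
        c = multiscale_curve(u, "MSE", tau_max=3)
        holed = dataclasses.replace(c, values=np.array([1.0, np.nan, 2.0]))
        assert math.isnan(curve_error(holed, c))

    def test_scale_range_mismatch_raises(self, rng):
        u = rng.normal(size=300)
        a = multiscale_curve(u, "MSE", tau_max=3)
        b = multiscale_curve(u, "MSE", tau_max=4)
        with pytest.raises(ValueError, match="scale range"):
            curve_error(a, b)


@pytest.fixture(scope="module")
def pink_set():
    return [gen_pink_noise(1200, seed=s) for s in (1, 2)]


class TestErrorSurface:

    def test_self_reference_error_is_zero(self, pink_set):
        surface = error_surface(pink_set[:1], "MSE", lengths=[1200], tau_max=5)
        assert surface.errors[0, 0] == 0.0

    def test_minimum_envelope_below_every_fixed_exponent(self, pink_set):
        surface = error_surface(
            pink_set, "MFE", lengths=[300, 600],
            exponents=[0.9, 1.0, 1.1], tau_max=5,
        )
        mins = surface.min_errors()
        for j in range(surface.exponents.size):
            assert np.all(mins <= surface.errors[:, j] + 1e-15)

    def test_tidy_frame_shape_and_columns(self, pink_set):
        surface = error_surface(
            pink_set, "MFE", lengths=[300, 600], exponents=[0.9, 1.1], tau_max=4
        )
        df = surface.to_frame()
        assert list(df.columns) == ["variant", "estimator", "length", "exponent", "error"]
        assert len(df) == 4
        assert (df["error"] >= 0).all()

    def test_matches_manual_composition(self, pink_set):
        """Surface cell == mean over series of curve_error(averaged, MSE_ref),
        with double-precision evaluation."""
        surface = error_surface(
            pink_set, "CMFE", lengths=[400], exponents=[1.0], tau_max=4,
            precision="double",
        )
        per = []
        for s in pink_set:
            refc = multiscale_curve(s, "MSE", tau_max=4)
            avg = averaged_curve(s, "CMFE", L=400, tau_max=4, n=1.0)
            per.append(curve_error(avg, refc))
        assert surface.errors[0, 0] == pytest.approx(np.mean(per), rel=1e-12)

    def test_single_precision_grid_close_to_double(self, pink_set):
        lo = error_surface(pink_set[:1], "MFE", lengths=[300],
                           exponents=[0.9, 1.1], tau_max=4, precision="single")
        hi = error_surface(pink_set[:1], "MFE", lengths=[300],
                           exponents=[0.9, 1.1], tau_max=4, precision="double")
        np.testing.assert_allclose(lo.errors, hi.errors, rtol=1e-4, atol=1e-7)

    def test_hard_variant_ignores_exponent_grid(self, pink_set):
        surface = error_surface(pink_set, "CMSE", lengths=[300], tau_max=4)
        assert surface.errors.shape == (1, 1)
        assert math.isnan(surface.exponents[0])


class TestOptimalExponents:
    def _surface(self, errors, exponents, lengths=(400,)):
        return ErrorSurface(
            variant="MFE", estimator="fuzzy",
            lengths=np.asarray(lengths),
            exponents=np.asarray(exponents, dtype=float),
            errors=np.asarray(errors, dtype=float),
            tau_max=20, n_series=1,
        )

    def test_single_exponent_grid(self):
        s = self._surface([[0.3], [0.2]], [1.0], lengths=(400, 800))
        assert optimal_exponents(s) == {400: 1.0, 800: 1.0}

    def test_argmin(self):
        s = self._surface([[0.04, 0.02, 0.03]], [0.9, 1.0, 1.1])
        assert optimal_exponents(s) == {400: 1.0}

    def test_ties_break_toward_smallest_exponent(self):
        s = self._surface([[0.02, 0.02, 0.03]], [0.9, 1.0, 1.1])
        assert optimal_exponents(s) == {400: 0.9}

    def test_hard_surface_rejected(self):
        s = self._surface([[0.02]], [np.nan])
        with pytest.raises(ValueError, match="exponent grid"):
            optimal_exponents(s)


class TestExponentFit:
    X = np.arange(400, 15_601, 400, dtype=float)

    @pytest.mark.parametrize(
        "a,b,c",
        [(1.64, -0.75, -3e-4), (0.82, -0.10, -4e-4)],
        ids=["increasing-toward-1.64", "increasing-toward-0.82"],
    )
    def test_noiseless_parameter_recovery(self, a, b, c):
        y = a + b * np.exp(c * self.X)
        model = fit_exponent_curve(self.X, y)
        assert model.a == pytest.approx(a, rel=1e-3)
        assert model.b == pytest.approx(b, rel=1e-3)
        assert model.c == pytest.approx(c, rel=1e-3)
        assert model.residual < 1e-10

    def test_noisy_recovery_within_five_percent(self):
        a, b, c = 1.64, -0.75, -3e-4
        rng = np.random.default_rng(77)
        for _ in range(50):
            y = a + b * np.exp(c * self.X) + rng.normal(0, 0.01, self.X.size)
            model = fit_exponent_curve(self.X, y)
            assert model.a == pytest.approx(a, rel=0.05)
            assert model.b == pytest.approx(b, rel=0.05)
            assert model.c == pytest.approx(c, rel=0.05)

    def test_constant_data_degenerates_to_flat_model(self):
        model = fit_exponent_curve(self.X, np.full(self.X.size, 0.9))
        assert model.a + model.b * math.exp(model.c * 400) == pytest.approx(0.9, abs=1e-6)
        assert model.a + model.b * math.exp(model.c * 15_600) == pytest.approx(0.9, abs=1e-6)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="at least 4"):
            fit_exponent_curve([400, 800, 1200], [1, 1, 1])

    def test_prediction_evaluates_printed_formula(self):
        model = ExponentModel(a=0.82, b=0.10, c=-3e-4, residual=0.0)
        assert predict_exponent(model, 1e4) == pytest.approx(
            0.82 + 0.10 * math.exp(-3.0), abs=1e-12
        )
        assert predict_exponent((0.82, 0.10, -3e-4), 1e7) == pytest.approx(0.82, abs=1e-9)
        assert predict_exponent((1.64, -0.75, -3e-4), 1e7) == pytest.approx(1.64, abs=1e-9)
        with pytest.raises(ValueError, match="positive"):
            predict_exponent(model, 0.0)
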