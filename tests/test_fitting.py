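"""Tests for normalization, the month axis, and multi-start least squares."""

import math

import numpy as np
import pytest

from phenosync.curves import (
    CurveFamily,
    CurveSpec,
    SkewNormalParams,
    VExpParams,
    curve_extremum,
    evaluate_curve,
)
from phenosync.fitting import (
    Biome,
    DegenerateSeriesError,
    InsufficientDataError,
    Organ,
    Process,
    SeasonalSeries,
    fit_seasonal_curve,
    month_axis_to_doy,
    normalize_series,
    select_curve_family,
)


def make_series(times, values, process=Process.GPP, normalized=False):
    return SeasonalSeries(
        process=process, organ=Organ.NONE, biome=Biome.BOREAL, site_id="s1",
        species=None, year=2016, times=np.asarray(times, float),
        values=np.asarray(values, float), normalized=normalized,
    )


def sample_skew(times, xi, omega, alpha, amplitude=1.0, noise_sd=0.0, rng=None):
    spec = CurveSpec(CurveFamily.SKEW_NORMAL,
                     SkewNormalParams(xi, omega, alpha, amplitude))
    v = evaluate_curve(spec, np.asarray(times, float))
    if noise_sd > 0:
        v = v + rng.normal(0, noise_sd, len(times))
    return v, spec


WEEKLY_26 = np.arange(26, dtype=float) * 7 + 80  # 26 weekly observations


class TestNormalize:
    def test_minmax_map(self):
        out = normalize_series(make_series([1, 2, 3, 4, 5, 6], [2, 4, 6, 8, 9, 10]))
        assert out.values[0] == 0 and out.values[-1] == 1
        assert out.normalized
        np.testing.assert_allclose(out.values, (np.array([2,4,6,8,9,10])-2)/8)

    def test_already_normalized_rejected(self):
        s = make_series(range(6), [0, 0.2, 1, 0.5, 0.1, 0], normalized=True)
        with pytest.raises(ValueError):
            normalize_series(s)

    def test_constant_series_rejected(self):
        with pytest.raises(DegenerateSeriesError):
            normalize_series(make_series(range(6), [3] * 6))

    def test_affine_invariance(self):
        v = [1.0, 5.0, 9.0, 4.0, 2.0, 1.5]
        a = normalize_series(make_series(range(6), v))
        b = normalize_series(make_series(range(6), [3 * x + 10 for x in v]))
        np.testing.assert_allclose(a.values, b.values, atol=1e-15)

    def test_order_statistics_preserved(self):
        v = np.array([3.0, 7.0, 2.0, 9.0, 5.0, 4.0])
        out = normalize_series(make_series(range(6), v))
        np.testing.assert_array_equal(np.argsort(out.values), np.argsort(v))


class TestMonthAxis:
    def test_mid_month_convention(self):
        np.testing.assert_array_equal(month_axis_to_doy([1]), [15])
        np.testing.assert_array_equal(month_axis_to_doy([12]), [349])
        np.testing.assert_array_equal(month_axis_to_doy([2]), [46])

    def test_strictly_increasing(self):
        doy = month_axis_to_doy(np.arange(1, 13))
        assert np.all(np.diff(doy) > 0)

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            month_axis_to_doy([0])
        with pytest.raises(ValueError):
            month_axis_to_doy([13])


class TestFitSkewNormal:
    def test_noise_free_exact_recovery(self):
        v, spec = sample_skew(WEEKLY_26, xi=160, omega=25, alpha=3)
        s = normalize_series(make_series(WEEKLY_26, v))
        fit = fit_seasonal_curve(s, CurveFamily.SKEW_NORMAL)
        assert fit.converged and fit.rse < 1e-6
        p = fit.spec.params
        # normalization rescales amplitude only; shape parameters recovered
        assert p.xi == pytest.approx(160, abs=1e-3)
        assert p.omega == pytest.approx(25, abs=1e-3)
        assert p.alpha == pytest.approx(3, abs=1e-2)
        true_peak = curve_extremum(spec)[0]
        assert fit.peak_time == pytest.approx(true_peak, abs=1e-4)

    def test_noisy_recovery_within_days(self):
        rng = np.random.default_rng(42)
        errors = []
        for _ in range(30):
            # unit-peak curve + noise sd 0.05 on the normalized scale
            v, spec = sample_skew(WEEKLY_26, 160, 25, 3, noise_sd=0.0)
            v = v / v.max() + rng.normal(0, 0.05, len(v))
            vn = np.maximum(v, 0)
            s = normalize_series(make_series(WEEKLY_26, vn))
            fit = fit_seasonal_curve(s, CurveFamily.SKEW_NORMAL)
            errors.append(abs(fit.peak_time - curve_extremum(spec)[0]))
        assert np.mean(errors) < 3.0

    def test_constant_plus_noise_not_significant(self):
        rng = np.random.default_rng(1)
        n_signif = 0
        for _ in range(100):
            v = 0.5 + rng.normal(0, 0.05, len(WEEKLY_26))
            s = normalize_series(make_series(WEEKLY_26, v))
            fit = fit_seasonal_curve(s, CurveFamily.SKEW_NORMAL)
            if fit.converged and fit.p_value <= 0.05:
                n_signif += 1
        assert n_signif <= 10  # at most 10% spurious seasonal signal

    def test_rse_matches_residual_recomputation(self):
        rng = np.random.default_rng(3)
        v, _ = sample_skew(WEEKLY_26, 150, 30, -2, noise_sd=0.03, rng=rng)
        s = normalize_series(make_series(WEEKLY_26, np.maximum(v, 0)))
        fit = fit_seasonal_curve(s, CurveFamily.SKEW_NORMAL)
        resid = s.values - evaluate_curve(fit.spec, s.times)
        n, k = fit.n_obs, 4
        assert fit.rse == pytest.approx(math.sqrt(np.sum(resid**2) / (n - k)),
                                        abs=1e-12)
        assert fit.sse == pytest.approx(float(np.sum(resid**2)), abs=1e-12)

    def test_determinism(self):
        rng = np.random.default_rng(9)
        v, _ = sample_skew(WEEKLY_26, 170, 20, 4, noise_sd=0.05, rng=rng)
        s = normalize_series(make_series(WEEKLY_26, np.maximum(v, 0)))
        f1 = fit_seasonal_curve(s, CurveFamily.SKEW_NORMAL, seed=0)
        f2 = fit_seasonal_curve(s, CurveFamily.SKEW_NORMAL, seed=0)
        assert f1.spec.params == f2.spec.params
        assert f1.sse == f2.sse and f1.p_value == f2.p_value

    def test_amplitude_scale_absorbed(self):
        # the same shape generated at different observation scales yields
        # identical timing after normalization
        peaks = []
        for amp in (0.5, 1.0, 20.0):
            v, _ = sample_skew(WEEKLY_26, 160, 25, 3, amplitude=amp)
            s = normalize_series(make_series(WEEKLY_26, v))
            peaks.append(fit_seasonal_curve(s, CurveFamily.SKEW_NORMAL).peak_time)
        assert max(peaks) - min(peaks) < 1e-6

    def test_insufficient_points(self):
        s = make_series(range(6), [0, 0.5, 1, 0.7, 0.2, 0.05], normalized=False)
        s = normalize_series(s)
        # skew normal needs >= 6 points; build shorter via direct error check
        with pytest.raises(InsufficientDataError):
            SeasonalSeries(Process.GPP, Organ.NONE, Biome.BOREAL, "s", None,
                           2016, np.arange(5.0), np.zeros(5))


class TestFitVExponential:
    def test_noise_free_recovery(self):
        spec = CurveSpec(CurveFamily.V_EXPONENTIAL, VExpParams(0.15, 1.0002, 200))
        times = np.asarray(month_axis_to_doy(np.arange(1, 13)), float)
        v = evaluate_curve(spec, times)
        s = normalize_series(make_series(times, v, process=Process.SOLUBLE_SUGARS))
        fit = fit_seasonal_curve(s, CurveFamily.V_EXPONENTIAL)
        assert fit.converged
        # min-max normalization shifts the dip affinely, so the family can
        # only match the shape approximately; timing is what matters
        assert fit.spec.params.xmax == pytest.approx(200, abs=0.1)
        assert fit.spec.params.mu > 1  # minimum-type recovered


class TestSelectFamily:
    def test_clean_skew_data_selects_skew(self):
        v, _ = sample_skew(WEEKLY_26, 160, 25, 3)
        s = normalize_series(make_series(WEEKLY_26, v))
        fam, fit = select_curve_family(s)
        assert fam is CurveFamily.SKEW_NORMAL and fit.converged

    def test_monotone_concave_falls_back_to_vexp(self):
        # concave/linear-like data: extremum far outside the window
        spec = CurveSpec(CurveFamily.V_EXPONENTIAL, VExpParams(1.0, 1.00005, 500))
        times = WEEKLY_26
        v = evaluate_curve(spec, times)
        s = normalize_series(make_series(times, v))
        fam, fit = select_curve_family(s)
        assert fam is CurveFamily.V_EXPONENTIAL

    def test_pathological_series_yields_no_seasonal_signal(self):
        s = make_series(np.arange(6.0) * 7, [0, 1, 0, 1, 0, 1], normalized=True)
        fam, fit = select_curve_family(s)
        assert fam is CurveFamily.V_EXPONENTIAL
        assert fit.p_value > 0.05  # no seasonal curve is claimed
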