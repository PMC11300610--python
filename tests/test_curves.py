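"""Unit and property tests for the seasonal curve families."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import norm

from phenosync.curves import (
    CrossingDomainError,
    CurveFamily,
    CurveSpec,
    ExtremumType,
    InvalidParameterError,
    Limb,
    SkewNormalParams,
    VExpParams,
    curve_auc,
    curve_extremum,
    evaluate_curve,
    max_activity_interval,
    percentile_times,
    search_window,
)
from conftest import random_skew_specs


def grid_mode(spec, coarse=0.01, fine=1e-5):
    """Two-stage dense-grid argmax/argmin, independent of the optimizer path."""
    lo, hi = search_window(spec)
    g = np.arange(lo, hi, coarse)
    v = evaluate_curve(spec, g)
    pick = np.argmax if spec.extremum_type is ExtremumType.MAXIMUM else np.argmin
    t0 = g[pick(v)]
    g2 = np.arange(t0 - 2 * coarse, t0 + 2 * coarse, fine)
    v2 = evaluate_curve(spec, g2)
    return float(g2[pick(v2)])


def grid_crossing(spec, target, limb, coarse=0.01):
    """Grid bracketing + linear interpolation crossing finder."""
    lo, hi = search_window(spec)
    t_ext = grid_mode(spec)
    if limb is Limb.ASCENDING:
        g = np.arange(lo, t_ext, coarse)
    else:
        g = np.arange(t_ext, hi, coarse)
    v = evaluate_curve(spec, g) - target
    sign_change = np.nonzero(np.diff(np.sign(v)))[0]
    assert len(sign_change) >= 1
    i = sign_change[0]
    t1, t2, v1, v2 = g[i], g[i + 1], v[i], v[i + 1]
    return float(t1 - v1 * (t2 - t1) / (v2 - v1))


class TestEvaluate:
    def test_symmetric_peak_value(self, symmetric_spec):
        assert evaluate_curve(symmetric_spec, 160) == pytest.approx(
            1 / (25 * math.sqrt(2 * math.pi)), abs=1e-15
        )

    def test_vexp_at_xmax_is_ymax(self):
        spec = CurveSpec(CurveFamily.V_EXPONENTIAL, VExpParams(1.0, 0.9, 200))
        assert evaluate_curve(spec, 200) == 1.0

    def test_high_precision_reference_value(self, skewed_spec):
        # frozen from a 30-significant-digit symbolic evaluation of the
        # closed form (sympy erf/exp at rational arguments)
        assert evaluate_curve(skewed_spec, 150) == pytest.approx(
            0.0228641095460686893448429114956, rel=1e-13
        )

    def test_alpha_zero_matches_scaled_gaussian(self):
        t = np.linspace(0, 365, 1001)
        for amp, xi, om in [(1.0, 160, 25), (3.7, 120, 40), (0.2, 200, 12)]:
            spec = CurveSpec(
                CurveFamily.SKEW_NORMAL, SkewNormalParams(xi, om, 0.0, amp)
            )
            np.testing.assert_allclose(
                evaluate_curve(spec, t), amp * norm.pdf(t, xi, om), atol=1e-12
            )

    def test_vectorized_matches_scalar(self, skewed_spec):
        t = np.array([100.0, 140.0, 163.2])
        vec = evaluate_curve(skewed_spec, t)
        assert vec.shape == (3,)
        for ti, vi in zip(t, vec):
            assert evaluate_curve(skewed_spec, ti) == vi

    def test_invalid_parameters_raise(self):
        with pytest.raises(InvalidParameterError):
            SkewNormalParams(xi=np.nan, omega=25, alpha=0)
        with pytest.raises(InvalidParameterError):
            SkewNormalParams(xi=160, omega=-1, alpha=0)
        with pytest.raises(InvalidParameterError):
            VExpParams(ymax=-0.5, mu=0.9, xmax=100)
        with pytest.raises(InvalidParameterError):
            evaluate_curve(
                CurveSpec(CurveFamily.SKEW_NORMAL, SkewNormalParams(160, 25, 0)),
                np.inf,
            )


class TestExtremum:
    def test_symmetric_mode_is_xi(self, symmetric_spec):
        t_ext, val = curve_extremum(symmetric_spec)
        assert t_ext == 160
        assert val == pytest.approx(1 / (25 * math.sqrt(2 * math.pi)))

    def test_vexp_minimum(self):
        spec = CurveSpec(CurveFamily.V_EXPONENTIAL, VExpParams(0.8, 1.2, 90))
        assert curve_extremum(spec) == (90, 0.8)
        assert spec.extremum_type is ExtremumType.MINIMUM

    def test_vexp_maximum_iff_mu_below_one(self):
        assert (
            CurveSpec(CurveFamily.V_EXPONENTIAL, VExpParams(1, 0.95, 90)).extremum_type
            is ExtremumType.MAXIMUM
        )
        with pytest.raises(InvalidParameterError):
            CurveSpec(CurveFamily.V_EXPONENTIAL, VExpParams(1, 1.0, 90)).extremum_type

    def test_mode_matches_grid_oracle(self, skewed_spec):
        t_ext, _ = curve_extremum(skewed_spec)
        assert t_ext == pytest.approx(grid_mode(skewed_spec), abs=1e-3)

    @pytest.mark.parametrize("alpha", [0.5, 1.0, 2.5, 4.0])
    def test_mode_sign_symmetry(self, alpha):
        pos = CurveSpec(CurveFamily.SKEW_NORMAL, SkewNormalParams(150, 20, alpha))
        neg = CurveSpec(CurveFamily.SKEW_NORMAL, SkewNormalParams(150, 20, -alpha))
        tp, _ = curve_extremum(pos)
        tn, _ = curve_extremum(neg)
        assert (tp - 150) == pytest.approx(-(tn - 150), abs=1e-5)

    @given(
        xi=st.floats(50, 300),
        omega=st.floats(5, 60),
        alpha=st.floats(-8, 8),
    )
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_unimodality(self, xi, omega, alpha):
        spec = CurveSpec(CurveFamily.SKEW_NORMAL, SkewNormalParams(xi, omega, alpha))
        t_ext, peak = curve_extremum(spec)
        lo, hi = search_window(spec)
        g = np.arange(lo, hi, 0.1)
        v = evaluate_curve(spec, g)
        # strict monotonicity where the curve is numerically alive; the
        # far tail may underflow to zero in double precision
        alive = v > peak * 1e-14
        before = v[(g < t_ext - 0.1) & alive]
        after = v[(g > t_ext + 0.1) & alive]
        assert np.all(np.diff(before) > 0)
        assert np.all(np.diff(after) < 0)
        assert np.all(np.diff(v[g < t_ext - 0.1]) >= 0)
        assert np.all(np.diff(v[g > t_ext + 0.1]) <= 0)


class TestPercentileTimes:
    LEVELS = (0.1, 0.25, 0.5, 0.75, 0.9)

    def test_symmetric_crossings_mirror(self, symmetric_spec):
        asc = percentile_times(symmetric_spec, [0.5], Limb.ASCENDING)[0.5]
        desc = percentile_times(symmetric_spec, [0.5], Limb.DESCENDING)[0.5]
        assert (desc - 160) == pytest.approx(160 - asc, abs=1e-6)

    def test_level_one_returns_extremum(self, skewed_spec, dip_spec):
        for spec in (skewed_spec, dip_spec):
            t_ext, _ = curve_extremum(spec)
            for limb in Limb:
                assert percentile_times(spec, [1.0], limb)[1.0] == t_ext

    @pytest.mark.parametrize("limb", list(Limb))
    def test_crossing_value_consistency(self, skewed_spec, limb):
        _, peak = curve_extremum(skewed_spec)
        times = percentile_times(skewed_spec, self.LEVELS, limb)
        for q, t in times.items():
            assert evaluate_curve(skewed_spec, t) == pytest.approx(
                q * peak, abs=1e-6 * peak
            )

    @pytest.mark.parametrize("limb", list(Limb))
    def test_matches_grid_oracle(self, skewed_spec, limb):
        _, peak = curve_extremum(skewed_spec)
        times = percentile_times(skewed_spec, self.LEVELS, limb)
        for q, t in times.items():
            assert t == pytest.approx(grid_crossing(skewed_spec, q * peak, limb),
                                      abs=1e-3)

    def test_monotone_in_level(self, skewed_spec):
        asc = percentile_times(skewed_spec, self.LEVELS, Limb.ASCENDING)
        desc = percentile_times(skewed_spec, self.LEVELS, Limb.DESCENDING)
        asc_t = [asc[q] for q in self.LEVELS]
        desc_t = [desc[q] for q in self.LEVELS]
        assert np.all(np.diff(asc_t) > 0)
        assert np.all(np.diff(desc_t) < 0)

    def test_minimum_curve_levels(self, dip_spec):
        # level q targets v_min + (1-q) * (window amplitude); larger q is
        # closer to the minimum on both limbs
        times_a = percentile_times(dip_spec, self.LEVELS, Limb.ASCENDING)
        t_ext, v_min = curve_extremum(dip_spec)
        lo, hi = search_window(dip_spec)
        v_edge = max(evaluate_curve(dip_spec, lo), evaluate_curve(dip_spec, hi))
        for q, t in times_a.items():
            target = v_min + (1 - q) * (v_edge - v_min)
            assert evaluate_curve(dip_spec, t) == pytest.approx(target, rel=1e-5)
            assert t < t_ext

    def test_unreachable_level_raises(self, symmetric_spec):
        # far below the curve value at the window edge: no crossing on the limb
        with pytest.raises(CrossingDomainError):
            percentile_times(symmetric_spec, [1e-12], Limb.ASCENDING)


class TestAUC:
    def test_gaussian_normalization(self):
        spec = CurveSpec(CurveFamily.SKEW_NORMAL, SkewNormalParams(160, 25, 0, 1.0))
        assert curve_auc(spec, search_window(spec)) == pytest.approx(1.0, abs=1e-8)

    def test_constant_vexp_line(self):
        spec = CurveSpec(CurveFamily.V_EXPONENTIAL, VExpParams(1.0, 1.0, 100))
        assert curve_auc(spec, (0, 10)) == pytest.approx(10.0, abs=1e-10)

    def test_matches_simpson_oracle(self, skewed_spec):
        # frozen from fixed-step Simpson integration at 1e-3-day resolution
        assert curve_auc(skewed_spec, (120, 180)) == pytest.approx(
            0.8173982766688737, rel=1e-8
        )

    def test_additivity(self, skewed_spec):
        a, b, c = 100.0, 151.3, 220.0
        total = curve_auc(skewed_spec, (a, c))
        assert curve_auc(skewed_spec, (a, b)) + curve_auc(skewed_spec, (b, c)) == (
            pytest.approx(total, rel=1e-8)
        )

    def test_invalid_interval(self, skewed_spec):
        with pytest.raises(ValueError):
            curve_auc(skewed_spec, (180, 120))


class TestMaxActivityInterval:
    def test_symmetric_about_xi(self, symmetric_spec):
        lo, hi = max_activity_interval(symmetric_spec)
        assert (hi - 160) == pytest.approx(160 - lo, abs=1e-5)

    def test_width_shrinks_with_level(self, skewed_spec):
        _, peak = curve_extremum(skewed_spec)
        widths = []
        for q in (0.5, 0.75, 0.9):
            a = percentile_times(skewed_spec, [q], Limb.ASCENDING)[q]
            d = percentile_times(skewed_spec, [q], Limb.DESCENDING)[q]
            widths.append(d - a)
        assert widths[0] > widths[1] > widths[2]

    def test_matches_grid_oracle(self, skewed_spec):
        _, peak = curve_extremum(skewed_spec)
        lo, hi = max_activity_interval(skewed_spec)
        assert lo == pytest.approx(
            grid_crossing(skewed_spec, 0.75 * peak, Limb.ASCENDING), abs=1e-3
        )
        assert hi == pytest.approx(
            grid_crossing(skewed_spec, 0.75 * peak, Limb.DESCENDING), abs=1e-3
        )

    def test_minimum_curve_interval_brackets_minimum(self, dip_spec):
        lo, hi = max_activity_interval(dip_spec)
        t_ext, v_min = curve_extremum(dip_spec)
        assert lo < t_ext < hi
        # inside the interval the curve stays at or below the 25%-range level
        wlo, whi = search_window(dip_spec)
        v_edge = max(evaluate_curve(dip_spec, wlo), evaluate_curve(dip_spec, whi))
        level = v_min + 0.25 * (v_edge - v_min)
        g = np.linspace(lo + 1e-6, hi - 1e-6, 200)
        assert np.all(evaluate_curve(dip_spec, g) <= level + 1e-9)


def test_randomized_specs_satisfy_percentile_consistency():
    for spec in random_skew_specs(10, seed=7):
        _, peak = curve_extremum(spec)
        for limb in Limb:
            times = percentile_times(spec, (0.25, 0.75), limb)
            for q, t in times.items():
                assert evaluate_curve(spec, t) == pytest.approx(
                    q * peak, abs=1e-6 * peak
                )
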