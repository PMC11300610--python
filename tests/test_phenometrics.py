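"""Phenometrics, deltas, event sequences and growing-season spans."""

import numpy as np
import pytest

from phenosync.curves import CurveFamily, CurveSpec, Limb, SkewNormalParams, VExpParams
from phenosync.fitting import Biome, FittedCurve, Organ, Process
from phenosync.phenometrics import (
    PERCENTILE_LEVELS,
    compute_phenometrics,
    event_sequence,
    growing_season_span,
    timing_delta,
)


def fitted(spec, process=Process.GPP, organ=Organ.NONE, biome=Biome.BOREAL,
           p_value=0.001):
    return FittedCurve(
        spec=spec, sse=0.01, rse=0.02, p_value=p_value, n_obs=30,
        converged=True, n_params=4, family=spec.family,
    )


def metrics_for(spec, **kw):
    ctx = dict(process=Process.GPP, organ=Organ.NONE, biome=Biome.BOREAL)
    ctx.update(kw)
    return compute_phenometrics(fitted(spec), **ctx)


class TestComputePhenometrics:
    def test_symmetric_curve(self):
        spec = CurveSpec(CurveFamily.SKEW_NORMAL, SkewNormalParams(160, 25, 0))
        m = metrics_for(spec)
        assert m.peak_time == pytest.approx(160, abs=1e-6)
        lo, hi = m.max_activity
        assert (hi - 160) == pytest.approx(160 - lo, abs=1e-5)

    def test_type_invariants(self):
        spec = CurveSpec(CurveFamily.SKEW_NORMAL, SkewNormalParams(140, 30, 4))
        m = metrics_for(spec)
        lo, hi = m.max_activity
        assert lo <= m.peak_time <= hi
        assert m.auc_max_activity <= m.auc_total
        for (q, limb), t in m.percentile_times.items():
            if limb is Limb.ASCENDING:
                assert t <= m.peak_time
            else:
                assert t >= m.peak_time
        assert set(q for q, _ in m.percentile_times) == set(PERCENTILE_LEVELS)

    def test_minimum_curve_metrics(self):
        spec = CurveSpec(CurveFamily.V_EXPONENTIAL, VExpParams(0.2, 1.001, 210))
        m = metrics_for(spec, process=Process.SOLUBLE_SUGARS, organ=Organ.STEM)
        assert m.peak_time == 210
        lo, hi = m.max_activity
        assert lo < 210 < hi

    def test_requires_significance(self):
        spec = CurveSpec(CurveFamily.SKEW_NORMAL, SkewNormalParams(160, 25, 0))
        bad = fitted(spec)
        bad.p_value = 0.2
        with pytest.raises(ValueError):
            compute_phenometrics(bad, process=Process.GPP, biome=Biome.BOREAL)

    def test_requires_convergence(self):
        bad = FittedCurve(spec=None, sse=np.inf, rse=np.inf, p_value=1.0,
                          n_obs=10, converged=False)
        with pytest.raises(ValueError):
            compute_phenometrics(bad, process=Process.GPP, biome=Biome.BOREAL)


class TestTimingDelta:
    def spec_at(self, xi):
        return CurveSpec(CurveFamily.SKEW_NORMAL, SkewNormalParams(xi, 25, 2))

    def test_identity_and_antisymmetry(self):
        a = metrics_for(self.spec_at(150), process=Process.GPP)
        b = metrics_for(self.spec_at(120), process=Process.CAMBIAL_ACTIVITY)
        assert timing_delta(a, a, 1.0).delta == 0
        d_ab = timing_delta(a, b, 0.5, Limb.ASCENDING).delta
        d_ba = timing_delta(b, a, 0.5, Limb.ASCENDING).delta
        assert d_ab == pytest.approx(-d_ba, abs=1e-12)

    def test_biome_mismatch_rejected(self):
        a = metrics_for(self.spec_at(150), biome=Biome.BOREAL)
        b = metrics_for(self.spec_at(120), biome=Biome.TEMPERATE,
                        process=Process.CAMBIAL_ACTIVITY)
        with pytest.raises(ValueError):
            timing_delta(a, b, 1.0)

    def test_shifted_copies_constant_delta(self):
        # equal-shape time-shifted curves: delta equals the shift at every
        # level and limb
        a = metrics_for(self.spec_at(180), process=Process.GPP)
        b = metrics_for(self.spec_at(150), process=Process.CAMBIAL_ACTIVITY)
        for q in PERCENTILE_LEVELS:
            for limb in Limb:
                assert timing_delta(a, b, q, limb).delta == pytest.approx(
                    30.0, abs=1e-4
                )
        assert timing_delta(a, b, 1.0).delta == pytest.approx(30.0, abs=1e-5)

    def test_sign_convention(self):
        flux = metrics_for(self.spec_at(140), process=Process.NEE)
        wood = metrics_for(self.spec_at(170), process=Process.CAMBIAL_ACTIVITY)
        rec = timing_delta(flux, wood, 1.0)
        assert rec.delta < 0  # negative: flux event earlier


class TestEventSequence:
    def mk(self, xi, process, organ=Organ.NONE):
        spec = CurveSpec(CurveFamily.SKEW_NORMAL, SkewNormalParams(xi, 25, 0))
        return metrics_for(spec, process=process, organ=organ)

    def test_sorted_by_time(self):
        ms = [self.mk(160, Process.GPP), self.mk(150, Process.CAMBIAL_ACTIVITY)]
        seq = event_sequence(ms, Biome.BOREAL)
        assert [e for e, _ in seq] == ["cambial_activity", "GPP"]

    def test_permutation_invariance_and_closure(self):
        ms = [self.mk(t, p) for t, p in
              [(150, Process.NEE), (160, Process.GPP), (155, Process.RECO)]]
        seq1 = event_sequence(ms, Biome.BOREAL)
        seq2 = event_sequence(ms[::-1], Biome.BOREAL)
        assert seq1 == seq2
        assert sorted(e for e, _ in seq1) == sorted(m.event_name for m in ms)

    def test_tie_break_canonical_order(self):
        ms = [self.mk(160, Process.GPP), self.mk(160, Process.NEE)]
        seq = event_sequence(ms, Biome.BOREAL)
        assert [e for e, _ in seq] == ["NEE", "GPP"]  # NEE first in canon order


class TestGrowingSeason:
    def mk(self, xi, process):
        spec = CurveSpec(CurveFamily.SKEW_NORMAL, SkewNormalParams(xi, 25, 0))
        return metrics_for(spec, process=process)

    def test_span_arithmetic(self):
        ms = [self.mk(130, Process.NEE), self.mk(160, Process.GPP),
              self.mk(203, Process.RECO)]
        start, end, dur = growing_season_span(ms, Biome.BOREAL)
        assert (start, end, dur) == (
            pytest.approx(130, abs=1e-6),
            pytest.approx(203, abs=1e-6),
            pytest.approx(73, abs=1e-6),
        )

    def test_duplicate_events_do_not_change_span(self):
        ms = [self.mk(130, Process.NEE), self.mk(203, Process.RECO)]
        span1 = growing_season_span(ms, Biome.BOREAL)
        span2 = growing_season_span(ms + [self.mk(203, Process.RECO)], Biome.BOREAL)
        assert span1[2] == span2[2]
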