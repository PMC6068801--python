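import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stepfuse import labeler as lb
from stepfuse import simulate as sim
from stepfuse.types import Activity, GpsFix, GroundTruthSegment, StepEventSeries, WeakLabelSegment

CFG = lb.FuzzyConfig()


def steps_at(times):
    return StepEventSeries(np.asarray(sorted(times), dtype=float))


def uniform_steps(start, end, spm):
    n = int(round((end - start) * spm / 60.0))
    return np.linspace(start, end, n, endpoint=False)


class TestSpmWindows:
    def test_uniform_100(self):
        w = lb.compute_spm_windows(steps_at(uniform_steps(0, 60, 100)), (0, 60))
        assert len(w) == 1
        assert w[0].spm == pytest.approx(100)

    def test_no_steps(self):
        w = lb.compute_spm_windows(steps_at([]), (0, 60))
        assert w[0].spm == 0

    def test_trailing_45s_scaled(self):
        # 75 steps in the 45-s trailing window -> 100 steps/min
        times = list(uniform_steps(0, 60, 60)) + list(np.linspace(60, 105, 75, endpoint=False))
        w = lb.compute_spm_windows(steps_at(times), (0, 105))
        assert len(w) == 2
        assert w[1].duration == pytest.approx(45)
        assert w[1].spm == pytest.approx(100)

    def test_short_trailing_discarded(self):
        w = lb.compute_spm_windows(steps_at([]), (0, 80))
        assert len(w) == 1  # 20-s remainder < 30 s dropped

    def test_short_span_rejected(self):
        with pytest.raises(ValueError):
            lb.compute_spm_windows(steps_at([]), (0, 30))


class TestMergeWindows:
    @staticmethod
    def windows(spms, width=60.0):
        return [lb.SpmWindow(i * width, (i + 1) * width, s) for i, s in enumerate(spms)]

    def test_example_sequence(self):
        merged = lb.merge_windows(self.windows([102, 98, 105, 0, 0]))
        assert len(merged) == 2
        assert merged[0].spm == pytest.approx((102 + 98 + 105) / 3)
        assert merged[1].spm == 0

    def test_strict_threshold(self):
        merged = lb.merge_windows(self.windows([100, 111]))
        assert len(merged) == 2  # diff 11, not < 10

    def test_single_window_identity(self):
        merged = lb.merge_windows(self.windows([42]))
        assert len(merged) == 1
        assert (merged[0].start, merged[0].end, merged[0].spm) == (0, 60, 42)

    def test_non_contiguous_never_merge(self):
        ws = [lb.SpmWindow(0, 60, 100), lb.SpmWindow(120, 180, 100)]
        assert len(lb.merge_windows(ws)) == 2

    @given(st.lists(st.floats(0, 200), min_size=1, max_size=30))
    @settings(max_examples=100, deadline=None)
    def test_merge_properties(self, spms):
        ws = self.windows(spms)
        merged = lb.merge_windows(ws)
        # ordered, disjoint, covering
        assert merged[0].start == 0 and merged[-1].end == pytest.approx(60.0 * len(spms))
        for a, b in zip(merged, merged[1:]):
            assert a.end == pytest.approx(b.start)
        # per-segment spm equals the duration-weighted mean of its windows,
        # and each split was justified by a >= 10 spm jump from the running mean
        for seg in merged:
            inside = [w.spm for w in ws if seg.start <= w.start < seg.end]
            assert seg.spm == pytest.approx(np.mean(inside))
        for a, b in zip(merged, merged[1:]):
            first_of_b = next(w.spm for w in ws if w.start == b.start)
            assert abs(first_of_b - a.spm) >= CFG.merge_spm - 1e-9


class TestSpeed:
    def test_identical_coordinates(self):
        a = GpsFix(0, 45.0, 7.0, 5.0)
        b = GpsFix(60, 45.0, 7.0, 5.0)
        assert lb.estimate_speed(a, b) == 0.0

    def test_lat_degree_oracle(self):
        # 0.01 deg latitude = 0.01 * pi/180 * 6371 km = 1111.95 m
        a = GpsFix(0, 0.0, 0.0, 5.0)
        b = GpsFix(60, 0.01, 0.0, 5.0)
        assert lb.estimate_speed(a, b) == pytest.approx(18.5325, abs=1e-3)

    def test_speed_halves_with_double_dt(self):
        a = GpsFix(0, 0.0, 0.0, 5.0)
        b = GpsFix(60, 0.01, 0.0, 5.0)
        b2 = GpsFix(120, 0.01, 0.0, 5.0)
        assert lb.estimate_speed(a, b2) == pytest.approx(lb.estimate_speed(a, b) / 2)

    def test_nonpositive_dt(self):
        a = GpsFix(60, 0, 0, 5)
        with pytest.raises(ValueError):
            lb.estimate_speed(a, GpsFix(60, 0.01, 0, 5))


class TestSegmentSpeed:
    SEG = lb.MergedSegment(0, 600, 0.0)

    def test_single_pair(self):
        fixes = [GpsFix(0, 0, 0, 20.0), GpsFix(60, 0.01, 0, 5.0)]
        speed, w = lb.segment_speed(self.SEG, fixes, CFG)
        assert speed == pytest.approx(18.5325, abs=1e-3)
        assert w == pytest.approx(min(1.0, CFG.a0 / 20.0))

    def test_equal_dt_weighted_mean(self):
        # speeds 1 and 3 m/s over equal intervals -> 2 m/s
        d1 = 60.0 * 1.0 / 111194.93  # degrees latitude covering 60 m
        d3 = 60.0 * 3.0 / 111194.93
        fixes = [
            GpsFix(0, 0, 0, 5),
            GpsFix(60, d1, 0, 5),
            GpsFix(120, d1 + d3, 0, 5),
        ]
        speed, w = lb.segment_speed(self.SEG, fixes, CFG)
        assert speed == pytest.approx(2.0, rel=1e-3)
        assert w == 1.0

    @pytest.mark.parametrize("fixes", [[], [GpsFix(10, 0, 0, 5)]])
    def test_degenerate(self, fixes):
        assert lb.segment_speed(self.SEG, fixes, CFG) == (None, 0.0)


class TestMemberships:
    def test_walking_peak(self):
        assert lb.step_membership(100, CFG)[Activity.WALKING] == pytest.approx(1.0)

    def test_running_peak(self):
        assert lb.step_membership(170, CFG)[Activity.RUNNING] == pytest.approx(1.0)

    def test_zero_spm_sedentary(self):
        m = lb.step_membership(0, CFG)
        assert m[Activity.SITTING] == 1.0
        assert m[Activity.WALKING] < 1e-3 and m[Activity.RUNNING] < 1e-3

    @pytest.mark.parametrize("spm", [50, 130])
    def test_ambiguous_cadences_below_half(self, spm):
        m = lb.step_membership(spm, CFG)
        assert all(v < 0.5 for v in m.values())

    @pytest.mark.parametrize(
        "v,act",
        [(1.4, Activity.WALKING), (6.0, Activity.CYCLING), (25.0, Activity.TRANSPORTATION)],
    )
    def test_speed_plateaus(self, v, act):
        assert lb.speed_membership(v, CFG)[act] == 1.0

    @given(st.floats(0, 300))
    @settings(max_examples=100, deadline=None)
    def test_memberships_in_unit_interval(self, spm):
        for v in lb.step_membership(spm, CFG).values():
            assert 0.0 <= v <= 1.0
        for v in lb.speed_membership(spm / 5.0, CFG).values():
            assert 0.0 <= v <= 1.0


class TestCombineProbability:
    def test_zero_weight_returns_p_step(self):
        assert lb.combine_probability(0.8, 0.1, 0.0) == 0.8

    def test_direct_substitution(self):
        assert lb.combine_probability(0.8, 0.6, 1.0) == pytest.approx(0.7)

    @given(st.floats(0, 1), st.floats(0, 10))
    @settings(max_examples=100, deadline=None)
    def test_fixed_point(self, p, w):
        assert lb.combine_probability(p, p, w) == pytest.approx(p)

    @given(st.floats(0, 1), st.floats(0, 1), st.floats(0, 10))
    @settings(max_examples=200, deadline=None)
    def test_bounds(self, p_step, p_gps, w):
        out = lb.combine_probability(p_step, p_gps, w)
        assert 0.0 <= out <= 1.0

    @given(st.floats(0, 1), st.floats(0, 1), st.floats(0, 1), st.floats(0, 10))
    @settings(max_examples=200, deadline=None)
    def test_monotone(self, a, b, p_gps, w):
        lo, hi = sorted((a, b))
        assert lb.combine_probability(lo, p_gps, w) <= lb.combine_probability(hi, p_gps, w) + 1e-12
        assert lb.combine_probability(p_gps, lo, w) <= lb.combine_probability(p_gps, hi, w) + 1e-12

    @pytest.mark.parametrize("bad", [(-0.1, 0.5, 1), (0.5, 1.2, 1), (0.5, 0.5, -1)])
    def test_out_of_range(self, bad):
        with pytest.raises(ValueError):
            lb.combine_probability(*bad)


class TestAssignWeakLabel:
    def test_treadmill_walking_without_gps(self):
        seg = lb.MergedSegment(0, 600, 100.0, None, 0.0)
        out = lb.assign_weak_label(seg, CFG)
        assert out.activity is Activity.WALKING
        assert out.probability == pytest.approx(1.0)

    def test_ambiguous_50_spm_missing(self):
        seg = lb.MergedSegment(0, 300, 50.0, None, 0.0)
        assert lb.assign_weak_label(seg, CFG).is_missing

    def test_transport_overrides_spurious_steps(self):
        seg = lb.MergedSegment(0, 600, 0.0, 25.0, 1.0)
        out = lb.assign_weak_label(seg, CFG)
        assert out.activity is Activity.TRANSPORTATION
        assert out.probability == pytest.approx(1.0)

    def test_gps_only_classes_gated_by_w_min(self):
        seg = lb.MergedSegment(0, 600, 0.0, 6.0, 0.1)  # cycling speed, poor GPS
        out = lb.assign_weak_label(seg, CFG)
        assert out.activity is not Activity.CYCLING

    @given(
        st.floats(0, 250),
        st.one_of(st.none(), st.floats(0, 40)),
        st.floats(0, 1),
    )
    @settings(max_examples=200, deadline=None)
    def test_labeled_implies_above_threshold(self, spm, speed, w):
        seg = lb.MergedSegment(0, 60, spm, speed, w if speed is not None else 0.0)
        out = lb.assign_weak_label(seg, CFG)
        if not out.is_missing:
            assert out.probability >= CFG.theta


class TestSmoothing:
    @staticmethod
    def seq(*acts):
        segs = []
        for i, a in enumerate(acts):
            prob = None if a is None else 0.9
            segs.append(WeakLabelSegment(i * 60.0, (i + 1) * 60.0, a, prob))
        return segs

    def test_cycling_then_transport(self):
        out = lb.smooth_labels(self.seq(Activity.CYCLING, Activity.TRANSPORTATION))
        assert [s.activity for s in out] == [Activity.TRANSPORTATION] * 2

    def test_transport_then_cycling(self):
        out = lb.smooth_labels(self.seq(Activity.TRANSPORTATION, Activity.CYCLING))
        assert [s.activity for s in out] == [Activity.TRANSPORTATION] * 2

    def test_cycling_walking_unchanged(self):
        segs = self.seq(Activity.CYCLING, Activity.WALKING)
        assert lb.smooth_labels(segs) == segs

    def test_missing_gap_not_bridged(self):
        segs = self.seq(Activity.CYCLING, None, Activity.TRANSPORTATION)
        assert lb.smooth_labels(segs) == segs

    @given(
        st.lists(
            st.sampled_from(list(Activity) + [None]),
            min_size=0,
            max_size=12,
        )
    )
    @settings(max_examples=100, deadline=None)
    def test_no_consecutive_pair_survives(self, acts):
        out = lb.smooth_labels(self.seq(*acts))
        for a, b in zip(out, out[1:]):
            assert {a.activity, b.activity} != {Activity.CYCLING, Activity.TRANSPORTATION}
        # smoothing only ever rewrites cycling to transportation
        for before, after in zip(self.seq(*acts), out):
            if before.activity is not Activity.CYCLING:
                assert after.activity == before.activity


class TestQualityReport:
    def test_perfect_agreement(self):
        truth = [GroundTruthSegment(0, 600, Activity.WALKING)]
        weak = [WeakLabelSegment(0, 600, Activity.WALKING, 1.0)]
        (day,) = lb.label_quality_report(weak, truth)
        assert day.precision == 1.0 and day.missing_rate == 0.0

    def test_all_missing(self):
        truth = [GroundTruthSegment(0, 600, Activity.WALKING)]
        weak = [WeakLabelSegment(0, 600, None, None)]
        (day,) = lb.label_quality_report(weak, truth)
        assert day.precision is None and day.missing_rate == 1.0

    def test_partial(self):
        truth = [GroundTruthSegment(0, 100, Activity.WALKING)]
        weak = [
            WeakLabelSegment(0, 50, Activity.WALKING, 1.0),
            WeakLabelSegment(50, 75, Activity.RUNNING, 0.8),
            WeakLabelSegment(75, 100, None, None),
        ]
        (day,) = lb.label_quality_report(weak, truth)
        assert day.precision == pytest.approx(50 / 75)
        assert day.missing_rate == pytest.approx(25 / 100)

    def test_unambiguous_trace_high_precision(self, mini_trace):
        schedule, _, steps, fixes = mini_trace
        weak = lb.weak_label_trace(steps, fixes, (0.0, schedule.duration))
        truth = sim.schedule_to_truth(schedule)
        (day,) = lb.label_quality_report(weak, truth)
        assert day.precision >= 0.95
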