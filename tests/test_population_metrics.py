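"""Session metrics, trajectories, and paired comparisons."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from catrace import (
    CalciumEvent,
    EventRaster,
    SessionInfo,
    SessionMetrics,
    build_trajectory,
    event_frequency,
    mean_amplitude,
    paired_comparison,
    session_metrics,
    synchronicity,
)


def make_raster(
    peaks_by_roi, n_rois=None, rate=5.0, duration_s=None, session=None, amp=1.0
):
    """Raster from {roi_index: [peak frames]} with uniform amplitudes."""
    n_rois = n_rois or (max(peaks_by_roi) + 1 if peaks_by_roi else 1)
    roi_ids = tuple(f"roi{i:03d}" for i in range(n_rois))
    n_frames = 1 + max(
        (f for frames in peaks_by_roi.values() for f in frames), default=10
    )
    if duration_s is not None and session is None:
        session = SessionInfo(duration_s=duration_s)
    events = []
    for i in sorted(peaks_by_roi):
        for f in sorted(peaks_by_roi[i]):
            events.append(
                CalciumEvent(
                    roi_id=roi_ids[i],
                    peak_frame=f,
                    peak_time_s=f / rate,
                    amplitude=amp,
                    pass_level=1,
                    run_start=f,
                    run_end=f + 1,
                )
            )
    return EventRaster(
        events=tuple(events),
        roi_ids=roi_ids,
        n_frames=n_frames,
        sampling_rate=rate,
        session=session,
    )


class TestFrequency:
    def test_six_events_in_two_minutes(self):
        raster = make_raster({0: list(range(0, 60, 10))}, duration_s=120.0)
        per_roi, mean = event_frequency(raster)
        assert mean == pytest.approx(3.0)
        assert per_roi["roi000"] == pytest.approx(3.0)

    def test_no_events_is_zero(self):
        raster = make_raster({}, n_rois=3, duration_s=600.0)
        _, mean = event_frequency(raster)
        assert mean == 0.0

    def test_ten_minute_session(self):
        raster = make_raster({0: list(range(7))}, duration_s=600.0)
        _, mean = event_frequency(raster)
        assert mean == pytest.approx(0.7)

    def test_silent_rois_pull_the_cell_weighted_mean_down(self):
        raster = make_raster({0: [1, 2, 3]}, n_rois=3, duration_s=60.0)
        per_roi, mean = event_frequency(raster)
        assert per_roi.tolist() == [3.0, 0.0, 0.0]
        assert mean == pytest.approx(1.0)


class TestAmplitude:
    def test_mean_of_two(self):
        r1 = make_raster({0: [5]}, amp=0.5, duration_s=60.0)
        r2 = make_raster({0: [9]}, amp=1.5, duration_s=60.0)
        merged = EventRaster(
            events=r1.events + r2.events,
            roi_ids=("roi000",),
            n_frames=10,
            sampling_rate=5.0,
        )
        assert mean_amplitude(merged) == pytest.approx(1.0)

    def test_single_event_returns_its_amplitude(self):
        raster = make_raster({0: [3]}, amp=0.42, duration_s=60.0)
        assert mean_amplitude(raster) == pytest.approx(0.42)

    def test_empty_raster_is_missing_not_zero(self):
        raster = make_raster({}, duration_s=60.0)
        assert mean_amplitude(raster) is None
        m = session_metrics(raster)
        assert m.mean_amplitude is None
        with pytest.raises(ValueError, match="missing"):
            SessionMetrics(0.0, 0.0, 0.0, n_rois=1, n_events=0)


class TestSynchronicity:
    @pytest.mark.parametrize("method", ["cluster", "frame"])
    def test_two_coincident_one_lone_peak(self, method):
        raster = make_raster({0: [10], 1: [10], 2: [20]})
        assert synchronicity(raster, 0, method) == pytest.approx(50.0)

    @pytest.mark.parametrize("method", ["cluster", "frame"])
    def test_full_coincidence_is_100(self, method):
        raster = make_raster({i: [15] for i in range(5)})
        assert synchronicity(raster, 0, method) == pytest.approx(100.0)

    @pytest.mark.parametrize("method", ["cluster", "frame"])
    def test_no_events_is_zero(self, method):
        raster = make_raster({}, n_rois=4)
        assert synchronicity(raster, 0, method) == 0.0

    def test_window_tolerance_captures_one_frame_jitter(self):
        raster = make_raster({0: [10], 1: [12], 2: [8]})
        assert synchronicity(raster, 0, "cluster") < 100.0
        assert synchronicity(raster, 1, "cluster") == pytest.approx(100.0)

    def test_adding_coincident_event_never_decreases_frame_summary(self):
        before = make_raster({0: [10], 1: [20]}, n_rois=3)
        after = make_raster({0: [10], 1: [20], 2: [10]}, n_rois=3)
        assert synchronicity(after, 0, "frame") >= synchronicity(
            before, 0, "frame"
        )

    def test_bounded_in_0_100(self, rng):
        for _ in range(20):
            peaks = {
                i: list(
                    np.unique(rng.integers(0, 50, rng.integers(0, 6)))
                )
                for i in range(4)
            }
            raster = make_raster(peaks, n_rois=4)
            for method in ("cluster", "frame"):
                s = synchronicity(raster, 1, method)
                assert 0.0 <= s <= 100.0


class TestSessionBundle:
    def test_empty_session(self):
        m = session_metrics(make_raster({}, n_rois=2, duration_s=600.0))
        assert (m.synchronicity_pct, m.frequency_per_min, m.n_events) == (
            0.0,
            0.0,
            0,
        )
        assert m.mean_amplitude is None

    def test_single_roi_single_event(self):
        m = session_metrics(
            make_raster({0: [5]}, duration_s=120.0, amp=0.33)
        )
        assert m.synchronicity_pct == pytest.approx(100.0)
        assert m.frequency_per_min == pytest.approx(0.5)
        assert m.mean_amplitude == pytest.approx(0.33)

    def test_invariant_under_roi_reordering(self):
        a = make_raster({0: [10, 30], 1: [10]}, n_rois=2, duration_s=60.0)
        b = make_raster({1: [10, 30], 0: [10]}, n_rois=2, duration_s=60.0)
        ma, mb = session_metrics(a), session_metrics(b)
        assert ma.synchronicity_pct == mb.synchronicity_pct
        assert ma.frequency_per_min == mb.frequency_per_min
        assert ma.mean_amplitude == mb.mean_amplitude


def _metrics(animal, day, phase, freq, rep=0, sync=10.0, amp=0.3):
    return SessionMetrics(
        synchronicity_pct=sync,
        frequency_per_min=freq,
        mean_amplitude=amp,
        n_rois=10,
        n_events=int(freq * 10),
        session=SessionInfo(animal, day, phase, 600.0, rep),
    )


class TestTrajectory:
    def test_baseline_normalisation(self):
        sessions = [
            _metrics("m1", 1, "baseline", 2.0),
            _metrics("m1", 3, "baseline", 2.0),
            _metrics("m1", 5, "stimulation", 1.0),
        ]
        traj = build_trajectory(sessions, normalize_baseline=True)
        freq = traj[traj["metric"] == "frequency_per_min"]
        assert freq["normalized_value"].tolist() == [100.0, 100.0, 50.0]

    def test_single_session(self):
        traj = build_trajectory([_metrics("m1", 1, "baseline", 1.0)])
        assert set(traj["day"]) == {1}
        assert len(traj) == 3  # one row per metric

    def test_days_sorted_within_animal(self):
        sessions = [
            _metrics("m1", 5, "stimulation", 1.0),
            _metrics("m1", 1, "baseline", 2.0),
        ]
        traj = build_trajectory(sessions)
        assert all(
            days == [1, 5]
            for days in traj.groupby("metric")["day"].apply(list)
        )

    def test_replicates_averaged_per_day(self):
        sessions = [
            _metrics("m1", 1, "baseline", 2.0, rep=0),
            _metrics("m1", 1, "baseline", 4.0, rep=1),
        ]
        traj = build_trajectory(sessions)
        freq = traj[traj["metric"] == "frequency_per_min"]
        assert freq["value"].tolist() == [3.0]

    def test_duplicate_session_rejected(self):
        sessions = [
            _metrics("m1", 1, "baseline", 2.0),
            _metrics("m1", 1, "baseline", 2.5),
        ]
        with pytest.raises(ValueError, match="duplicate"):
            build_trajectory(sessions)

    def test_phase_regression_rejected(self):
        sessions = [
            _metrics("m1", 1, "stimulation", 2.0),
            _metrics("m1", 3, "baseline", 2.0),
        ]
        with pytest.raises(ValueError, match="phases out of order"):
            build_trajectory(sessions)


class TestPairedComparison:
    def test_closed_form_example(self):
        # d = {1, 2, 0}: t = sqrt(3), df = 2; two-sided p from the df=2
        # Student CDF F(t) = 1/2 + t / (2*sqrt(2 + t^2)):
        # p = 2*(1 - (1/2 + sqrt(3)/(2*sqrt(5)))) = 0.225403...
        res = paired_comparison([1.0, 2.0, 3.0], [2.0, 4.0, 3.0])
        assert res.t_statistic == pytest.approx(np.sqrt(3.0))
        assert res.df == 2
        assert res.p_value == pytest.approx(0.2254033, abs=1e-6)
        assert res.mean_difference == pytest.approx(1.0)

    def test_matches_scipy_ttest_rel(self, rng):
        a = rng.normal(1.0, 0.3, 8)
        b = a + rng.normal(0.2, 0.2, 8)
        res = paired_comparison(a, b)
        ref = stats.ttest_rel(b, a)
        assert res.t_statistic == pytest.approx(ref.statistic)
        assert res.p_value == pytest.approx(ref.pvalue)

    def test_swapping_days_negates_t_keeps_p(self):
        a, b = [1.0, 2.0, 3.0], [2.0, 4.0, 3.0]
        fwd = paired_comparison(a, b)
        rev = paired_comparison(b, a)
        assert rev.t_statistic == pytest.approx(-fwd.t_statistic)
        assert rev.p_value == pytest.approx(fwd.p_value)

    def test_zero_variance_differences_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            paired_comparison([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            paired_comparison([1.0], [2.0])
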