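"""Rupture-event detector tests: trivial traces, injected events, invariants."""

import numpy as np
import pytest

from nucmorph import rupture, synthetic
from nucmorph.rupture import DetectionParams, ReporterTrace


def _trace(nuc, cyt, dt=2.0, nes_nuc=None, nes_cyt=None, mitosis=None, cell_id="c0"):
    nuc = np.asarray(nuc, float)
    n = nuc.size
    return ReporterTrace(
        cell_id=cell_id,
        time=np.arange(n) * dt,
        nls_nuc=nuc,
        nls_cyt=np.asarray(cyt, float),
        nes_nuc=np.asarray(nes_nuc, float) if nes_nuc is not None else np.full(n, 10.0),
        nes_cyt=np.asarray(nes_cyt, float) if nes_cyt is not None else np.full(n, 30.0),
        mitosis=mitosis,
    )


def _event_trace(n=60, start=20, stop=28, base=3.0, cyt=20.0, noise=0.0, seed=0):
    """Square-ish rupture: ratio drops from base to ~1, then re-accumulates."""
    rng = np.random.default_rng(seed)
    ratio = np.full(n, base)
    ratio[start:stop] = 1.0
    for k in range(stop, n):  # exponential recovery, tau ~ 1.5 frames
        ratio[k] = base - (base - 1.0) * np.exp(-(k - stop + 1) / 1.5)
    nuc = ratio * cyt
    if noise:
        nuc = nuc * np.exp(rng.normal(0, noise, n))
    return _trace(nuc, np.full(n, cyt))


class TestRatioTrace:
    def test_equal_channels_give_unit_ratio(self):
        t = _trace(np.full(30, 7.0), np.full(30, 7.0))
        ratio, baseline = rupture.compute_ratio_trace(t)
        assert np.allclose(ratio, 1.0)
        assert baseline == pytest.approx(1.0)

    def test_constant_ratio_baseline(self):
        t = _trace(np.full(30, 60.0), np.full(30, 20.0))
        ratio, baseline = rupture.compute_ratio_trace(t)
        assert baseline == pytest.approx(3.0)

    def test_zero_cytoplasm_rejected(self):
        cyt = np.full(30, 5.0)
        cyt[10:14] = 0.0
        t = ReporterTrace("c", np.arange(30) * 2.0, np.ones(30), cyt,
                          np.ones(30), np.ones(30))
        with pytest.raises(ValueError, match="cytoplasmic"):
            rupture.compute_ratio_trace(t)

    def test_baseline_excludes_event_frames(self):
        t = _event_trace()
        _, baseline = rupture.compute_ratio_trace(t)
        assert baseline == pytest.approx(3.0, rel=0.02)


class TestDetector:
    def test_constant_trace_yields_no_events(self):
        t = _trace(np.full(60, 60.0), np.full(60, 20.0))
        assert rupture.detect_rupture_events(t) == []

    def test_single_event_detected_with_correct_extent(self):
        t = _event_trace(start=20, stop=28)
        events = rupture.detect_rupture_events(t)
        assert len(events) == 1
        ev = events[0]
        assert not ev.truncated
        assert ev.start == pytest.approx(40.0, abs=4.0)  # frame 20 at dt=2
        # recovery begins at frame 28 (56 min); end within a few frames
        assert 56.0 <= ev.end <= 66.0
        assert ev.depth == pytest.approx(2.0 / 3.0, abs=0.05)

    def test_injected_synthetic_event_duration(self):
        """Generator ground truth: duration recovered within one frame-ish."""
        spec = synthetic.TraceSpec(n_cells=60, event_rate=0.05, noise_cv=0.02, seed=8)
        traces, gt = synthetic.generate_reporter_traces(spec)
        by_id = {t.cell_id: t for t in traces}
        durs, true_durs = [], []
        for _, ev in gt.iterrows():
            if ev.recovery_onset > 230.0:
                continue  # truncated by the recording window
            found = rupture.detect_rupture_events(by_id[ev.cell_id])
            assert len(found) >= 1
            durs.append(found[0].duration)
            true_durs.append(ev.recovery_onset - ev.open_time)
        assert len(durs) >= 5
        errors = np.array(durs) - np.array(true_durs)
        assert abs(np.median(errors)) <= 2.0

    def test_event_inside_mitosis_window_discarded(self):
        t = _event_trace(start=20, stop=28)
        mito = np.zeros(60, bool)
        mito[18:32] = True
        t2 = _trace(t.nls_nuc, t.nls_cyt, mitosis=mito)
        assert rupture.detect_rupture_events(t2) == []

    def test_slow_decline_is_not_sudden(self):
        # ratio drifts from 3 to 1 over 30 frames: no step passes d_step
        ratio = np.r_[np.full(10, 3.0), np.linspace(3.0, 1.0, 30), np.full(20, 1.0)]
        t = _trace(ratio * 20.0, np.full(60, 20.0))
        assert rupture.detect_rupture_events(t) == []

    def test_truncated_event_flagged(self):
        ratio = np.full(40, 3.0)
        ratio[30:] = 1.0  # event never recovers before the trace ends
        t = _trace(ratio * 20.0, np.full(40, 20.0))
        events = rupture.detect_rupture_events(t)
        assert len(events) == 1
        assert events[0].truncated

    def test_detection_invariant_to_channel_scaling(self):
        t = _event_trace(noise=0.02, seed=3)
        scaled = _trace(t.nls_nuc * 37.0, t.nls_cyt * 37.0)
        a = rupture.detect_rupture_events(t)
        b = rupture.detect_rupture_events(scaled)
        assert [(e.start, e.end) for e in a] == [(e.start, e.end) for e in b]

    def test_raising_dmin_never_increases_event_count(self):
        spec = synthetic.depleted_trace_spec(n_cells=60, seed=9)
        traces, _ = synthetic.generate_reporter_traces(spec)
        counts = []
        for d_min in (0.2, 0.3, 0.4, 0.5, 0.6):
            p = DetectionParams(d_min=d_min)
            counts.append(
                sum(len(rupture.detect_rupture_events(t, p)) for t in traces)
            )
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_nes_influx_crossvalidates_events(self):
        spec = synthetic.TraceSpec(n_cells=80, event_rate=0.05, noise_cv=0.02, seed=12)
        traces, gt = synthetic.generate_reporter_traces(spec)
        events = [e for t in traces for e in rupture.detect_rupture_events(t)]
        assert len(events) > 0
        assert np.mean([e.crossvalidated for e in events]) >= 0.8

    def test_sensitivity_and_false_positives(self):
        """Detector quality on labelled synthetic cohorts."""
        # sensitivity on clearly resolvable events
        spec = synthetic.depleted_trace_spec(n_cells=150, seed=21)
        traces, gt = synthetic.generate_reporter_traces(spec)
        by_id = {t.cell_id: t for t in traces}
        found = 0
        resolvable = 0
        for _, ev in gt.iterrows():
            if ev.open_time > 230.0:
                continue
            resolvable += 1
            events = rupture.detect_rupture_events(by_id[ev.cell_id])
            if any(e.start <= ev.recovery_onset and e.end >= ev.open_time for e in events):
                found += 1
        assert resolvable >= 15
        assert found / resolvable >= 0.95
        # false positives: >500 cell-hours of event-free traces
        spec0 = synthetic.control_trace_spec(n_cells=150, seed=22)
        traces0, _ = synthetic.generate_reporter_traces(spec0)
        fp = sum(len(rupture.detect_rupture_events(t)) for t in traces0)
        assert fp / 600.0 < 0.01


class TestCohortSummary:
    def test_control_cohort_is_event_free(self):
        """83 control cells, 4 h: not a single exchange event."""
        spec = synthetic.control_trace_spec(seed=0)
        traces, _ = synthetic.generate_reporter_traces(spec)
        events = [e for t in traces for e in rupture.detect_rupture_events(t)]
        s = rupture.cohort_event_summary(traces, events)
        assert s.n_cells == 83
        assert s.n_events == 0
        assert s.mean_duration_min is None

    def test_rate_arithmetic(self):
        t = _event_trace(n=121, start=40, stop=45)  # 121 frames x 2 min = 4 h
        ev = rupture.RuptureEvent("c0", start=80.0, end=90.0, depth=0.6)
        s = rupture.cohort_event_summary([t], [ev])
        assert s.events_per_cell_hour == pytest.approx(0.25)
        assert s.mean_duration_min == pytest.approx(10.0)

    def test_unknown_cell_rejected(self):
        t = _event_trace()
        ev = rupture.RuptureEvent("ghost", start=0.0, end=10.0, depth=0.5)
        with pytest.raises(ValueError, match="unknown cell"):
            rupture.cohort_event_summary([t], [ev])

    def test_empty_trace_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            rupture.cohort_event_summary([], [])

    def test_truncated_events_excluded_from_mean_duration(self):
        t = _event_trace(n=121)
        evs = [
            rupture.RuptureEvent("c0", 10.0, 20.0, 0.5),
            rupture.RuptureEvent("c0", 200.0, 240.0, 0.5, truncated=True),
        ]
        s = rupture.cohort_event_summary([t], evs)
        assert s.n_events == 2
        assert s.n_truncated == 1
        assert s.mean_duration_min == pytest.approx(10.0)


class TestTraceRoundTrip:
    def test_dataframe_round_trip(self):
        spec = synthetic.TraceSpec(n_cells=3, event_rate=0.05, seed=5)
        traces, _ = synthetic.generate_reporter_traces(spec)
        import pandas as pd

        df = pd.concat([t.to_dataframe() for t in traces], ignore_index=True)
        back = rupture.traces_from_dataframe(df)
        assert len(back) == 3
        for a, b in zip(traces, back):
            assert np.allclose(a.nls_nuc, b.nls_nuc)
            assert np.array_equal(a.mitosis, b.mitosis)

    def test_trace_validation(self):
        with pytest.raises(ValueError, match="5 frames"):
            ReporterTrace("c", [0, 2], [1, 1], [1, 1], [1, 1], [1, 1])
        with pytest.raises(ValueError, match="uniform"):
            ReporterTrace("c", [0, 2, 3, 7, 9], np.ones(5), np.ones(5),
                          np.ones(5), np.ones(5))
        with pytest.raises(ValueError, match="negative"):
            ReporterTrace("c", [0, 2, 4, 6, 8], [1, 1, -1, 1, 1], np.ones(5),
                          np.ones(5), np.ones(5))
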