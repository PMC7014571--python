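import math

import numpy as np
import pytest

from wormnest.kymo import (
    HeadBendEvent,
    Kymogram,
    LocomotionBouts,
    PeakKymogram,
    build_peak_kymogram,
    compute_bend_angles,
    cycle_periods,
    head_bend_amplitude,
    preprocess_kymogram,
    trace_propagations,
)


def _arc_midline(total_turn, n_frames=3):
    """26 points along a circular arc with the given total turning angle."""
    theta = np.linspace(0.0, total_turn, 25)  # heading of each of 25 segments
    pts = np.zeros((26, 2))
    for i, th in enumerate(theta):
        pts[i + 1] = pts[i] + [np.cos(th), np.sin(th)]
    return np.tile(pts, (n_frames, 1, 1))


class TestBendAngles:
    def test_collinear_gives_zero(self):
        pts = np.zeros((2, 26, 2))
        pts[:, :, 0] = np.arange(26)
        k = compute_bend_angles(pts, 10.0)
        assert np.allclose(k.angles, 0.0)

    def test_single_right_angle(self):
        pts = np.zeros((1, 26, 2))
        pts[0, :13, 0] = np.arange(13)
        pts[0, 13:, 0] = 12.0
        pts[0, 13:, 1] = np.arange(1, 14)
        k = compute_bend_angles(pts, 10.0)
        assert np.isclose(k.angles[0, 11], math.pi / 2)
        other = np.delete(k.angles[0], 11)
        assert np.allclose(other, 0.0)

    @pytest.mark.parametrize("turn", [0.5, -1.2, 2.0])
    def test_arc_turning_shared_equally(self, turn):
        k = compute_bend_angles(_arc_midline(turn), 10.0)
        assert np.allclose(k.angles, turn / 24, atol=1e-9)

    def test_rejects_bad_shapes_and_duplicates(self):
        with pytest.raises(ValueError):
            compute_bend_angles(np.zeros((2, 25, 2)), 10.0)
        pts = _arc_midline(1.0, n_frames=1)
        pts[0, 5] = pts[0, 4]
        with pytest.raises(ValueError):
            compute_bend_angles(pts, 10.0)

    def test_nan_frames_flagged_missing(self):
        pts = _arc_midline(1.0, n_frames=3)
        pts[1, 7] = np.nan
        k = compute_bend_angles(pts, 10.0)
        assert k.missing_mask[1].all() and not k.missing_mask[0].any()


class TestPreprocess:
    def _kym(self, col, fr=10.0):
        ang = np.zeros((len(col), 24))
        ang[:, 0] = col
        return Kymogram(angles=ang, frame_rate_hz=fr)

    def test_short_gap_linearly_bridged(self):
        col = np.zeros(40)
        col[20:] = 1.0
        col[15:20] = np.nan  # 0.5 s gap at 10 Hz between 0 and 1
        k = preprocess_kymogram(self._kym(col), smooth_window_s=0.0)
        assert not k.missing_mask[15:20, 0].any()
        expected = np.interp(np.arange(15, 20), [14, 20], [0.0, 1.0])
        assert np.allclose(k.angles[15:20, 0], expected)

    def test_long_gap_stays_masked(self):
        col = np.zeros(60)
        col[20:40] = np.nan  # 2 s gap
        k = preprocess_kymogram(self._kym(col), smooth_window_s=0.0)
        assert k.missing_mask[20:40, 0].all()

    def test_constant_column_unchanged_by_smoothing(self):
        col = np.full(50, 0.7)
        k = preprocess_kymogram(self._kym(col), smooth_window_s=0.5)
        assert np.allclose(k.angles[:, 0], 0.7)


class TestPeakKymogram:
    def test_sinusoid_alternation_and_large_delta(self):
        t = np.arange(600) / 10.0
        ang = np.zeros((600, 24))
        ang[:, 3] = 0.5 * np.sin(2 * np.pi * 0.5 * t)
        k = Kymogram(angles=ang, frame_rate_hz=10.0)
        pk = build_peak_kymogram(k, 0.3)
        col = pk.values[:, 3]
        nz = col[col != 0]
        assert nz.size >= 500 // 100  # several extrema
        assert np.all(nz[::2] == nz[0])  # alternating
        pk2 = build_peak_kymogram(k, 1.5)  # delta > 2A
        assert np.count_nonzero(pk2.values[:, 3]) == 0

    def test_offset_sinusoid_never_crossing_zero(self):
        t = np.arange(600) / 10.0
        ang = np.zeros((600, 24))
        ang[:, 0] = 1.0 + 0.3 * np.sin(2 * np.pi * 0.5 * t)  # always > 0
        k = Kymogram(angles=ang, frame_rate_hz=10.0)
        pk = build_peak_kymogram(k, 0.3)
        assert np.count_nonzero(pk.values[:, 0] == 1) >= 4
        assert np.count_nonzero(pk.values[:, 0] == -1) >= 4


def _pk_from_peaks(peaks, n_frames=400, fr=10.0):
    """peaks: list of (frame, col0based, sign)."""
    vals = np.zeros((n_frames, 24), dtype=np.int8)
    for f, c, s in peaks:
        vals[f, c] = s
    return PeakKymogram(
        values=vals, frame_rate_hz=fr, deltas=np.full(24, 0.3)
    )


def _forward(n_frames=400):
    return LocomotionBouts(intervals=[(0, n_frames, "forward")])


class TestTracer:
    def test_anterior_cutoff_classifies_head_cast(self):
        peaks = [(10 + 2 * j, j, 1) for j in range(10)]  # cols 1..10
        pk = _pk_from_peaks(peaks)
        evs = trace_propagations(pk, _forward())
        assert len(evs) == 1
        ev = evs[0]
        assert ev.class_label == "head_cast"
        assert ev.final_segment == 10

    def test_full_propagation_reaches_tail(self):
        peaks = [(10 + 2 * j, j, -1) for j in range(24)]
        pk = _pk_from_peaks(peaks)
        evs = trace_propagations(pk, _forward())
        assert evs[0].class_label == "propagated"
        assert evs[0].final_segment == 24
        assert evs[0].termination_reason == "tail_reached"
        assert evs[0].sign == "dorsal"

    def test_reversal_interruption_is_unclassified(self):
        peaks = [(10 + 2 * j, j, 1) for j in range(24)]
        pk = _pk_from_peaks(peaks)
        # reversal begins right after the column-12 peak (frame 32)
        bouts = LocomotionBouts(
            intervals=[(0, 33, "forward"), (33, 400, "reverse")]
        )
        evs = trace_propagations(pk, bouts)
        ev = [e for e in evs if e.bout_label == "forward"][0]
        assert ev.final_segment == 12
        assert ev.termination_reason == "reversal_or_missing"
        assert ev.class_label == "unclassified"

    def test_missing_data_terminates(self):
        peaks = [(10 + 2 * j, j, 1) for j in range(24)]
        pk = _pk_from_peaks(peaks)
        pk.missing_mask = np.zeros((400, 24), dtype=bool)
        pk.missing_mask[31:40, 11] = True  # column #12 masked mid-bend
        evs = trace_propagations(pk, _forward())
        assert evs[0].termination_reason == "reversal_or_missing"
        assert evs[0].class_label == "unclassified"

    def test_opposite_sign_terminates(self):
        peaks = [(10 + 2 * j, j, 1) for j in range(8)]
        peaks.append((26, 8, -1))  # wrong sign in column #9
        pk = _pk_from_peaks(peaks)
        evs = trace_propagations(pk, _forward())
        assert evs[0].termination_reason == "opposite_sign"
        assert evs[0].final_segment == 8
        assert evs[0].class_label == "head_cast"

    def test_two_skipped_columns_allowed_third_not(self):
        peaks = [(10 + 2 * j, j, 1) for j in range(24) if j not in (5, 6)]
        pk = _pk_from_peaks(peaks)
        evs = trace_propagations(pk, _forward())
        assert evs[0].final_segment == 24  # two skips permitted
        peaks = [(10 + 2 * j, j, 1) for j in range(24) if j not in (5, 6, 7)]
        pk = _pk_from_peaks(peaks)
        evs = trace_propagations(pk, _forward())
        assert evs[0].final_segment == 5  # three gaps terminate

    def test_isolated_seed_unclassified(self):
        pk = _pk_from_peaks([(50, 1, 1)])
        evs = trace_propagations(pk, _forward())
        assert evs[0].isolated and evs[0].class_label == "unclassified"

    def test_ten_second_gap_terminates(self):
        peaks = [(10 + 2 * j, j, 1) for j in range(10)]
        peaks.append((10 + 18 + 105, 10, 1))  # col #11 peak 10.5 s later
        pk = _pk_from_peaks(peaks)
        evs = trace_propagations(pk, _forward())
        ev = evs[0]
        assert ev.final_segment == 10
        assert ev.termination_reason == "time_gap"

    def test_reverse_bout_tail_to_head_wave_fully_propagates(self):
        # tail-to-head travel: column j peaks later for smaller j
        peaks = [(10 + 2 * (23 - j), j, 1) for j in range(24)]
        pk = _pk_from_peaks(peaks)
        bouts = LocomotionBouts(intervals=[(0, 400, "reverse")])
        evs = trace_propagations(pk, bouts)
        assert evs[0].bout_label == "reverse"
        assert evs[0].class_label == "propagated"
        assert evs[0].final_segment == 24

    def test_each_peak_assigned_at_most_once(self):
        from wormnest.pipeline import analyze_kymogram
        from wormnest.synthetic import BehaviorSimConfig, gen_kymogram

        kym, bouts, _ = gen_kymogram(
            BehaviorSimConfig(duration_s=120.0, seed=5)
        )
        events, pk, _ = analyze_kymogram(kym, bouts)
        seen = set()
        for ev in events:
            for seg, frame in ev.assigned_peaks:
                key = (ev.bout_label, seg, frame)
                assert key not in seen
                seen.add(key)
            segs = [s for s, _ in ev.assigned_peaks]
            assert segs == sorted(segs) and len(set(segs)) == len(segs)


def _ev(onset_s, label, fr=10.0):
    return HeadBendEvent(
        onset_frame=int(round(onset_s * fr)),
        sign="dorsal",
        class_label=label,
        assigned_peaks=[(2, int(round(onset_s * fr)))],
    )


class TestCyclePeriods:
    def test_headcast_doubling(self):
        evs = [_ev(0.0, "head_cast"), _ev(0.5, "head_cast")]
        assert cycle_periods(evs, "headcast_doubled", 10.0) == [1.0]

    def test_single_event_gives_empty(self):
        assert cycle_periods([_ev(1.0, "head_cast")], "headcast_doubled", 10.0) == []

    def test_propagated_full_ignores_interruption(self):
        evs = [
            _ev(0.0, "propagated"), _ev(1.0, "propagated"),
            _ev(1.4, "head_cast"), _ev(2.0, "propagated"),
        ]
        assert cycle_periods(evs, "propagated_full", 10.0) == [2.0, 2.0]
        # the strict mode is broken by the intervening cast
        assert cycle_periods(evs, "propagated_doubled", 10.0) == [2.0]

    def test_unknown_mode(self):
        with pytest.raises(ValueError):
            cycle_periods([], "bogus", 10.0)


class TestHeadBendAmplitude:
    def test_five_segment_sum(self):
        ang = np.zeros((100, 24))
        ang[50, 1:6] = 0.2
        k = Kymogram(angles=ang, frame_rate_hz=10.0)
        ev = HeadBendEvent(
            onset_frame=50, sign="ventral",
            assigned_peaks=[(s, 50) for s in range(2, 7)],
        )
        amps = head_bend_amplitude(k, [ev])
        assert np.isclose(amps[0], 1.0)

    def test_zero_kymogram(self):
        k = Kymogram(angles=np.zeros((50, 24)), frame_rate_hz=10.0)
        assert head_bend_amplitude(k, []).size == 0
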