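import math

import numpy as np
import pytest

from wormnest.phase import (
    assign_event_phases,
    cycle_peak_fraction,
    detection_allowed_mask,
    hilbert_phase,
    interp_phase,
    polar_skewness_test,
    two_distribution_test,
)

TWO_PI = 2 * math.pi


class TestInterpPhase:
    def test_linear_between_anchors(self):
        ps = interp_phase([0.0, 2.0], [1.0], n_frames=30, frame_rate_hz=10.0)
        for t, expect in [(0.5, math.pi / 2), (1.0, math.pi), (1.5, 1.5 * math.pi)]:
            assert np.isclose(float(ps.at(t)[0]), expect)

    def test_anchor_gets_anchor_phase(self):
        ps = interp_phase([0.0, 2.0], [1.0], n_frames=30, frame_rate_hz=10.0)
        assert float(ps.at(0.0)[0]) == 0.0
        assert np.isclose(float(ps.at(1.0)[0]), math.pi)

    def test_intervening_same_type_peak_ignored(self):
        base = interp_phase([0.0, 2.0], [1.0], 30, 10.0)
        extra = interp_phase([0.0, 0.3, 2.0], [1.0], 30, 10.0)
        t = np.linspace(0.0, 2.0, 21)
        assert np.allclose(base.at(t), extra.at(t))

    def test_one_type_only_all_invalid(self):
        ps = interp_phase([0.0, 1.0, 2.0], [], 30, 10.0)
        assert not ps.valid.any()

    def test_outside_anchored_span_invalid(self):
        ps = interp_phase([1.0, 3.0], [2.0], 50, 10.0)
        assert np.isnan(float(ps.at(0.5)[0]))
        assert np.isnan(float(ps.at(3.5)[0]))


class TestAssignEventPhases:
    def test_first_cast_only_and_context_label(self):
        ps = interp_phase([0.0, 2.0, 4.0], [1.0, 3.0], 60, 10.0)
        samples, dropped = assign_event_phases(
            [0.4, 0.7, 2.5],  # a pair after the first dorsal bend, one later
            ps, "initial_headcast",
            context_times_s=[0.0, 2.0], context_signs=["dorsal", "ventral"],
        )
        assert len(samples) == 2
        assert samples[0].time_s == 0.4
        assert samples[0].kind == "initial_headcast_dorsal"
        assert samples[1].time_s == 2.5
        assert samples[1].kind == "initial_headcast_ventral"

    def test_cast_without_context_dropped(self):
        ps = interp_phase([1.0, 3.0], [2.0], 60, 10.0)
        samples, dropped = assign_event_phases(
            [0.5], ps, "initial_headcast",
            context_times_s=[1.0], context_signs=["dorsal"],
        )
        assert samples == [] and dropped == 1

    def test_generic_kind_samples_every_event(self):
        ps = interp_phase([0.0, 2.0], [1.0], 30, 10.0)
        samples, dropped = assign_event_phases([0.5, 1.5], ps, "first_trough")
        assert [round(s.phase, 3) for s in samples] == [
            round(math.pi / 2, 3), round(1.5 * math.pi, 3)
        ]


class TestHilbertPhase:
    def test_sinusoid_matches_analytic(self):
        fr = 30.0
        t = np.arange(0, 30, 1 / fr)
        x = np.sin(2 * np.pi * 1.0 * t)
        ps = hilbert_phase(x, [(0, t.size)], fr, smooth_window_s=0.15)
        expect = (2 * np.pi * t - np.pi / 2) % TWO_PI
        ok = ps.valid
        dev = np.angle(np.exp(1j * (ps.phase[ok] - expect[ok])))
        assert np.abs(dev).max() < 0.05

    def test_border_cycles_removed(self):
        fr = 30.0
        t = np.arange(0, 10, 1 / fr)
        x = np.sin(2 * np.pi * 1.0 * t)
        ps = hilbert_phase(x, [(0, t.size)], fr, smooth_window_s=0.1)
        assert not ps.valid[:15].any() and not ps.valid[-15:].any()
        assert ps.valid.sum() > 0.5 * t.size

    def test_bouts_are_independent(self):
        fr = 30.0
        t = np.arange(0, 20, 1 / fr)
        x = np.sin(2 * np.pi * 1.0 * t)
        full = hilbert_phase(x, [(0, 300), (330, 600)], fr)
        assert not full.valid[300:330].any()
        # each bout analyzed on its own: recompute one bout alone
        solo = hilbert_phase(x, [(330, 600)], fr)
        ok = full.valid & solo.valid
        assert np.allclose(full.phase[ok], solo.phase[ok])

    def test_constant_bout_invalid(self):
        ps = hilbert_phase(np.ones(200), [(0, 200)], 30.0)
        assert not ps.valid.any()


class TestCyclePeakFraction:
    def _ps(self, n_cycles=5, fr=10.0, f=1.0):
        t = np.arange(int(n_cycles / f * fr) + 1) / fr
        phase = (TWO_PI * f * t) % TWO_PI
        valid = np.ones(t.size, dtype=bool)
        from wormnest.phase import PhaseSeries
        return PhaseSeries(phase, valid, fr), t

    def test_event_in_every_cycle(self):
        ps, t = self._ps()
        events = [0.5 + k for k in range(5)]
        assert cycle_peak_fraction(ps, events) == 1.0

    def test_no_events_zero(self):
        ps, _ = self._ps()
        assert cycle_peak_fraction(ps, []) == 0.0

    def test_masked_cycle_excluded_from_denominator(self):
        ps, t = self._ps()
        miss = np.zeros(ps.phase.size, dtype=bool)
        miss[12] = True  # one frame inside the second cycle
        with_mask = cycle_peak_fraction(ps, [0.5], missing_mask=miss)
        without = cycle_peak_fraction(ps, [0.5])
        assert with_mask == pytest.approx(1 / 4)
        assert without == pytest.approx(1 / 5)

    def test_no_complete_cycles_errors(self):
        from wormnest.phase import PhaseSeries
        ps = PhaseSeries(np.zeros(5), np.zeros(5, dtype=bool), 10.0)
        with pytest.raises(ValueError):
            cycle_peak_fraction(ps, [0.1])


class TestDetectionAllowedMask:
    def test_requires_delta_excursion_from_previous_peak(self):
        x = np.array([0.0, 1.0, 0.5, 0.9, 0.0, -1.0])
        allowed = detection_allowed_mask(x, [1], 0.4)
        assert allowed[:1].all()          # before first peak: allowed
        assert not allowed[1]             # at the peak itself: no excursion
        assert allowed[2]                 # 0.5 is 0.5 below the peak
        assert not allowed[3]             # 0.9 is only 0.1 below
        assert allowed[4] and allowed[5]


class TestPolarSkewness:
    def test_concentrated_samples_rejected(self):
        rng = np.random.default_rng(0)
        cycles = [rng.uniform(0, TWO_PI, 40) for _ in range(50)]
        samples = [1.0] * 50  # all mass at one phase
        p = polar_skewness_test(samples, cycles, 10_000, rng=rng)
        assert p <= 1e-3

    def test_null_samples_uniform_p(self):
        rng = np.random.default_rng(1)
        cycles = [rng.uniform(0, TWO_PI, 40) for _ in range(60)]
        ps = []
        for _ in range(60):
            samples = [c[rng.integers(0, c.size)] for c in cycles]
            ps.append(polar_skewness_test(samples, cycles, 400, rng=rng))
        # roughly uniform: median near 0.5, few extremes
        assert 0.3 < np.median(ps) < 0.7

    def test_zero_samples_error(self):
        with pytest.raises(ValueError):
            polar_skewness_test([], [], 100)

    def test_sample_cycle_mismatch_error(self):
        with pytest.raises(ValueError):
            polar_skewness_test([0.5], [np.array([0.1]), np.array([0.2])], 100)


class TestTwoDistribution:
    def test_subsample_gives_uniformish_p(self):
        rng = np.random.default_rng(2)
        big = rng.uniform(0, TWO_PI, 400)
        ps = []
        for _ in range(200):
            sub = rng.choice(big, 60, replace=False)
            ps.append(two_distribution_test(big, sub, 500, rng=rng))
        assert 0.4 <= np.median(ps) <= 0.6

    def test_disjoint_supports_rejected(self):
        rng = np.random.default_rng(3)
        big = rng.uniform(0.0, 1.0, 120)
        small = rng.uniform(4.0, 5.0, 40)
        assert two_distribution_test(big, small, 2000, rng=rng) <= 1e-3

    def test_small_larger_than_large_rejected(self):
        with pytest.raises(ValueError):
            two_distribution_test([0.1] * 3, [0.2] * 5, 100)


class TestCrossMethodConsistency:
    def test_interp_and_hilbert_agree_on_clean_sinusoid(self):
        fr = 30.0
        f = 0.5
        t = np.arange(0, 40, 1 / fr)
        # ventral-positive angle: dorsal peak (minimum) at phase 0
        x = -0.5 * np.cos(TWO_PI * f * t)
        dorsal = t[np.isclose(t % (1 / f), 0.0, atol=1e-9)]
        ventral = dorsal + 1.0 / (2 * f)
        ventral = ventral[ventral < t[-1]]
        pi_ = interp_phase(dorsal, ventral, t.size, fr)
        ph = hilbert_phase(x, [(0, t.size)], fr, smooth_window_s=0.2,
                           convention_offset=math.pi)
        ok = pi_.valid & ph.valid
        dev = np.angle(np.exp(1j * (pi_.phase[ok] - ph.phase[ok])))
        assert np.abs(dev).max() < 0.3
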