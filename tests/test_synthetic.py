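import math

import numpy as np
import pytest

from wormnest.synthetic import (
    BehaviorSimConfig,
    CouplingSpec,
    NeuralSimConfig,
    NeuronSpec,
    gen_event_trains,
    gen_kymogram,
    gen_traces,
)


class TestGenKymogram:
    def test_deterministic(self):
        cfg = BehaviorSimConfig(duration_s=60.0, seed=9)
        k1, b1, g1 = gen_kymogram(cfg)
        k2, b2, g2 = gen_kymogram(cfg)
        assert np.array_equal(k1.angles, k2.angles)
        assert b1.intervals == b2.intervals
        assert g1.cast_initiation_phases == g2.cast_initiation_phases

    def test_pure_wave_all_bends_propagated(self):
        cfg = BehaviorSimConfig(
            duration_s=120.0, noise_sd_rad=0.0, reversal_rate_hz=0.0,
            headcast_attempt_rate_hz=0.0, seed=1,
        )
        _, _, gt = gen_kymogram(cfg)
        assert gt.bends and all(
            b.class_label == "propagated" and b.extent_segment == 24
            for b in gt.bends
        )

    @pytest.mark.parametrize("gate", [(0.0, math.pi), (0.5, 2.0)])
    def test_gate_enforced_by_construction(self, gate):
        cfg = BehaviorSimConfig(
            duration_s=900.0, wave_freq_hz=0.25, noise_sd_rad=0.0,
            reversal_rate_hz=0.0, headcast_attempt_rate_hz=3.0,
            headcast_gate=gate, seed=2,
        )
        _, _, gt = gen_kymogram(cfg)
        phases = np.array(gt.cast_initiation_phases)
        assert phases.size >= 20
        assert np.all((phases >= gate[0]) & (phases < gate[1]))

    def test_casts_suppressed_during_reversals(self):
        cfg = BehaviorSimConfig(
            duration_s=600.0, wave_freq_hz=0.25, headcast_attempt_rate_hz=2.0,
            reversal_rate_hz=0.05, reversal_duration_s=10.0, seed=3,
        )
        _, _, gt = gen_kymogram(cfg)
        casts = [b for b in gt.bends if b.class_label == "head_cast"]
        assert casts
        for b in casts:
            assert b.bout_label == "forward"
            for s, e in gt.reversal_intervals_s:
                assert not (s <= b.onset_s < e)

    def test_rejects_invalid_config(self):
        with pytest.raises(ValueError):
            gen_kymogram(BehaviorSimConfig(wave_freq_hz=-1.0))
        with pytest.raises(ValueError):
            gen_kymogram(BehaviorSimConfig(headcast_extent_segment=20))
        with pytest.raises(ValueError):
            gen_kymogram(BehaviorSimConfig(noise_sd_rad=float("nan")))

    def test_fixed_rate_override(self):
        cfg = BehaviorSimConfig(
            duration_s=600.0, wave_freq_hz=0.25, noise_sd_rad=0.0,
            reversal_rate_hz=0.0, headcast_rate_per_cycle=0.0, seed=4,
        )
        _, _, gt = gen_kymogram(cfg)
        assert not gt.cast_initiation_phases


class TestGenTraces:
    def test_reverse_silent_neuron_events_in_forward_only(self):
        cfg = NeuralSimConfig(
            duration_s=2000.0,
            neurons=[NeuronSpec("N", rate_forward_hz=0.05, rate_reverse_hz=0.0)],
            seed=1,
        )
        _, gt = gen_traces(cfg)
        fwd = [(s, e) for s, e, lab in gt.state_intervals_s if lab == "forward"]
        for t in gt.event_times["N"]:
            assert any(s <= t < e for s, e in fwd)

    def test_coupling_lag_exact_without_jitter(self):
        cfg = NeuralSimConfig(
            duration_s=2000.0,
            neurons=[
                NeuronSpec("A", rate_forward_hz=0.03),
                NeuronSpec("B", coupled_to="A", lag_s=15.0, jitter_s=0.0),
            ],
            seed=2,
        )
        _, gt = gen_traces(cfg)
        a, b = gt.event_times["A"], gt.event_times["B"]
        expected = a + 15.0
        expected = expected[(expected >= 0) & (expected < 2000.0)]
        assert np.allclose(np.sort(b), np.sort(expected))

    def test_no_bleach_no_events_constant_trace(self):
        cfg = NeuralSimConfig(
            duration_s=300.0,
            neurons=[NeuronSpec("N", rate_forward_hz=0.0, rate_reverse_hz=0.0)],
            bleach_tau_s=np.inf, noise_sd=0.0, seed=3,
        )
        ts, _ = gen_traces(cfg)
        assert np.allclose(ts.F[0], ts.F[0, 0])

    def test_bleach_multiplies_exponential(self):
        cfg = NeuralSimConfig(
            duration_s=300.0,
            neurons=[NeuronSpec("N", rate_forward_hz=0.0, rate_reverse_hz=0.0)],
            bleach_tau_s=150.0, noise_sd=0.0, seed=3,
        )
        ts, _ = gen_traces(cfg)
        t = np.arange(ts.n_frames) / cfg.frame_rate_hz
        assert np.allclose(ts.F[0], np.exp(-t / 150.0))

    def test_undefined_partner_rejected(self):
        cfg = NeuralSimConfig(
            neurons=[NeuronSpec("B", coupled_to="missing")], seed=0
        )
        with pytest.raises(ValueError, match="undefined partner"):
            gen_traces(cfg)

    def test_state_rates_respected_in_expectation(self):
        # rate recovery: counts within 3 standard errors over >= 100 states
        cfg = NeuralSimConfig(
            duration_s=20000.0, mean_forward_s=100.0, mean_reverse_s=60.0,
            neurons=[NeuronSpec("N", rate_forward_hz=0.05, rate_reverse_hz=0.01)],
            seed=5,
        )
        _, gt = gen_traces(cfg)
        for lab, rate in (("forward", 0.05), ("reverse", 0.01)):
            ivs = [(s, e) for s, e, l in gt.state_intervals_s if l == lab]
            assert len(ivs) >= 100
            total = sum(e - s for s, e in ivs)
            n = sum(
                int(np.count_nonzero(
                    (gt.event_times["N"] >= s) & (gt.event_times["N"] < e)
                ))
                for s, e in ivs
            )
            mu = rate * total
            assert abs(n - mu) <= 3 * math.sqrt(mu)


class TestGenEventTrains:
    def test_deterministic(self, toy_states):
        p1, _ = gen_event_trains(3, CouplingSpec(), toy_states, seed=7)
        p2, _ = gen_event_trains(3, CouplingSpec(), toy_states, seed=7)
        for (a1, b1), (a2, b2) in zip(p1, p2):
            assert np.array_equal(a1, a2) and np.array_equal(b1, b2)

    def test_full_coupling_zero_lag_copies_train(self, toy_states):
        pairs, coupled = gen_event_trains(
            2, CouplingSpec(fraction=1.0, lag_s=0.0), toy_states, seed=1
        )
        assert coupled == [0, 1]
        for ref, tgt in pairs:
            assert np.array_equal(ref, tgt)

    def test_zero_coupling_trains_distinct(self, toy_states):
        pairs, coupled = gen_event_trains(
            2, CouplingSpec(fraction=0.0), toy_states, seed=1
        )
        assert coupled == []
        ref, tgt = pairs[0]
        assert not np.array_equal(ref, tgt)

    def test_negative_rate_rejected(self, toy_states):
        with pytest.raises(ValueError):
            gen_event_trains(1, CouplingSpec(), toy_states, rate_hz=-0.1)

    def test_events_inside_states(self, toy_states):
        pairs, _ = gen_event_trains(
            2, CouplingSpec(fraction=0.5, lag_s=15.0), toy_states, seed=2
        )
        for ref, tgt in pairs:
            for t in np.concatenate([ref, tgt]):
                assert any(s <= t < e for s, e in toy_states)
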