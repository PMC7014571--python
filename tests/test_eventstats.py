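import numpy as np
import pytest
from statsmodels.stats.multitest import multipletests

from wormnest.eventstats import (
    EventTrain,
    bhy_correct,
    covariogram,
    ipi_randomness_test,
    raw_crosscorrelogram,
)
from wormnest.synthetic import CouplingSpec, gen_event_trains

FR = 3.0


def brute_force_crosscorrelogram(ref, tgt, states, fr, bin_s=10.0, max_lag=60.0):
    """Frame-enumeration oracle for the raw cross-correlogram."""
    edges = np.arange(-max_lag, max_lag + bin_s / 2, bin_s)
    counts = np.zeros(edges.size - 1)
    avail = np.zeros(edges.size - 1)
    for s, e in states:
        r_in = [r for r in ref if s <= r < e]
        t_in = [t for t in tgt if s <= t < e]
        frames = [i / fr for i in range(int(np.ceil(s * fr - 1e-9)),
                                        int(np.ceil(e * fr - 1e-9)))]
        for r in r_in:
            for t in t_in:
                lag = t - r
                for b in range(edges.size - 1):
                    if edges[b] <= lag < edges[b + 1]:
                        counts[b] += 1
            for ft in frames:
                lag = ft - r
                for b in range(edges.size - 1):
                    if edges[b] <= lag < edges[b + 1]:
                        avail[b] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(avail > 0, counts / avail, np.nan)
    return freq, counts, avail


class TestRawCrosscorrelogram:
    def test_identical_trains_mass_at_zero_lag(self, toy_states):
        times = np.array([10.0, 40.0, 70.0, 150.0, 190.0])
        ref = EventTrain(times, "a", FR)
        tgt = EventTrain(times, "b", FR)
        freq, counts, avail, edges = raw_crosscorrelogram(ref, tgt, toy_states)
        zero_bin = np.searchsorted(edges, 0.0, side="right") - 1
        assert counts[zero_bin] == times.size
        assert freq[zero_bin] == counts[zero_bin] / avail[zero_bin]

    def test_shifted_train_lands_in_lag_bin(self, toy_states):
        ref_t = np.array([10.0, 120.0, 230.0])
        tgt_t = ref_t + 15.0
        freq, counts, _, edges = raw_crosscorrelogram(
            EventTrain(ref_t, "a", FR), EventTrain(tgt_t, "b", FR), toy_states
        )
        b = np.searchsorted(edges, 15.0) - 1
        assert edges[b] == 10.0 and counts[b] == 3

    def test_matches_bruteforce_on_toy_state(self):
        # one 100 s state; a reference peak 5 s before the state end makes
        # the far positive-lag bins run out of available frames
        states = [(0.0, 100.0)]
        ref = np.array([20.0, 95.0])
        tgt = np.array([10.0, 30.0, 60.0, 92.0])
        got_f, got_c, got_a, _ = raw_crosscorrelogram(
            EventTrain(ref, "a", FR), EventTrain(tgt, "b", FR), states
        )
        exp_f, exp_c, exp_a = brute_force_crosscorrelogram(
            ref, tgt, states, FR
        )
        assert np.array_equal(got_c, exp_c)
        assert np.array_equal(got_a, exp_a)
        assert np.allclose(got_f, exp_f, equal_nan=True)

    def test_empty_reference_rejected(self, toy_states):
        with pytest.raises(ValueError):
            raw_crosscorrelogram(
                EventTrain(np.array([]), "a", FR),
                EventTrain(np.array([10.0]), "b", FR),
                toy_states,
            )


class TestCovariogram:
    def test_planted_coupling_detected_in_correct_bin(self, toy_states):
        pairs, _ = gen_event_trains(
            2, CouplingSpec(fraction=0.8, lag_s=15.0), toy_states,
            rate_hz=0.04, frame_rate_hz=FR, seed=5,
        )
        rng = np.random.default_rng(0)
        for ref, tgt in pairs:
            cov = covariogram(
                EventTrain(ref, "a", FR), EventTrain(tgt, "b", FR),
                toy_states, 2000, rng=rng,
            )
            assert cov.sign == "positive"
            assert cov.p_value < 0.05
            assert cov.bin_edges[cov.extremum_bin] == 10.0

    def test_independent_pair_not_significant(self, toy_states):
        pairs, _ = gen_event_trains(
            4, CouplingSpec(), toy_states, rate_hz=0.04,
            frame_rate_hz=FR, seed=11,
        )
        rng = np.random.default_rng(1)
        ps = [
            covariogram(
                EventTrain(r, "a", FR), EventTrain(t, "b", FR),
                toy_states, 2000, rng=rng,
            ).p_value
            for r, t in pairs
        ]
        assert not bhy_correct(ps).any()

    def test_low_power_pair_flagged(self, toy_states):
        cov = covariogram(
            EventTrain(np.array([10.0, 30.0]), "a", FR),
            EventTrain(np.array([50.0]), "b", FR),
            toy_states, 500, seed=0,
        )
        assert cov.low_power and cov.p_value == 1.0

    def test_shuffle_corrector_converges(self, toy_states):
        """Mean resampled correlogram approaches the flat chance level."""
        pairs, _ = gen_event_trains(
            1, CouplingSpec(), toy_states, rate_hz=0.05,
            frame_rate_hz=FR, seed=3,
        )
        ref, tgt = pairs[0]

        def corrector(n_res, seed):
            return covariogram(
                EventTrain(ref, "a", FR), EventTrain(tgt, "b", FR),
                toy_states, n_res, seed=seed,
            ).resampled_mean

        truth = corrector(30_000, 99)
        ok = np.isfinite(truth)
        devs = [
            np.nanmax(np.abs(corrector(n, 42)[ok] - truth[ok]))
            for n in (100, 1000, 10_000)
        ]
        assert devs[2] < devs[0]

    def test_symmetry_under_train_swap(self):
        # shared single state: cov(a,b) at +L mirrors cov(b,a) at -L
        states = [(0.0, 200.0)]
        ref = np.array([20.0, 80.0, 140.0])
        tgt = np.array([35.0, 95.0, 155.0])
        f_ab, c_ab, *_ = raw_crosscorrelogram(
            EventTrain(ref, "a", FR), EventTrain(tgt, "b", FR), states
        )
        f_ba, c_ba, *_ = raw_crosscorrelogram(
            EventTrain(tgt, "b", FR), EventTrain(ref, "a", FR), states
        )
        assert np.array_equal(c_ab, c_ba[::-1])


class TestBhy:
    def test_single_small_p_significant(self):
        assert bhy_correct([0.01], alpha=0.05).tolist() == [True]

    def test_all_ones_none_significant(self):
        assert not bhy_correct([1.0] * 10).any()

    def test_matches_direct_inequality_and_statsmodels(self):
        pvals = [0.001, 0.01, 0.03, 0.9]
        got = bhy_correct(pvals, alpha=0.05)
        # direct step-up evaluation with c(4) = 25/12
        m, c_m = 4, 25.0 / 12.0
        order = np.argsort(pvals)
        passed = [
            pvals[order[i]] <= (i + 1) * 0.05 / (m * c_m) for i in range(m)
        ]
        k = max([i for i, p in enumerate(passed) if p], default=-1)
        direct = np.zeros(m, dtype=bool)
        if k >= 0:
            direct[order[:k + 1]] = True
        assert np.array_equal(got, direct)
        sm = multipletests(pvals, alpha=0.05, method="fdr_by")[0]
        assert np.array_equal(got, sm)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_statsmodels_oracle_random_vectors(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(0, 1, 30) ** 3
        for alpha in (0.01, 0.05, 0.2):
            assert np.array_equal(
                bhy_correct(p, alpha),
                multipletests(p, alpha=alpha, method="fdr_by")[0],
            )

    def test_flags_monotone_in_alpha(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(0, 1, 40) ** 2
        prev = np.zeros(40, dtype=bool)
        for alpha in (0.01, 0.05, 0.1, 0.3):
            cur = bhy_correct(p, alpha)
            assert np.all(prev <= cur)
            prev = cur

    def test_empty_input(self):
        assert bhy_correct([]).size == 0

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bhy_correct([0.5, 1.2])


class TestIpiRandomness:
    def test_regular_train_strongly_rejected(self, toy_states):
        reg = np.concatenate(
            [np.arange(s + 5, e - 5, 10.0) for s, e in toy_states]
        )
        p = ipi_randomness_test(reg, toy_states, FR, 10_000, seed=1)
        assert p <= 1e-3

    def test_single_event_per_state_errors(self, toy_states):
        times = np.array([s + 50.0 for s, _ in toy_states])
        with pytest.raises(ValueError, match="inter-peak"):
            ipi_randomness_test(times, toy_states, FR, 500, seed=0)

    def test_poisson_null_not_rejected_typically(self, toy_states):
        rng = np.random.default_rng(5)
        rej = 0
        n_sim = 40
        for i in range(n_sim):
            pairs, _ = gen_event_trains(
                1, CouplingSpec(), toy_states, rate_hz=0.05,
                frame_rate_hz=FR, seed=900 + i,
            )
            try:
                p = ipi_randomness_test(pairs[0][0], toy_states, FR, 500, rng=rng)
            except ValueError:
                continue
            rej += p < 0.05
        assert rej <= 7  # ~5% expected; binomial(40, .05) rarely exceeds 7
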