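"""Covariogram statistics for sparse calcium-event trains.

Standard cross-correlation misbehaves on sparse data: two neurons with one
or two transients per forward command state can show large spurious
correlations.  Covariograms instead accumulate, for every reference-neuron
peak, the lags of all target-neuron peaks within the same forward command
state into 10 s bins, normalize each bin by the number of frames in which a
peak could have occurred (which varies with state duration), and subtract
the mean of many resampled cross-correlograms in which the target's peak
times are redrawn uniformly within each state (the shuffle corrector).  The
resampling also yields significance: the p value is the fraction of
resampled covariograms whose extremum is at least as large as the actual
one, with the sign of the relationship set by whether the actual extremum is
a maximum or a minimum.  Multiple comparisons across neuron pairs use the
Benjamini-Hochberg-Yekutieli procedure, valid under arbitrary dependence.

A companion resampling test asks whether a neuron's inter-peak-interval
distribution differs from random placement — the operational definition of
rhythmic (non-random) activity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EventTrain",
    "Covariogram",
    "raw_crosscorrelogram",
    "covariogram",
    "bhy_correct",
    "ipi_randomness_test",
]

DEFAULT_BIN_S = 10.0
DEFAULT_MAX_LAG_S = 60.0
_CHUNK = 2000  # resamples per vectorized block


@dataclass
class EventTrain:
    """Sorted event times (s) for one neuron on a known frame grid."""

    times: np.ndarray
    label: str = ""
    frame_rate_hz: float = 3.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("event times must be strictly increasing")


@dataclass
class Covariogram:
    """Shuffle-corrected cross-correlogram of one neuron pair."""

    bin_edges: np.ndarray          # len n_bins + 1, symmetric about 0 lag
    values: np.ndarray             # chance-subtracted frequencies; NaN = no data
    raw: np.ndarray
    resampled_mean: np.ndarray
    envelope: np.ndarray           # (2, n_bins): 2.5 / 97.5 percentiles
    sign: str                      # "positive" or "negative"
    p_value: float
    extremum_bin: int
    low_power: bool
    n_resamples: int
    seed: int | None = None


def _state_frames(state, fr):
    s, e = state
    i0 = int(np.ceil(s * fr - 1e-9))
    i1 = int(np.ceil(e * fr - 1e-9))
    return i0, i1


def _available_frames(ref_times, states, edges, fr):
    """Per-bin count of frames a target peak could occupy, over all ref peaks."""
    avail = np.zeros(edges.size - 1)
    for st in states:
        s, e = st
        refs = ref_times[(ref_times >= s) & (ref_times < e)]
        for r in refs:
            for b in range(edges.size - 1):
                lo_t = max(s, r + edges[b])
                hi_t = min(e, r + edges[b + 1])
                if hi_t > lo_t:
                    f0 = int(np.ceil(lo_t * fr - 1e-9))
                    f1 = int(np.ceil(hi_t * fr - 1e-9))
                    avail[b] += max(0, f1 - f0)
    return avail


def raw_crosscorrelogram(
    ref: EventTrain,
    tgt: EventTrain,
    states: list[tuple[float, float]],
    bin_s: float = DEFAULT_BIN_S,
    max_lag_s: float = DEFAULT_MAX_LAG_S,
):
    """Frequency of target peaks at lags relative to reference peaks.

    Lags are accumulated within states only, in ``bin_s``-wide bins spanning
    +-``max_lag_s``, then each bin is divided by its available-frame count
    (frames in which a target peak could have fallen, summed over reference
    peaks and states).  Bins with no available frames are NaN.

    Returns
    -------
    (frequencies, counts, available, bin_edges)
    """
    if ref.times.size == 0:
        raise ValueError("empty reference train")
    fr = ref.frame_rate_hz
    edges = np.arange(-max_lag_s, max_lag_s + bin_s / 2, bin_s)
    counts = np.zeros(edges.size - 1)
    for st in states:
        s, e = st
        r = ref.times[(ref.times >= s) & (ref.times < e)]
        g = tgt.times[(tgt.times >= s) & (tgt.times < e)]
        if r.size == 0 or g.size == 0:
            continue
        lags = (g[:, None] - r[None, :]).ravel()
        counts += np.histogram(lags, bins=edges)[0]
    avail = _available_frames(ref.times, states, edges, fr)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(avail > 0, counts / avail, np.nan)
    return freq, counts, avail, edges


def _resampled_counts(ref, tgt, states, edges, fr, n_resamples, rng):
    """Counts of lag bins for resampled target trains, (n_resamples, n_bins)."""
    n_bins = edges.size - 1
    total = np.zeros((n_resamples, n_bins))
    lo, width = edges[0], edges[1] - edges[0]
    for st in states:
        s, e = st
        r = ref.times[(ref.times >= s) & (ref.times < e)]
        n_t = int(np.count_nonzero((tgt.times >= s) & (tgt.times < e)))
        if r.size == 0 or n_t == 0:
            continue
        i0, i1 = _state_frames(st, fr)
        frames = np.arange(i0, i1)
        if frames.size < n_t:
            continue
        done = 0
        while done < n_resamples:
            m = min(_CHUNK, n_resamples - done)
            keys = rng.random((m, frames.size))
            pick = np.argpartition(keys, n_t - 1, axis=1)[:, :n_t]
            times = frames[pick] / fr  # (m, n_t)
            lags = times[:, :, None] - r[None, None, :]
            bi = np.floor((lags - lo) / width).astype(np.int64)
            ok = (bi >= 0) & (bi < n_bins)
            rows = np.broadcast_to(
                np.arange(m)[:, None, None], bi.shape
            )
            flat = rows[ok] * n_bins + bi[ok]
            total[done:done + m] += np.bincount(
                flat, minlength=m * n_bins
            ).reshape(m, n_bins)
            done += m
    return total


def covariogram(
    ref: EventTrain,
    tgt: EventTrain,
    states: list[tuple[float, float]],
    n_resamples: int = 10_000,
    *,
    bin_s: float = DEFAULT_BIN_S,
    max_lag_s: float = DEFAULT_MAX_LAG_S,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> Covariogram:
    """Shuffle-corrected covariogram with resampling significance.

    The covariogram is the raw cross-correlogram minus the mean of
    ``n_resamples`` resampled correlograms in which the target's peak times
    are redrawn uniformly (without replacement, at frame resolution) within
    each forward state.  The relationship sign follows the larger of
    |maximum| and |minimum|; the p value is the fraction of resampled
    covariograms whose corresponding extremum is at least as large in
    magnitude.  Pairs with fewer than 2 events in either train are flagged
    low power with p = 1.
    """
    if n_resamples < 100:
        raise ValueError("n_resamples must be >= 100")
    if rng is None:
        rng = np.random.default_rng(seed)
    fr = ref.frame_rate_hz

    raw, counts, avail, edges = raw_crosscorrelogram(
        ref, tgt, states, bin_s, max_lag_s
    )
    n_bins = edges.size - 1

    def in_states(times):
        return sum(
            int(np.count_nonzero((times >= s) & (times < e))) for s, e in states
        )

    low_power = in_states(ref.times) < 2 or in_states(tgt.times) < 2
    res_counts = _resampled_counts(ref, tgt, states, edges, fr, n_resamples, rng)
    with np.errstate(invalid="ignore", divide="ignore"):
        res_freq = np.where(avail > 0, res_counts / avail, np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        shuffle_corrector = (
            np.nanmean(res_freq, axis=0) if res_freq.size else raw * np.nan
        )
    cov = raw - shuffle_corrector
    res_cov = res_freq - shuffle_corrector

    finite = np.isfinite(cov)
    if not finite.any():
        raise ValueError("covariogram has no bins with available data")
    vmax = np.nanmax(cov)
    vmin = np.nanmin(cov)
    if abs(vmax) >= abs(vmin):
        sign, extremum = "positive", vmax
        ex_bin = int(np.nanargmax(cov))
        res_ex = np.nanmax(res_cov, axis=1)
        p = float(np.mean(res_ex >= extremum))
    else:
        sign, extremum = "negative", vmin
        ex_bin = int(np.nanargmin(cov))
        res_ex = np.nanmin(res_cov, axis=1)
        p = float(np.mean(np.abs(res_ex) >= abs(extremum)))
    if low_power:
        p = 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        env = np.nanpercentile(res_cov, [2.5, 97.5], axis=0)
    return Covariogram(
        bin_edges=edges,
        values=cov,
        raw=raw,
        resampled_mean=shuffle_corrector,
        envelope=env,
        sign=sign,
        p_value=p,
        extremum_bin=ex_bin,
        low_power=low_power,
        n_resamples=n_resamples,
        seed=seed,
    )


def bhy_correct(pvals, alpha: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg-Yekutieli step-up FDR control under dependence.

    Hypothesis i (sorted p ascending) is significant when
    ``p(i) <= i * alpha / (m * c(m))`` with ``c(m) = sum_{k=1..m} 1/k``,
    rejecting all hypotheses up to the largest such i.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    m = p.size
    c_m = np.sum(1.0 / np.arange(1, m + 1))
    order = np.argsort(p, kind="stable")
    thresh = (np.arange(1, m + 1) * alpha) / (m * c_m)
    passed = p[order] <= thresh
    flags = np.zeros(m, dtype=bool)
    if passed.any():
        k = int(np.max(np.flatnonzero(passed)))
        flags[order[: k + 1]] = True
    return flags


def ipi_randomness_test(
    event_times_s,
    states: list[tuple[float, float]],
    frame_rate_hz: float,
    n_resamples: int = 10_000,
    bin_width_s: float = 5.0,
    *,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> float:
    """Resampling test for non-random inter-peak intervals.

    Within each forward state, the same number of peak times is redrawn
    uniformly (frame grid, without replacement); the resampled inter-peak
    intervals are pooled over states and the run is repeated
    ``n_resamples`` times to build the average random IPI histogram.  The
    deviation statistic is the bin-by-bin summed absolute difference from
    that average; the p value is the fraction of resampled IPI
    distributions deviating at least as much as the actual one.

    Raises
    ------
    ValueError
        If no state contains two or more events (no IPIs exist).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    te = np.asarray(event_times_s, dtype=float)
    fr = frame_rate_hz

    per_state = []
    max_dur = 0.0
    for st in states:
        s, e = st
        max_dur = max(max_dur, e - s)
        ev = te[(te >= s) & (te < e)]
        if ev.size >= 2:
            per_state.append((st, ev))
    if not per_state:
        raise ValueError("no inter-peak intervals (need >= 2 events in a state)")

    n_bins = max(1, int(np.ceil(max_dur / bin_width_s)))
    edges = np.arange(n_bins + 1) * bin_width_s

    actual = np.zeros(n_bins)
    for _, ev in per_state:
        ipis = np.diff(np.sort(ev))
        bi = np.clip((ipis / bin_width_s).astype(np.int64), 0, n_bins - 1)
        actual += np.bincount(bi, minlength=n_bins)

    res = np.zeros((n_resamples, n_bins))
    for (st, ev) in per_state:
        i0, i1 = _state_frames(st, fr)
        frames = np.arange(i0, i1)
        n_k = ev.size
        if frames.size < n_k:
            continue
        done = 0
        while done < n_resamples:
            m = min(_CHUNK, n_resamples - done)
            keys = rng.random((m, frames.size))
            pick = np.argpartition(keys, n_k - 1, axis=1)[:, :n_k]
            times = np.sort(frames[pick] / fr, axis=1)
            ipis = np.diff(times, axis=1)
            bi = np.clip((ipis / bin_width_s).astype(np.int64), 0, n_bins - 1)
            rows = np.broadcast_to(np.arange(m)[:, None], bi.shape)
            flat = rows.ravel() * n_bins + bi.ravel()
            res[done:done + m] += np.bincount(
                flat, minlength=m * n_bins
            ).reshape(m, n_bins)
            done += m

    avg_random = res.mean(axis=0)
    dev_actual = np.sum(np.abs(actual - avg_random))
    dev_res = np.sum(np.abs(res - avg_random), axis=1)
    return float(np.mean(dev_res >= dev_actual))
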