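"""Oscillation phase and phase-nesting statistics.

The phase of the propagated-bend cycle (or of the SMDD/SMDV alternation
cycle) is defined by linear interpolation between alternating anchor peaks:
dorsal - ventral - dorsal maps to 0 - pi - 2*pi rad.  Interpolation makes the
phase independent of intervening head-casts or non-alternating oscillations.
A Hilbert-transform phase of a smoothed head-bend angle provides the
continuous alternative for moving recordings, computed per locomotion bout
with partial border cycles removed.

Nesting statistics are resampling-based: for each (half-)cycle that
contributed a real event-phase sample, one phase is redrawn at random from
the time points where an event could have been detected, a fractional phase
histogram is built, and its bin-by-bin summed absolute difference from the
all-phases distribution measures skewness.  The p value is the fraction of
resampled distributions at least as skewed as the actual one.  A second test
compares two phase distributions (e.g. forward vs reverse peaks) by
subsampling the larger to the smaller's size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import hilbert as _hilbert

__all__ = [
    "PhaseSeries",
    "EventPhaseSample",
    "interp_phase",
    "assign_event_phases",
    "hilbert_phase",
    "cycle_peak_fraction",
    "polar_skewness_test",
    "two_distribution_test",
    "detection_allowed_mask",
]

TWO_PI = 2.0 * math.pi
DEFAULT_N_BINS = 16


@dataclass
class PhaseSeries:
    """Per-frame phase in [0, 2*pi) with a validity mask.

    ``anchor_times``/``anchor_cum`` (cumulative, unwrapped anchor phases)
    allow exact evaluation at arbitrary times for interpolated phase.
    """

    phase: np.ndarray
    valid: np.ndarray
    frame_rate_hz: float
    convention: str = ""
    anchor_times: np.ndarray | None = None
    anchor_cum: np.ndarray | None = None

    def at(self, times_s) -> np.ndarray:
        """Phase at arbitrary times; NaN where undefined."""
        t = np.atleast_1d(np.asarray(times_s, dtype=float))
        if self.anchor_times is not None and self.anchor_times.size >= 2:
            out = np.interp(t, self.anchor_times, self.anchor_cum) % TWO_PI
            out[(t < self.anchor_times[0]) | (t > self.anchor_times[-1])] = np.nan
            return out
        idx = np.round(t * self.frame_rate_hz).astype(int)
        out = np.full(t.shape, np.nan)
        ok = (idx >= 0) & (idx < self.phase.size)
        sel = idx[ok]
        vals = np.where(self.valid[sel], self.phase[sel], np.nan)
        out[ok] = vals
        return out


@dataclass
class EventPhaseSample:
    event_id: int
    time_s: float
    phase: float
    kind: str


def interp_phase(
    anchors_a_s,
    anchors_b_s,
    n_frames: int,
    frame_rate_hz: float,
) -> PhaseSeries:
    """Linearly interpolated phase between alternating anchor peaks.

    Phase runs 0 -> pi from each A anchor (e.g. dorsal propagated-bend
    maximum, or the first SMDD peak following an SMDV peak) to the next B
    anchor, and pi -> 2*pi from B to the next A.  Same-type peaks between
    two anchors are ignored (first-of-type rule).  Frames outside the
    anchored span are invalid; fewer than three alternating anchors (one
    A-B-A triplet) yield an all-invalid series.
    """
    a = np.sort(np.asarray(anchors_a_s, dtype=float))
    b = np.sort(np.asarray(anchors_b_s, dtype=float))
    chain_t: list[float] = []
    chain_ty: list[int] = []  # 0 = A, 1 = B
    ia = ib = 0
    if a.size and (not b.size or a[0] <= b[0]):
        want = 0
    elif b.size:
        want = 1
    else:
        want = -1
    while want in (0, 1):
        if want == 0:
            while ia < a.size and chain_t and a[ia] <= chain_t[-1]:
                ia += 1
            if ia >= a.size:
                break
            chain_t.append(float(a[ia]))
            chain_ty.append(0)
            ia += 1
            want = 1
        else:
            while ib < b.size and chain_t and b[ib] <= chain_t[-1]:
                ib += 1
            if ib >= b.size:
                break
            chain_t.append(float(b[ib]))
            chain_ty.append(1)
            ib += 1
            want = 0

    phase = np.full(n_frames, np.nan)
    valid = np.zeros(n_frames, dtype=bool)
    if len(chain_t) < 3:
        return PhaseSeries(phase, valid, frame_rate_hz, convention="interp")
    anchor_t = np.asarray(chain_t)
    start = 0.0 if chain_ty[0] == 0 else math.pi
    anchor_cum = start + math.pi * np.arange(len(chain_t))
    t_grid = np.arange(n_frames) / frame_rate_hz
    inside = (t_grid >= anchor_t[0]) & (t_grid <= anchor_t[-1])
    phase[inside] = np.interp(t_grid[inside], anchor_t, anchor_cum) % TWO_PI
    valid[inside] = True
    return PhaseSeries(
        phase, valid, frame_rate_hz,
        convention="interp",
        anchor_times=anchor_t,
        anchor_cum=anchor_cum,
    )


def assign_event_phases(
    event_times_s,
    ps: PhaseSeries,
    kind: str = "event",
    *,
    context_times_s=None,
    context_signs=None,
):
    """Sample the oscillation phase of selected events.

    ``kind="initial_headcast"``: ``context_times_s``/``context_signs`` give
    the propagated-bend anchor times and signs ("dorsal"/"ventral"); only
    the first head-cast following each propagated bend is sampled and is
    labeled by the preceding bend's sign.  Any other ``kind`` samples every
    event (e.g. the first trough of each unilateral SMD oscillation, passed
    directly).  Events at frames with undefined phase are dropped.

    Returns
    -------
    (samples, n_dropped)
    """
    te = np.sort(np.asarray(event_times_s, dtype=float))
    samples: list[EventPhaseSample] = []
    dropped = 0
    if kind == "initial_headcast":
        if context_times_s is None or context_signs is None:
            raise ValueError("initial_headcast sampling needs context bends")
        ct = np.asarray(context_times_s, dtype=float)
        order = np.argsort(ct)
        ct = ct[order]
        cs = [context_signs[i] for i in order]
        if ct.size == 0:
            return [], int(te.size)
        for i, t0 in enumerate(ct):
            t1 = ct[i + 1] if i + 1 < ct.size else np.inf
            in_between = te[(te > t0) & (te < t1)]
            if in_between.size == 0:
                continue
            c = float(in_between[0])
            ph = float(ps.at(c)[0])
            if not np.isfinite(ph):
                dropped += 1
                continue
            samples.append(EventPhaseSample(
                event_id=len(samples),
                time_s=c,
                phase=ph,
                kind=f"initial_headcast_{cs[i]}",
            ))
        # casts before the first context bend have no defined half-cycle
        dropped += int(np.count_nonzero(te <= ct[0]))
        return samples, dropped

    for i, t in enumerate(te):
        ph = float(ps.at(t)[0])
        if not np.isfinite(ph):
            dropped += 1
            continue
        samples.append(EventPhaseSample(event_id=i, time_s=float(t), phase=ph, kind=kind))
    return samples, dropped


def hilbert_phase(
    angle_series,
    bouts_frames: list[tuple[int, int]],
    frame_rate_hz: float,
    smooth_window_s: float = 1.0,
    convention_offset: float = 0.0,
) -> PhaseSeries:
    """Analytic-signal phase of a smoothed angle series, per locomotion bout.

    The Hilbert transform is applied independently to each bout (no phase
    continuity across gaps); the first and last full cycle of each bout are
    invalidated as partial border cycles.  The smoothing (boxcar) removes
    head-cast transients before the transform.  ``convention_offset`` is
    added to the raw analytic angle (use pi to map a ``-A*cos(phi)`` series
    onto the dorsal-0 convention).
    """
    x = np.asarray(angle_series, dtype=float)
    n = x.size
    phase = np.full(n, np.nan)
    valid = np.zeros(n, dtype=bool)
    win = max(1, int(round(smooth_window_s * frame_rate_hz)))
    if win % 2 == 0:
        win += 1
    for s, e in bouts_frames:
        seg = x[s:e]
        if seg.size < 4 or not np.isfinite(seg).all():
            continue
        if win > 1:
            kernel = np.ones(win) / win
            pad = np.pad(seg, win // 2, mode="edge")
            seg = np.convolve(pad, kernel, mode="valid")
        seg = seg - seg.mean()
        if seg.std() < 1e-12:
            continue  # constant bout: zero analytic amplitude, undefined
        ana = _hilbert(seg)
        ph = np.unwrap(np.angle(ana))
        # drop partial border cycles
        lo, hi = ph[0] + TWO_PI, ph[-1] - TWO_PI
        ok = (ph >= lo) & (ph <= hi)
        idx = np.arange(s, e)[ok]
        phase[idx] = (ph[ok] + convention_offset) % TWO_PI
        valid[idx] = True
    return PhaseSeries(phase, valid, frame_rate_hz, convention="hilbert")


def cycle_peak_fraction(
    ps: PhaseSeries,
    event_times_s,
    centering: str = "0_to_2pi",
    missing_mask=None,
) -> float:
    """Fraction of complete, fully observed cycles containing >= 1 event.

    Cycles are segmented at phase 0 (``"0_to_2pi"``) or at phase pi
    (``"minus_pi_to_pi"``) so the typical event phase is centered and noise
    cannot push events into a neighboring cycle.  Cycles containing any
    masked frame (``missing_mask``) are excluded from the denominator.
    """
    if centering not in ("0_to_2pi", "minus_pi_to_pi"):
        raise ValueError(f"unknown centering {centering!r}")
    offset = 0.0 if centering == "0_to_2pi" else math.pi
    fr = ps.frame_rate_hz
    te = np.asarray(event_times_s, dtype=float)
    miss = (
        np.zeros(ps.phase.size, dtype=bool)
        if missing_mask is None else np.asarray(missing_mask, dtype=bool)
    )

    n_cycles = 0
    n_hit = 0
    # walk contiguous valid runs, unwrap, cut at offset + 2*pi*k
    i = 0
    n = ps.phase.size
    while i < n:
        if not ps.valid[i]:
            i += 1
            continue
        j = i
        while j < n and ps.valid[j]:
            j += 1
        ph = np.unwrap(ps.phase[i:j])
        k0 = math.ceil((ph[0] - offset) / TWO_PI)
        k1 = math.floor((ph[-1] - offset) / TWO_PI)
        for k in range(k0, k1):
            lo_ph = offset + TWO_PI * k
            hi_ph = lo_ph + TWO_PI
            a = i + int(np.searchsorted(ph, lo_ph))
            b = i + int(np.searchsorted(ph, hi_ph))
            if b <= a:
                continue
            if miss[a:b].any():
                continue
            n_cycles += 1
            t_lo, t_hi = a / fr, b / fr
            if np.any((te >= t_lo) & (te < t_hi)):
                n_hit += 1
        i = j
    if n_cycles == 0:
        raise ValueError("no complete, fully observed cycles")
    return n_hit / n_cycles


def detection_allowed_mask(series, peak_frames, delta: float) -> np.ndarray:
    """Frames where a peak could possibly have been detected.

    A candidate frame must differ from the most recent detected peak's value
    by at least ``delta`` (the detection threshold that produced the peaks).
    Frames before the first peak are allowed.
    """
    x = np.asarray(series, dtype=float)
    allowed = np.ones(x.size, dtype=bool)
    pf = np.sort(np.asarray(peak_frames, dtype=int))
    for a, b in zip(pf, np.append(pf[1:], x.size)):
        seg = x[a:b]
        allowed[a:b] = np.abs(seg - x[a]) >= delta
    return allowed


def _fraction_hist(phases, n_bins):
    h = np.histogram(np.asarray(phases) % TWO_PI, bins=n_bins, range=(0, TWO_PI))[0]
    tot = h.sum()
    return h / tot if tot > 0 else h.astype(float)


def polar_skewness_test(
    sample_phases,
    cycle_allowed_phases: list[np.ndarray],
    n_resamples: int = 10_000,
    n_bins: int = DEFAULT_N_BINS,
    *,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> float:
    """Is a phase-sample distribution more skewed than chance?

    ``cycle_allowed_phases`` holds, for every (half-)cycle that contributed
    one real sample, the phases of the time points where an event could have
    been detected (see :func:`detection_allowed_mask`).  Each resample draws
    one phase per cycle; skewness is the summed absolute bin-by-bin
    difference between a distribution and the all-phases distribution pooled
    over those cycles.  The p value is the fraction of resampled
    distributions at least as skewed as the actual samples.
    """
    samples = np.asarray(sample_phases, dtype=float)
    if samples.size == 0:
        raise ValueError("no phase samples")
    cycles = [np.asarray(c, dtype=float) for c in cycle_allowed_phases if len(c)]
    if len(cycles) != samples.size:
        raise ValueError(
            "need one non-empty allowed-phase set per sample "
            f"(got {len(cycles)} cycles for {samples.size} samples)"
        )
    if rng is None:
        rng = np.random.default_rng(seed)

    all_phases = np.concatenate(cycles)
    all_dist = _fraction_hist(all_phases, n_bins)
    actual = _fraction_hist(samples, n_bins)
    skew_actual = np.sum(np.abs(actual - all_dist))

    # one random allowed phase per cycle, vectorized over resamples
    n_c = len(cycles)
    draws = np.empty((n_resamples, n_c))
    for i, c in enumerate(cycles):
        draws[:, i] = c[rng.integers(0, c.size, size=n_resamples)]
    bi = np.floor(draws % TWO_PI / (TWO_PI / n_bins)).astype(np.int64)
    bi = np.clip(bi, 0, n_bins - 1)
    rows = np.broadcast_to(np.arange(n_resamples)[:, None], bi.shape)
    hists = np.bincount(
        (rows.ravel() * n_bins + bi.ravel()), minlength=n_resamples * n_bins
    ).reshape(n_resamples, n_bins) / n_c
    skew_res = np.sum(np.abs(hists - all_dist), axis=1)
    return float(np.mean(skew_res >= skew_actual))


def two_distribution_test(
    dist_large,
    dist_small,
    n_resamples: int = 10_000,
    n_bins: int = DEFAULT_N_BINS,
    *,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> float:
    """Does a small phase distribution differ from a larger reference one?

    Random subsamples of the large distribution, of the small one's size,
    give the null for the summed absolute bin-by-bin difference between the
    (fractional) subsample histogram and the large distribution's histogram.
    The p value is the fraction of subsamples differing at least as much as
    the small distribution does.
    """
    big = np.asarray(dist_large, dtype=float)
    small = np.asarray(dist_small, dtype=float)
    if small.size == 0 or big.size == 0:
        raise ValueError("empty distribution")
    if small.size > big.size:
        raise ValueError("dist_small must not be larger than dist_large")
    if rng is None:
        rng = np.random.default_rng(seed)
    big_dist = _fraction_hist(big, n_bins)
    actual = np.sum(np.abs(_fraction_hist(small, n_bins) - big_dist))

    n_s = small.size
    done = 0
    devs = np.empty(n_resamples)
    chunk = max(1, min(n_resamples, 4_000_000 // max(big.size, 1)))
    while done < n_resamples:
        m = min(chunk, n_resamples - done)
        keys = rng.random((m, big.size))
        pick = np.argpartition(keys, n_s - 1, axis=1)[:, :n_s]
        sub = big[pick]
        bi = np.clip(
            np.floor(sub % TWO_PI / (TWO_PI / n_bins)).astype(np.int64),
            0, n_bins - 1,
        )
        rows = np.broadcast_to(np.arange(m)[:, None], bi.shape)
        hists = np.bincount(
            rows.ravel() * n_bins + bi.ravel(), minlength=m * n_bins
        ).reshape(m, n_bins) / n_s
        devs[done:done + m] = np.sum(np.abs(hists - big_dist), axis=1)
        done += m
    return float(np.mean(devs >= actual))
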