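"""Amplitude-threshold (delta) peak detection and automatic delta selection.

Extrema are defined by an amplitude excursion: a maximum must be preceded and
followed by values lower by at least ``delta``, and vice versa for minima.
Detected maxima and minima therefore strictly alternate in time, which is what
the propagation tracer and the event-train statistics rely on.

The threshold ``delta`` trades false positives (too liberal) against false
negatives (too conservative).  :func:`auto_delta` selects a near-optimal value
per series by sweeping a delta range, counting detected peaks at each value,
and locating the breakpoint of a two-segment piecewise-linear least-squares
fit to the peaks-vs-delta curve: at low delta the curve falls steeply (noise
peaks vanish quickly), at high delta it is nearly flat (only large-amplitude
peaks remain), and the elbow between the two regimes balances both error
types.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PeakSet",
    "DELTA_PRESETS",
    "detect_peaks",
    "piecewise_breakpoint",
    "auto_delta",
    "detect_peaks_derivative",
    "NoChangepointError",
]

#: Published sweep ranges (start, stop, step), one per data regime.
DELTA_PRESETS: dict[str, tuple[float, float, float]] = {
    # smoothed time derivatives of immobilized ΔF/F0 traces
    "derivative": (1e-4, 0.03, 5e-5),
    # raw immobilized traces, 1.5-3 Hz volumetric imaging
    "immobilized_raw": (0.001, 0.5, 0.001),
    # raw immobilized traces, 50 Hz single-plane imaging
    "immobilized_50hz": (0.08, 0.3, 0.0005),
    # freely moving ΔR/R0 recordings
    "moving": (0.001, 1.0, 0.001),
}


class NoChangepointError(ValueError):
    """The peaks-vs-delta curve has no usable two-segment breakpoint."""


@dataclass
class PeakSet:
    """Alternating maxima/minima of one series.

    ``maxima``/``minima`` are frame indices; ``max_values``/``min_values`` the
    series values there.  ``delta_used`` records the detection threshold.
    """

    maxima: np.ndarray
    minima: np.ndarray
    max_values: np.ndarray
    min_values: np.ndarray
    delta_used: float

    def __post_init__(self) -> None:
        self.maxima = np.asarray(self.maxima, dtype=np.intp)
        self.minima = np.asarray(self.minima, dtype=np.intp)
        self.max_values = np.asarray(self.max_values, dtype=float)
        self.min_values = np.asarray(self.min_values, dtype=float)

    @property
    def n_maxima(self) -> int:
        return int(self.maxima.size)

    def times(self, frame_rate_hz: float) -> np.ndarray:
        """Maxima as seconds."""
        return self.maxima / float(frame_rate_hz)


def _tracker(x: np.ndarray, idx: np.ndarray, delta: float, last: int):
    """Excursion tracker over candidate sample positions ``idx``.

    ``idx`` must contain every position at which the running max/min or the
    search direction can change (monotone-run endpoints suffice).
    """
    maxima: list[int] = []
    minima: list[int] = []
    max_vals: list[float] = []
    min_vals: list[float] = []
    mn, mx = np.inf, -np.inf
    mn_pos = mx_pos = -1
    look_for_max: bool | None = None

    for i in idx:
        v = x[i]
        if v > mx:
            mx, mx_pos = v, i
        if v < mn:
            mn, mn_pos = v, i
        if look_for_max is None:
            if v <= mx - delta:
                if 0 < mx_pos < last:
                    maxima.append(mx_pos)
                    max_vals.append(mx)
                look_for_max = False
                mn, mn_pos = v, i
            elif v >= mn + delta:
                if 0 < mn_pos < last:
                    minima.append(mn_pos)
                    min_vals.append(mn)
                look_for_max = True
                mx, mx_pos = v, i
        elif look_for_max:
            if v <= mx - delta:
                if 0 < mx_pos < last:
                    maxima.append(mx_pos)
                    max_vals.append(mx)
                look_for_max = False
                mn, mn_pos = v, i
        else:
            if v >= mn + delta:
                if 0 < mn_pos < last:
                    minima.append(mn_pos)
                    min_vals.append(mn)
                look_for_max = True
                mx, mx_pos = v, i
    return maxima, minima, max_vals, min_vals


def _candidate_indices(x: np.ndarray) -> list[np.ndarray]:
    """Per finite run: monotone-run endpoints (plateau-first semantics)."""
    finite = np.isfinite(x)
    runs = []
    n = x.size
    starts = np.flatnonzero(finite & ~np.roll(finite, 1))
    if finite[0]:
        starts = np.unique(np.concatenate([[0], starts]))
    for a in starts:
        b = a
        nxt = np.flatnonzero(~finite[a:])
        b = a + (nxt[0] if nxt.size else n - a)
        seg = x[a:b]
        if seg.size == 0:
            continue
        d = np.diff(seg)
        s = np.sign(d)
        nzi = np.flatnonzero(s)
        if nzi.size == 0:
            runs.append(np.array([a, b - 1]) if b - a > 1 else np.array([a]))
            continue
        s_nz = s[nzi]
        turn = np.flatnonzero(s_nz[1:] != s_nz[:-1])
        cand = np.concatenate([[0], nzi[turn] + 1, [b - a - 1]])
        runs.append(np.unique(cand) + a)
    return runs


def detect_peaks(series, delta: float) -> PeakSet:
    """Detect alternating local maxima/minima separated by at least ``delta``.

    A maximum is emitted once the series has dropped by >= delta on both
    sides; minima symmetrically.  NaN samples (missing data) break detection
    runs: no extremum may straddle a gap.  Series endpoints are never
    extrema.

    Parameters
    ----------
    series : 1-D array-like
        Signal; NaN marks missing samples.
    delta : float
        Amplitude threshold, > 0, in series units.
    """
    if not np.isfinite(delta) or delta <= 0:
        raise ValueError(f"delta must be positive and finite, got {delta!r}")
    x = np.asarray(series, dtype=float).ravel()
    if x.size < 3:
        raise ValueError("series must have at least 3 samples")

    maxima: list[int] = []
    minima: list[int] = []
    max_vals: list[float] = []
    min_vals: list[float] = []
    last = x.size - 1
    for idx in _candidate_indices(x):
        mx, mn, mxv, mnv = _tracker(x, idx, delta, last)
        maxima.extend(mx)
        minima.extend(mn)
        max_vals.extend(mxv)
        min_vals.extend(mnv)

    return PeakSet(
        maxima=np.array(maxima, dtype=np.intp),
        minima=np.array(minima, dtype=np.intp),
        max_values=np.array(max_vals, dtype=float),
        min_values=np.array(min_vals, dtype=float),
        delta_used=float(delta),
    )


def detect_peaks_reference(series, delta: float) -> PeakSet:
    """Sample-by-sample reference implementation of :func:`detect_peaks`.

    Kept as an independent oracle: iterates every sample instead of monotone
    run endpoints.  Output must be identical.
    """
    if not np.isfinite(delta) or delta <= 0:
        raise ValueError(f"delta must be positive and finite, got {delta!r}")
    x = np.asarray(series, dtype=float).ravel()
    if x.size < 3:
        raise ValueError("series must have at least 3 samples")
    last = x.size - 1
    maxima: list[int] = []
    minima: list[int] = []
    max_vals: list[float] = []
    min_vals: list[float] = []
    start = 0
    finite = np.isfinite(x)
    for a in range(x.size + 1):
        if a == x.size or not finite[a]:
            if a > start:
                mx, mn, mxv, mnv = _tracker(
                    x, np.arange(start, a), delta, last
                )
                maxima.extend(mx)
                minima.extend(mn)
                max_vals.extend(mxv)
                min_vals.extend(mnv)
            start = a + 1
    return PeakSet(
        maxima=np.array(maxima, dtype=np.intp),
        minima=np.array(minima, dtype=np.intp),
        max_values=np.array(max_vals, dtype=float),
        min_values=np.array(min_vals, dtype=float),
        delta_used=float(delta),
    )


def piecewise_breakpoint(y, with_improvement: bool = False):
    """Index at which a curve is best split into two least-squares lines.

    Scans every interior breakpoint k (each side needs >= 2 points), fits an
    independent straight line to y[:k] and y[k:], and returns the k whose
    summed squared residual is smallest — the exact small-N criterion for
    "both the mean and slope change most abruptly".  Residuals are weighted
    relative to each segment's own level: the two regimes of a
    peaks-vs-delta sweep differ by orders of magnitude (hundreds of noise
    peaks vs a handful of real ones), and unweighted least squares would let
    the steep noise regime swamp misfit in the flat regime, biasing the
    breakpoint liberal.  A curve built from two exact lines is still
    recovered exactly (zero cost at the true junction).

    Raises
    ------
    NoChangepointError
        If the curve has fewer than 4 points or is constant.
    """
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if n < 4:
        raise NoChangepointError(f"need >= 4 points for a breakpoint, got {n}")
    if np.allclose(y, y[0]):
        raise NoChangepointError("constant curve has no change point")

    def _cost(seg: np.ndarray) -> float:
        t = np.arange(seg.size, dtype=float)
        coef, res, *_ = np.linalg.lstsq(
            np.column_stack([t, np.ones_like(t)]), seg, rcond=None
        )
        if res.size:
            sse = float(res[0])
        else:
            fit = coef[0] * t + coef[1]
            sse = float(np.sum((seg - fit) ** 2))
        scale = float(np.mean(np.abs(seg))) + 1.0
        return sse / scale**2

    best_k, best_cost = -1, np.inf
    for k in range(2, n - 1):
        cost = _cost(y[:k]) + _cost(y[k:])
        if cost < best_cost - 1e-15:
            best_cost, best_k = cost, k
    if with_improvement:
        single = _cost(y)
        impr = 1.0 - best_cost / single if single > 0 else 0.0
        return best_k, impr
    return best_k


def _delta_grid(delta_range: tuple[float, float, float]) -> np.ndarray:
    lo, hi, step = (float(v) for v in delta_range)
    if not (lo < hi and step > 0 and lo > 0):
        raise ValueError(f"invalid delta range {delta_range!r}")
    n = int(np.floor((hi - lo) / step + 1e-9)) + 1
    return lo + step * np.arange(n)


def peak_count_curve(series, delta_range) -> tuple[np.ndarray, np.ndarray]:
    """Number of detected maxima at every delta in the range."""
    deltas = _delta_grid(delta_range)
    counts = np.array([detect_peaks(series, d).n_maxima for d in deltas])
    return deltas, counts


def auto_delta(series, delta_range=None, fallback: bool = True) -> float:
    """Near-optimal detection threshold from the peaks-vs-delta breakpoint.

    Parameters
    ----------
    series : 1-D array-like
    delta_range : (min, max, step) or preset name, optional
        Sweep range.  None uses the std-based default: max = std(series),
        min = step = std/100.
    fallback : bool
        If the curve carries no change point and ``fallback`` is true, retry
        on the std-based default range; if that also fails, return its upper
        bound (most conservative usable value).
    """
    x = np.asarray(series, dtype=float).ravel()
    if isinstance(delta_range, str):
        delta_range = DELTA_PRESETS[delta_range]
    if delta_range is None:
        delta_range = _std_range(x)
    deltas, counts = peak_count_curve(x, delta_range)
    try:
        k = _refined_breakpoint(counts)
        return float(deltas[k])
    except NoChangepointError:
        if not fallback:
            raise
        std_range = _std_range(x)
        if not np.allclose(std_range, delta_range):
            deltas, counts = peak_count_curve(x, std_range)
            try:
                k = _refined_breakpoint(counts)
                return float(deltas[k])
            except NoChangepointError:
                pass
        return float(std_range[1])


def _refined_breakpoint(
    counts: np.ndarray,
    min_improvement: float = 0.5,
    drop_factor: float = 1.3,
) -> int:
    """Iteratively refined two-segment breakpoint of a peaks-vs-delta curve.

    The first split soaks up the steep noise regime; when the tail segment
    still starts well above its own plateau level (``drop_factor`` times the
    tail median) and a further split reduces the weighted residual by more
    than ``min_improvement`` relative to a single line, the scan repeats on
    the tail.  A curve made of two exact lines is untouched: its tail is a
    single line with no remaining drop.
    """
    k, _ = piecewise_breakpoint(counts, with_improvement=True)
    offset = 0
    for _ in range(3):
        tail = counts[offset + k:]
        if tail.size < 6:
            break
        if not tail[0] >= drop_factor * np.median(tail) + 1:
            break
        try:
            k2, impr2 = piecewise_breakpoint(tail, with_improvement=True)
        except NoChangepointError:
            break
        if impr2 < min_improvement:
            break
        offset += k
        k = k2
    return offset + k


def _std_range(x: np.ndarray) -> tuple[float, float, float]:
    sd = float(np.nanstd(x))
    if sd <= 0 or not np.isfinite(sd):
        sd = 1.0
    return (sd / 100.0, sd, sd / 100.0)


def detect_peaks_derivative(deriv_series, delta_range="derivative") -> PeakSet:
    """Peak detection on a (regularized) time-derivative trace.

    Runs :func:`auto_delta` + :func:`detect_peaks`, then applies the
    derivative-specific rules: maxima with value < 0 are excluded (slope
    changes of a fall, not rises), and of two consecutive maxima whose
    intervening minimum does not fall below 0 only the first is kept (the
    pair reflects a slope change within a single calcium rise).
    """
    x = np.asarray(deriv_series, dtype=float).ravel()
    delta = auto_delta(x, delta_range)
    ps = detect_peaks(x, delta)

    keep = np.ones(ps.maxima.size, dtype=bool)
    keep &= ps.max_values >= 0
    # second-of-pair rule, applied left to right on surviving maxima
    prev_kept = -1
    for i in range(ps.maxima.size):
        if not keep[i]:
            continue
        if prev_kept >= 0:
            lo, hi = ps.maxima[prev_kept], ps.maxima[i]
            between = (ps.minima > lo) & (ps.minima < hi)
            if not between.any() or ps.min_values[between].min() >= 0:
                keep[i] = False
                continue
        prev_kept = i
    return PeakSet(
        maxima=ps.maxima[keep],
        minima=ps.minima,
        max_values=ps.max_values[keep],
        min_values=ps.min_values,
        delta_used=delta,
    )
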