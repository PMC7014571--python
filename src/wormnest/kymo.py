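"""Posture kymogram analysis: bend angles, propagation tracing, classification.

A kymogram is a time x body-segment matrix of 24 signed bend angles measured
between 25 equally spaced midline segments (segment/angle indices are 1-based,
anterior to posterior).  During forward crawling each head bend propagates
posteriorly; tracing every bend's posterior-most segment separates two action
classes: *propagated-bends* that travel to segment #14 or beyond (the ~0.5 Hz
crawling gait) and *head-casts* that terminate at segment #13 or earlier
(faster, ~1 Hz oscillations nested in restricted phases of the gait).

Sign convention: ventral bends are positive angles, dorsal negative
(``ventral_positive=True``).  Time is 0-based frames; intervals are half-open
``[start, end)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .peaks import auto_delta, detect_peaks

__all__ = [
    "Kymogram",
    "PeakKymogram",
    "HeadBendEvent",
    "LocomotionBouts",
    "compute_bend_angles",
    "preprocess_kymogram",
    "build_peak_kymogram",
    "trace_propagations",
    "cycle_periods",
    "head_bend_amplitude",
]

N_ANGLES = 24
HEADCAST_MAX_SEGMENT = 13  # final propagation angle <= #13 -> head-cast


@dataclass
class Kymogram:
    """T x 24 matrix of body-bend angles in radians.

    ``missing_mask`` marks frames/segments where skeletonization failed;
    masked cells hold NaN.  ``ventral_positive`` records the sign convention.
    """

    angles: np.ndarray
    frame_rate_hz: float
    missing_mask: np.ndarray | None = None
    ventral_positive: bool = True

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=float)
        if self.angles.ndim != 2 or self.angles.shape[1] != N_ANGLES:
            raise ValueError(
                f"kymogram needs exactly {N_ANGLES} angle columns, "
                f"got shape {self.angles.shape}"
            )
        if not self.frame_rate_hz > 0:
            raise ValueError("frame_rate_hz must be positive")
        if self.missing_mask is None:
            self.missing_mask = ~np.isfinite(self.angles)
        else:
            self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
            if self.missing_mask.shape != self.angles.shape:
                raise ValueError("missing_mask shape mismatch")
        if not np.isfinite(self.angles[~self.missing_mask]).all():
            raise ValueError("non-finite angles outside the missing mask")

    @property
    def n_frames(self) -> int:
        return self.angles.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate_hz


@dataclass
class PeakKymogram:
    """Kymogram reduced to {-1, 0, +1}: angle minima, background, maxima."""

    values: np.ndarray  # T x 24 int8
    frame_rate_hz: float
    deltas: np.ndarray  # detection threshold used per column
    missing_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        self.deltas = np.asarray(self.deltas, dtype=float)
        if self.missing_mask is None:
            self.missing_mask = np.zeros(self.values.shape, dtype=bool)

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]


@dataclass
class LocomotionBouts:
    """Ordered, non-overlapping forward/reverse intervals in frames.

    ``intervals`` is a list of ``(start_frame, end_frame, label)`` with
    half-open frame ranges and label in {"forward", "reverse"}.
    """

    intervals: list[tuple[int, int, str]]
    source: str = "inferred"

    def __post_init__(self) -> None:
        prev_end = -1
        for s, e, lab in self.intervals:
            if lab not in ("forward", "reverse"):
                raise ValueError(f"unknown bout label {lab!r}")
            if not (0 <= s < e):
                raise ValueError(f"bad interval ({s}, {e})")
            if s < prev_end:
                raise ValueError("bout intervals overlap or are unsorted")
            prev_end = e

    @classmethod
    def from_reversals(
        cls, reversal_intervals_s, n_frames: int, frame_rate_hz: float
    ) -> "LocomotionBouts":
        """Manual reversal annotations; all other time is forward state."""
        marks = np.zeros(n_frames, dtype=bool)
        for s, e in reversal_intervals_s:
            i0 = max(0, int(round(s * frame_rate_hz)))
            i1 = min(n_frames, int(round(e * frame_rate_hz)))
            marks[i0:i1] = True
        intervals: list[tuple[int, int, str]] = []
        i = 0
        while i < n_frames:
            j = i
            while j < n_frames and marks[j] == marks[i]:
                j += 1
            intervals.append((i, j, "reverse" if marks[i] else "forward"))
            i = j
        return cls(intervals=intervals, source="manual_annotation")

    def covers(self, n_frames: int) -> bool:
        if not self.intervals:
            return n_frames == 0
        if self.intervals[0][0] != 0 or self.intervals[-1][1] < n_frames:
            return False
        for (s0, e0, _), (s1, e1, _) in zip(self.intervals, self.intervals[1:]):
            if s1 != e0:
                return False
        return True


@dataclass
class HeadBendEvent:
    """One traced head bend and its posterior propagation.

    ``sign`` is "ventral" or "dorsal"; ``assigned_peaks`` holds 1-based
    (segment, frame) pairs with strictly increasing segment indices;
    ``final_segment`` is the posterior-most assigned angle.  For reverse
    bouts segment indices refer to the left/right-flipped kymogram (bends
    quantified as if propagating head to tail).
    """

    onset_frame: int
    sign: str
    assigned_peaks: list[tuple[int, int]] = field(default_factory=list)
    final_segment: int = 2
    class_label: str = "unclassified"
    termination_reason: str = "end_of_recording"
    bout_label: str = "forward"
    isolated: bool = False

    def onset_s(self, frame_rate_hz: float) -> float:
        return self.onset_frame / frame_rate_hz


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def compute_bend_angles(
    midline: np.ndarray,
    frame_rate_hz: float,
    ventral_positive: bool = True,
) -> Kymogram:
    """Signed turning angles along a midline of 25 body segments.

    The midline is given as 26 ordered planar points head to tail (25 equal
    segments); the 24 angles are the signed turns between consecutive
    segment vectors.  Frames containing NaN are flagged missing.  A positive
    (counter-clockwise) turn is ventral under the default convention.
    """
    pts = np.asarray(midline, dtype=float)
    if pts.ndim != 3 or pts.shape[1] != 26 or pts.shape[2] != 2:
        raise ValueError(f"midline must be (T, 26, 2) points, got {pts.shape}")
    ok = np.isfinite(pts).all(axis=(1, 2))
    vec = np.diff(pts, axis=1)  # (T, 25, 2) segment vectors
    seg_len = np.hypot(vec[..., 0], vec[..., 1])
    if np.any(seg_len[ok] == 0):
        raise ValueError("duplicate consecutive midline points (zero-length segment)")
    a, b = vec[:, :-1, :], vec[:, 1:, :]
    cross = a[..., 0] * b[..., 1] - a[..., 1] * b[..., 0]
    dot = (a * b).sum(axis=-1)
    ang = np.arctan2(cross, dot)  # (T, 24)
    if not ventral_positive:
        ang = -ang
    ang[~ok, :] = np.nan
    mask = np.zeros_like(ang, dtype=bool)
    mask[~ok, :] = True
    return Kymogram(
        angles=ang,
        frame_rate_hz=frame_rate_hz,
        missing_mask=mask,
        ventral_positive=True,
    )


def preprocess_kymogram(
    k: Kymogram,
    smooth_window_s: float = 0.3,
    max_gap_s: float = 1.0,
) -> Kymogram:
    """Fill short missing-data gaps, then smooth each angle column.

    Missing runs strictly shorter than ``max_gap_s`` that are bounded by
    valid samples are linearly bridged and unmasked; longer runs stay
    masked.  Smoothing is a centered boxcar of ``smooth_window_s`` that
    ignores masked samples (normalized by the valid count in the window).
    """
    fr = k.frame_rate_hz
    ang = k.angles.copy()
    mask = k.missing_mask.copy()
    max_gap_frames = int(np.ceil(max_gap_s * fr))  # run of this many frames == 1 s

    t_idx = np.arange(k.n_frames)
    for j in range(N_ANGLES):
        col_mask = mask[:, j]
        if not col_mask.any() or col_mask.all():
            continue
        # enumerate missing runs
        d = np.diff(col_mask.astype(np.int8))
        starts = list(np.flatnonzero(d == 1) + 1)
        ends = list(np.flatnonzero(d == -1) + 1)
        if col_mask[0]:
            starts.insert(0, 0)
        if col_mask[-1]:
            ends.append(k.n_frames)
        for s, e in zip(starts, ends):
            interior = s > 0 and e < k.n_frames
            if interior and (e - s) < max_gap_frames:
                frac = (t_idx[s:e] - (s - 1)) / (e - (s - 1))
                ang[s:e, j] = ang[s - 1, j] + frac * (ang[e, j] - ang[s - 1, j])
                mask[s:e, j] = False
    ang[mask] = np.nan

    win = max(1, int(round(smooth_window_s * fr)))
    if win % 2 == 0:
        win += 1
    if win > 1:
        kernel = np.ones(win)
        valid = (~mask).astype(float)
        filled = np.where(mask, 0.0, ang)
        for j in range(N_ANGLES):
            num = np.convolve(filled[:, j], kernel, mode="same")
            den = np.convolve(valid[:, j], kernel, mode="same")
            with np.errstate(invalid="ignore"):
                sm = num / den
            ang[:, j] = np.where(mask[:, j], np.nan, sm)

    return Kymogram(
        angles=ang,
        frame_rate_hz=fr,
        missing_mask=mask,
        ventral_positive=k.ventral_positive,
    )


def build_peak_kymogram(k: Kymogram, delta) -> PeakKymogram:
    """Reduce each angle column to alternating extrema via the delta detector.

    ``delta`` may be a scalar, a per-column array, or "auto" (per-column
    automatic selection; see :func:`wormnest.peaks.auto_delta`).  Extrema
    need not straddle zero: a maximum can be dorsal (negative) if the bend
    changes by at least delta without crossing 0.
    """
    if isinstance(delta, str):
        if delta != "auto":
            raise ValueError(f"unknown delta mode {delta!r}")
        deltas = np.array(
            [auto_delta(np.where(k.missing_mask[:, j], np.nan, k.angles[:, j]))
             for j in range(N_ANGLES)]
        )
    else:
        deltas = np.broadcast_to(np.asarray(delta, dtype=float), (N_ANGLES,)).copy()
        if np.any(deltas <= 0):
            raise ValueError("delta must be positive")

    values = np.zeros(k.angles.shape, dtype=np.int8)
    for j in range(N_ANGLES):
        col = np.where(k.missing_mask[:, j], np.nan, k.angles[:, j])
        ps = detect_peaks(col, deltas[j])
        values[ps.maxima, j] = 1
        values[ps.minima, j] = -1
    return PeakKymogram(
        values=values,
        frame_rate_hz=k.frame_rate_hz,
        deltas=deltas,
        missing_mask=k.missing_mask.copy(),
    )


def _column_peaks(values: np.ndarray):
    """Per column: sorted peak frames and signs."""
    cols = []
    for j in range(values.shape[1]):
        nz = np.flatnonzero(values[:, j])
        cols.append((nz, values[nz, j].astype(int)))
    return cols


def trace_propagations(
    pk: PeakKymogram,
    bouts: LocomotionBouts,
    *,
    back_free_s: float = 0.1,
    back_budget_s: float = 1.0,
    max_gap_s: float = 10.0,
    max_skip: int = 2,
) -> list[HeadBendEvent]:
    """Trace every head bend's posterior propagation and classify it.

    Peaks in angle #2 seed head-bend events (angle #1 is noisier).  Events
    are processed in temporal order; each extremum is assigned to at most
    one event.  For each event the same-sign previous peak in angle #1 is
    attached first, then propagation iterates posteriorly, requiring a
    same-sign unassigned peak in each next angle.  Propagation terminates on
    an opposite-sign next peak, on a gap > 10 s since the previous assigned
    peak, after >= 2 unassigned peaks in the anterior angle, or when a
    reversal or missing data are encountered.  Up to ``max_skip`` angle
    columns may be skipped per propagation when no correct-sign peak is
    detected; assigned peaks may trail the previous one by ``back_free_s``
    freely and by up to ``back_budget_s`` once per event.

    Classification: final segment <= #13 -> head_cast, >= #14 -> propagated;
    termination by reversal/missing data (or the recording end) before #14
    leaves the bend unclassified, as do isolated single-segment bends.
    Reverse bouts are analyzed on the column-reversed kymogram so that
    tail-to-head waves mirror the forward analysis.
    """
    if pk.frame_rate_hz <= 0:
        raise ValueError("frame rate must be positive")
    if not bouts.covers(pk.n_frames):
        raise ValueError("bouts must cover the recording")

    events: list[HeadBendEvent] = []
    for label in ("forward", "reverse"):
        sel = [(s, e) for s, e, lab in bouts.intervals if lab == label]
        if not sel:
            continue
        vals = pk.values if label == "forward" else pk.values[:, ::-1]
        miss = pk.missing_mask if label == "forward" else pk.missing_mask[:, ::-1]
        events.extend(
            _trace_direction(
                vals, miss, sel, label, pk.frame_rate_hz,
                back_free_s, back_budget_s, max_gap_s, max_skip,
            )
        )
    events.sort(key=lambda ev: ev.onset_frame)
    return events


def _trace_direction(
    values, missing, bout_spans, bout_label, fr,
    back_free_s, back_budget_s, max_gap_s, max_skip,
):
    n_frames, n_cols = values.shape
    back_free = int(round(back_free_s * fr))
    back_budget = int(round(back_budget_s * fr))
    max_gap = int(round(max_gap_s * fr))

    col_frames, col_signs = zip(*_column_peaks(values))
    assigned = [np.zeros(f.size, dtype=bool) for f in col_frames]
    miss_frames = [np.flatnonzero(missing[:, j]) for j in range(n_cols)]

    def bout_of(frame):
        for s, e in bout_spans:
            if s <= frame < e:
                return s, e
        return None

    events: list[HeadBendEvent] = []
    seed_col = 1  # angle #2
    for seed_i, t0 in enumerate(col_frames[seed_col]):
        span = bout_of(t0)
        if span is None:
            continue
        bs, be = span
        sgn = int(col_signs[seed_col][seed_i])
        assigned[seed_col][seed_i] = True
        ev = HeadBendEvent(
            onset_frame=int(t0),
            sign="ventral" if sgn > 0 else "dorsal",
            bout_label=bout_label,
        )
        peaks: list[tuple[int, int]] = [(2, int(t0))]
        budget_used = False

        # anterior step to angle #1: nearest previous same-sign unassigned
        # peak; inherently backward, so it does not consume the once-per-event
        # backward budget of the posterior propagation
        f0, s0 = col_frames[0], col_signs[0]
        lo = max(bs, t0 - back_budget)
        j = np.searchsorted(f0, t0, side="right") - 1
        if j >= 0 and f0[j] >= lo and s0[j] == sgn and not assigned[0][j]:
            assigned[0][j] = True
            peaks.insert(0, (1, int(f0[j])))

        cur_col, cur_t = seed_col, int(t0)
        skips_used = 0
        reason = "tail_reached"
        while True:
            if cur_col >= n_cols - 1:
                reason = "tail_reached"
                break
            outcome = None
            pending = None
            tgt = cur_col
            while True:
                tgt += 1
                if tgt >= n_cols or (tgt - cur_col - 1) + skips_used > max_skip:
                    outcome = ("terminate", pending or "time_gap")
                    break
                frames_t, signs_t = col_frames[tgt], col_signs[tgt]
                # next peak, allowing the ubiquitous free backward tolerance
                lo = max(bs, cur_t - back_free)
                idx = np.searchsorted(frames_t, lo)
                cand = int(frames_t[idx]) if idx < frames_t.size else None

                # earliest event boundary ahead of the current peak
                mrow = miss_frames[tgt]
                mi = np.searchsorted(mrow, cur_t)
                m_next = int(mrow[mi]) if mi < mrow.size else None
                limit = min(be, cur_t + max_gap + 1)
                limit_reason = (
                    "end_of_recording" if be >= n_frames and limit == be
                    else "reversal_or_missing" if limit == be
                    else "time_gap"
                )
                if m_next is not None and m_next < limit:
                    limit, limit_reason = m_next, "reversal_or_missing"

                assignable = (
                    cand is not None
                    and cand < limit
                    and signs_t[idx] == sgn
                    and not assigned[tgt][idx]
                )
                if assignable:
                    # >= 2 unassigned peaks in the anterior angle before cand
                    af, aa = col_frames[tgt - 1], assigned[tgt - 1]
                    a_lo = np.searchsorted(af, cur_t, side="right")
                    a_hi = np.searchsorted(af, cand + back_free, side="right")
                    if np.count_nonzero(~aa[a_lo:a_hi]) >= 2:
                        outcome = ("terminate", "skipped_anterior_peaks")
                        break
                    assigned[tgt][idx] = True
                    outcome = ("assigned", tgt, cand)
                    break

                # once-per-event backward rescue within the 1 s budget
                if not budget_used:
                    b_lo = max(bs, cur_t - back_budget)
                    j0 = np.searchsorted(frames_t, b_lo)
                    j1 = np.searchsorted(frames_t, cur_t - back_free)
                    back = [
                        j for j in range(j1 - 1, j0 - 1, -1)
                        if signs_t[j] == sgn and not assigned[tgt][j]
                    ]
                    if back:
                        j = back[0]
                        assigned[tgt][j] = True
                        budget_used = True
                        outcome = ("assigned", tgt, int(frames_t[j]))
                        break

                if cand is not None and cand < limit:
                    if signs_t[idx] != sgn:
                        outcome = ("terminate", "opposite_sign")
                        break
                    # same sign but already assigned: try skipping the column
                    pending = pending or "time_gap"
                    continue
                # no candidate before the boundary
                if limit_reason in ("reversal_or_missing", "end_of_recording"):
                    outcome = ("terminate", limit_reason)
                    break
                pending = pending or limit_reason
                # fall through: skip this column
            if outcome[0] == "assigned":
                skips_used += outcome[1] - cur_col - 1
                cur_col, cur_t = outcome[1], outcome[2]
                peaks.append((cur_col + 1, cur_t))
            else:
                reason = outcome[1]
                break

        ev.assigned_peaks = peaks
        ev.final_segment = max(seg for seg, _ in peaks)
        ev.termination_reason = reason
        ev.isolated = len(peaks) == 1
        ev.class_label = _classify(ev)
        events.append(ev)
    return events


def _classify(ev: HeadBendEvent) -> str:
    if ev.isolated:
        return "unclassified"
    if (
        ev.termination_reason in ("reversal_or_missing", "end_of_recording")
        and ev.final_segment < HEADCAST_MAX_SEGMENT + 1
    ):
        return "unclassified"
    if ev.final_segment <= HEADCAST_MAX_SEGMENT:
        return "head_cast"
    return "propagated"


def cycle_periods(
    events: list[HeadBendEvent],
    mode: str,
    frame_rate_hz: float,
) -> list[float]:
    """Cycle periods (seconds) from classified head-bend events.

    modes
    -----
    ``headcast_doubled``
        Doubled inter-bend intervals between two consecutive head-casts
        (no other classified bend in between).
    ``propagated_doubled``
        Doubled intervals between two consecutive propagated-bends.
    ``propagated_full``
        Doubled intervals between successive propagated-bends regardless of
        intervening head-cast interruption (a doubled dorsal-to-ventral
        interval equals the dorsal-to-dorsal full cycle).
    """
    seq = sorted(
        (ev.onset_frame / frame_rate_hz, ev.class_label)
        for ev in events
        if ev.class_label in ("head_cast", "propagated")
    )
    out: list[float] = []
    if mode == "headcast_doubled" or mode == "propagated_doubled":
        want = "head_cast" if mode == "headcast_doubled" else "propagated"
        for (t0, c0), (t1, c1) in zip(seq, seq[1:]):
            if c0 == want and c1 == want:
                out.append(2.0 * (t1 - t0))
    elif mode == "propagated_full":
        props = [t for t, c in seq if c == "propagated"]
        out = [2.0 * (b - a) for a, b in zip(props, props[1:])]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return out


def head_bend_amplitude(
    k: Kymogram,
    events: list[HeadBendEvent],
    window_s: float = 1.0,
) -> np.ndarray:
    """Per-bend head amplitude: summed peak |angle| over segments #2-#6.

    For each event, segments 2-6 contribute the |angle| at their assigned
    peak frame; segments without an assigned peak contribute the maximum
    |angle| within ``window_s`` of the event onset.
    """
    fr = k.frame_rate_hz
    half = max(1, int(round(window_s * fr / 2)))
    amps = np.zeros(len(events))
    for i, ev in enumerate(events):
        by_seg = dict(ev.assigned_peaks)
        total = 0.0
        for seg in range(2, 7):
            if seg in by_seg:
                v = k.angles[by_seg[seg], seg - 1]
                total += abs(v) if np.isfinite(v) else 0.0
            else:
                lo = max(0, ev.onset_frame - half)
                hi = min(k.n_frames, ev.onset_frame + half + 1)
                col = k.angles[lo:hi, seg - 1]
                col = col[np.isfinite(col)]
                if col.size:
                    total += float(np.max(np.abs(col)))
        amps[i] = total
    return amps
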