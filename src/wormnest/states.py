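"""Command-state segmentation from a designated command interneuron.

The activity of a reverse-active command neuron (AVA) is split per frame into
RISE / HIGH / FALL / LOW phases from its trace and time derivative, and the
phases map onto motor command states: RISE and HIGH are the reversal command,
FALL the post-reversal turn, LOW the forward command.  Forward command states
shorter than 50 s rarely carry more than one activity fluctuation and are
excluded from frequency and covariogram analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NeuronPhaseSegmentation",
    "StateSegmentation",
    "segment_neuron_phases",
    "infer_command_states",
    "filter_forward_states",
    "state_durations",
    "default_phase_thresholds",
    "MIN_FORWARD_STATE_S",
]

MIN_FORWARD_STATE_S = 50.0

PHASE_TO_COMMAND = {"RISE": "reverse", "HIGH": "reverse", "FALL": "turn", "LOW": "forward"}


@dataclass
class NeuronPhaseSegmentation:
    """Per-frame phase labels for one neuron."""

    labels: np.ndarray  # of {"RISE", "HIGH", "FALL", "LOW"}; "" where missing
    frame_rate_hz: float
    pos_thr: float
    neg_thr: float
    level_thr: float


@dataclass
class StateSegmentation:
    """Ordered, non-overlapping command-state intervals in seconds."""

    intervals: list[tuple[float, float, str]]
    source_neuron: str = ""

    def __post_init__(self) -> None:
        prev = -np.inf
        for s, e, lab in self.intervals:
            if lab not in ("forward", "reverse", "turn"):
                raise ValueError(f"unknown state label {lab!r}")
            if not s < e:
                raise ValueError(f"empty or inverted interval ({s}, {e})")
            if s < prev:
                raise ValueError("intervals overlap or are unsorted")
            prev = e

    def with_label(self, label: str) -> list[tuple[float, float]]:
        return [(s, e) for s, e, lab in self.intervals if lab == label]


def default_phase_thresholds(deriv: np.ndarray, trace: np.ndarray):
    """MAD-based derivative thresholds and mid-range level threshold.

    The positive/negative derivative thresholds are +-3 median absolute
    deviations of the derivative; the level threshold is the trace midrange.
    """
    d = deriv[np.isfinite(deriv)]
    mad = np.median(np.abs(d - np.median(d)))
    if mad <= 0:
        mad = max(np.std(d), 1e-12)
    x = trace[np.isfinite(trace)]
    level = 0.5 * (np.min(x) + np.max(x))
    return 3.0 * mad, -3.0 * mad, level


def segment_neuron_phases(
    trace,
    deriv,
    pos_thr: float | None = None,
    neg_thr: float | None = None,
    level_thr: float | None = None,
    frame_rate_hz: float = 1.0,
) -> NeuronPhaseSegmentation:
    """Label each frame RISE, FALL, HIGH, or LOW.

    Frames with derivative above ``pos_thr`` are RISE, below ``neg_thr``
    FALL; remaining frames are HIGH if the trace is at or above
    ``level_thr``, LOW otherwise.  Thresholds default to
    :func:`default_phase_thresholds`.
    """
    trace = np.asarray(trace, dtype=float)
    deriv = np.asarray(deriv, dtype=float)
    if trace.shape != deriv.shape:
        raise ValueError("trace and derivative must be aligned")
    if pos_thr is None or neg_thr is None or level_thr is None:
        d_pos, d_neg, d_lvl = default_phase_thresholds(deriv, trace)
        pos_thr = d_pos if pos_thr is None else pos_thr
        neg_thr = d_neg if neg_thr is None else neg_thr
        level_thr = d_lvl if level_thr is None else level_thr
    if not pos_thr > 0:
        raise ValueError("pos_thr must be positive")
    if not neg_thr < 0:
        raise ValueError("neg_thr must be negative")

    labels = np.full(trace.shape, "", dtype=object)
    ok = np.isfinite(trace) & np.isfinite(deriv)
    rise = ok & (deriv > pos_thr)
    fall = ok & (deriv < neg_thr)
    rest = ok & ~rise & ~fall
    labels[rise] = "RISE"
    labels[fall] = "FALL"
    labels[rest & (trace >= level_thr)] = "HIGH"
    labels[rest & (trace < level_thr)] = "LOW"
    return NeuronPhaseSegmentation(
        labels=labels,
        frame_rate_hz=frame_rate_hz,
        pos_thr=float(pos_thr),
        neg_thr=float(neg_thr),
        level_thr=float(level_thr),
    )


def infer_command_states(
    phases: NeuronPhaseSegmentation,
    min_duration_s: float = 2.0,
) -> StateSegmentation:
    """Map command-neuron phases to forward / reverse / turn intervals.

    RISE and HIGH frames are the reversal command, FALL the post-reversal
    turn, LOW the forward command; adjacent same-command frames merge into
    intervals.  Missing frames extend the preceding interval.  Flicker
    shorter than ``min_duration_s`` (single-frame derivative excursions
    inside a plateau) is absorbed into the preceding interval.
    """
    fr = phases.frame_rate_hz
    labs = phases.labels
    cmd = [PHASE_TO_COMMAND.get(l, None) for l in labs]
    # carry command through missing frames
    last = None
    for i, c in enumerate(cmd):
        if c is None:
            cmd[i] = last
        else:
            last = c
    runs: list[list] = []  # [start, end, label]
    i = 0
    n = len(cmd)
    while i < n:
        if cmd[i] is None:
            i += 1
            continue
        j = i
        while j < n and cmd[j] == cmd[i]:
            j += 1
        runs.append([i, j, cmd[i]])
        i = j
    # absorb sub-threshold flicker into the previous run, iterating until
    # stable so merged neighbors collapse
    min_frames = max(1, int(round(min_duration_s * fr)))
    changed = True
    while changed and len(runs) > 1:
        changed = False
        out: list[list] = [runs[0]]
        for run in runs[1:]:
            prev = out[-1]
            if run[1] - run[0] < min_frames and run[1] < n:
                prev[1] = run[1]  # swallow the flicker
                changed = True
            elif run[2] == prev[2]:
                prev[1] = run[1]
                changed = True
            else:
                out.append(run)
        runs = out
    intervals = [(s / fr, e / fr, lab) for s, e, lab in runs]
    return StateSegmentation(intervals=intervals, source_neuron="")


def filter_forward_states(
    seg: StateSegmentation,
    min_duration_s: float = MIN_FORWARD_STATE_S,
) -> list[tuple[float, float]]:
    """Forward command states retained for frequency/covariogram analyses.

    Forward intervals shorter than ``min_duration_s`` are dropped (not
    relabeled); other labels are not returned.
    """
    return [
        (s, e) for s, e in seg.with_label("forward") if (e - s) >= min_duration_s
    ]


def state_durations(seg: StateSegmentation, label: str) -> list[float]:
    """Durations (s) of all intervals with the given label."""
    if label not in ("forward", "reverse", "turn"):
        raise ValueError(f"unknown state label {label!r}")
    return [e - s for s, e, lab in seg.intervals if lab == label]
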