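"""End-to-end analysis pipelines and synthetic benchmarks.

Two pipelines mirror the experimental designs: *immobilized* (trace
preprocessing -> command-state segmentation -> per-state statistics and
covariograms) and *moving* (kymogram -> propagation tracing -> phase
nesting).  The synthetic benchmark generates ground-truth data and runs the
moving pipeline against it, reporting classification agreement and nesting
statistics.  All randomized stages draw from seeded, stage-named substreams
so changing one stage's repetitions does not perturb the others.
"""

from __future__ import annotations

import hashlib
import json
import math
import zlib
from dataclasses import asdict

import numpy as np

from .eventstats import EventTrain, covariogram, bhy_correct, ipi_randomness_test
from .kymo import (
    HeadBendEvent,
    Kymogram,
    LocomotionBouts,
    build_peak_kymogram,
    cycle_periods,
    preprocess_kymogram,
    trace_propagations,
)
from .peaks import detect_peaks, auto_delta
from .phase import (
    assign_event_phases,
    detection_allowed_mask,
    interp_phase,
    polar_skewness_test,
)
from .states import (
    filter_forward_states,
    infer_command_states,
    segment_neuron_phases,
    state_durations,
)
from .synthetic import BehaviorSimConfig, gen_kymogram
from .traces import TraceSet, compute_dff, detrend_two_step, Trace

__all__ = [
    "stage_rng",
    "analyze_kymogram",
    "match_ground_truth",
    "headcast_phase_analysis",
    "window_of_opportunity_sweep",
    "run_immobilized",
    "run_synthetic_benchmark",
    "config_hash",
]

#: default detection threshold for synthetic/behavior kymograms (rad); the
#: per-column auto-delta is available via delta="auto"
DEFAULT_BEHAVIOR_DELTA = 0.3


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Independent, reproducible RNG substream named after a pipeline stage."""
    key = zlib.crc32(stage.encode()) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))


def config_hash(cfg) -> str:
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha1(blob).hexdigest()[:12]


# ---------------------------------------------------------------------------
# moving / behavior pipeline
# ---------------------------------------------------------------------------

def analyze_kymogram(
    kym: Kymogram,
    bouts: LocomotionBouts,
    *,
    delta=DEFAULT_BEHAVIOR_DELTA,
    smooth_window_s: float = 0.3,
):
    """Preprocess, peak-detect, and trace all head bends.

    Returns
    -------
    (events, peak_kymogram, preprocessed_kymogram)
    """
    kp = preprocess_kymogram(kym, smooth_window_s=smooth_window_s)
    pk = build_peak_kymogram(kp, delta)
    events = trace_propagations(pk, bouts)
    return events, pk, kp


def match_ground_truth(
    events: list[HeadBendEvent],
    gt,
    frame_rate_hz: float,
    tol_s: float = 0.35,
):
    """Match traced events to generator ground truth and score agreement.

    Each ground-truth bend is matched to the nearest unused detected event
    of the same bout direction whose seed time lies within ``tol_s``;
    agreement is the fraction of ground-truth bends whose matched event
    carries the same class label.

    Returns a dict with agreement, per-class counts, and miss counts.
    """
    fr = frame_rate_hz
    by_bout: dict[str, list] = {"forward": [], "reverse": []}
    for i, ev in enumerate(events):
        by_bout[ev.bout_label].append((ev.onset_frame / fr, i))
    for lab in by_bout:
        by_bout[lab].sort()

    used = set()
    n_match = n_agree = 0
    confusion: dict[tuple[str, str], int] = {}
    for bend in sorted(gt.bends, key=lambda b: b.seed_time_s):
        cands = by_bout.get(bend.bout_label, [])
        best = None
        for t, i in cands:
            if i in used or abs(t - bend.seed_time_s) > tol_s:
                continue
            d = abs(t - bend.seed_time_s)
            if best is None or d < best[0]:
                best = (d, i)
        if best is None:
            confusion[(bend.class_label, "missed")] = (
                confusion.get((bend.class_label, "missed"), 0) + 1
            )
            continue
        used.add(best[1])
        got = events[best[1]].class_label
        n_match += 1
        if got == bend.class_label:
            n_agree += 1
        confusion[(bend.class_label, got)] = (
            confusion.get((bend.class_label, got), 0) + 1
        )
    n_gt = len(gt.bends)
    return {
        "n_ground_truth": n_gt,
        "n_matched": n_match,
        "n_agree": n_agree,
        "agreement": n_agree / n_gt if n_gt else float("nan"),
        "confusion": confusion,
    }


def headcast_phase_analysis(
    kym: Kymogram,
    bouts: LocomotionBouts,
    *,
    delta=DEFAULT_BEHAVIOR_DELTA,
    smooth_window_s: float = 0.3,
    n_resamples: int = 10_000,
    n_bins: int = 16,
    rng: np.random.Generator | None = None,
    compute_p: bool = True,
):
    """Full phase-nesting analysis of one behavior recording.

    Traces head bends, builds the propagated-bend phase by interpolation
    between dorsal and ventral propagated-bend maxima, samples the phase of
    the first head-cast after each propagated bend, and (optionally) tests
    the sampled distribution's skewness against the detection-constrained
    all-phases distribution by resampling.
    """
    events, pk, kp = analyze_kymogram(
        kym, bouts, delta=delta, smooth_window_s=smooth_window_s
    )
    fr = kym.frame_rate_hz
    fwd = [ev for ev in events if ev.bout_label == "forward"]
    props = [ev for ev in fwd if ev.class_label == "propagated"]
    casts = [ev for ev in fwd if ev.class_label == "head_cast"]
    prop_t = np.array([ev.onset_frame / fr for ev in props])
    prop_s = [ev.sign for ev in props]
    order = np.argsort(prop_t)
    prop_t = prop_t[order]
    prop_s = [prop_s[i] for i in order]

    dorsal_t = prop_t[[s == "dorsal" for s in prop_s]]
    ventral_t = prop_t[[s == "ventral" for s in prop_s]]
    ps = interp_phase(dorsal_t, ventral_t, kym.n_frames, fr)

    cast_t = sorted(ev.onset_frame / fr for ev in casts)
    samples, dropped = assign_event_phases(
        cast_t, ps, "initial_headcast",
        context_times_s=prop_t, context_signs=prop_s,
    )

    # detection-constrained allowed frames on the seed angle (#2)
    col2 = np.where(kp.missing_mask[:, 1], np.nan, kp.angles[:, 1])
    peak_frames = np.flatnonzero(pk.values[:, 1] != 0)
    allowed = detection_allowed_mask(col2, peak_frames, float(pk.deltas[1]))
    allowed &= ps.valid & np.isfinite(col2)

    cycles = []
    for s in samples:
        i = int(np.searchsorted(prop_t, s.time_s)) - 1
        t0 = prop_t[i] if i >= 0 else 0.0
        t1 = prop_t[i + 1] if i + 1 < prop_t.size else kym.n_frames / fr
        f0 = max(0, int(math.ceil(t0 * fr)))
        f1 = min(kym.n_frames, int(math.ceil(t1 * fr)))
        idx = np.arange(f0, f1)
        sel = idx[allowed[idx]]
        if sel.size == 0:
            sel = idx[ps.valid[idx]]
        cycles.append(ps.phase[sel])

    p = None
    if compute_p and samples and all(len(c) for c in cycles):
        p = polar_skewness_test(
            [s.phase for s in samples], cycles, n_resamples, n_bins, rng=rng
        )
    return {
        "events": events,
        "phase_series": ps,
        "samples": samples,
        "cycles": cycles,
        "n_dropped": dropped,
        "p_value": p,
        "n_propagated": len(props),
        "n_head_casts": len(casts),
    }


def window_of_opportunity_sweep(
    *,
    wave_freqs_hz=(0.5, 0.25),
    duration_s: float = 1200.0,
    gate=(0.0, math.pi),
    attempt_rate_hz: float = 1.0,
    noise_sd_rad: float = 0.05,
    seed: int = 0,
    delta=DEFAULT_BEHAVIOR_DELTA,
):
    """Head-cast frequency and recovered gate support across wave frequencies.

    Holds the phase gate fixed while sweeping the propagated-bend frequency;
    slower waves open longer within-gate time windows, so the recovered
    head-cast rate should rise while the recovered initiation phases stay
    inside the same gate.
    """
    out = {}
    for i, f in enumerate(wave_freqs_hz):
        cfg = BehaviorSimConfig(
            duration_s=duration_s,
            wave_freq_hz=f,
            headcast_gate=tuple(gate),
            headcast_attempt_rate_hz=attempt_rate_hz,
            reversal_rate_hz=0.0,
            noise_sd_rad=noise_sd_rad,
            seed=int(np.random.SeedSequence([seed, i]).generate_state(1)[0] % (2**31)),
        )
        kym, bouts, gt = gen_kymogram(cfg)
        res = headcast_phase_analysis(kym, bouts, delta=delta, compute_p=False)
        phases = np.array([s.phase for s in res["samples"]])
        out[f] = {
            "headcast_rate_hz": res["n_head_casts"] / duration_s,
            "n_head_casts": res["n_head_casts"],
            "recovered_phases": phases,
            "phase_lo": float(np.min(phases)) if phases.size else float("nan"),
            "phase_hi": float(np.max(phases)) if phases.size else float("nan"),
            "true_cast_count": len(gt.cast_initiation_phases),
        }
    return out


# ---------------------------------------------------------------------------
# immobilized pipeline
# ---------------------------------------------------------------------------

def preprocess_traces(ts: TraceSet, background: float = 0.0):
    """Background-subtracted ΔF/F₀ plus two-step detrending, per neuron."""
    dffs = np.empty_like(ts.F)
    detr = np.empty_like(ts.F)
    fallbacks = []
    for i in range(ts.n_neurons):
        tr = Trace(F=ts.F[i], frame_rate_hz=ts.frame_rate_hz, background=background)
        dff = compute_dff(tr)
        det, fb = detrend_two_step(dff, ts.frame_rate_hz)
        dffs[i], detr[i] = dff, det
        fallbacks.append(fb)
    return dffs, detr, fallbacks


def _smooth_gradient(x: np.ndarray, fr: float, window_s: float = 2.0) -> np.ndarray:
    win = max(1, int(round(window_s * fr)))
    if win % 2 == 0:
        win += 1
    if win > 1:
        kern = np.ones(win) / win
        x = np.convolve(np.pad(x, win // 2, mode="edge"), kern, mode="valid")
    return np.gradient(x, 1.0 / fr)


def run_immobilized(
    ts: TraceSet,
    command_neuron: str = "AVA",
    *,
    background: float = 0.0,
    n_resamples: int = 10_000,
    seed: int = 0,
    pair_covariograms: bool = False,
):
    """Immobilized pipeline: traces -> states -> per-state statistics.

    Detrends every trace, segments command states from the designated
    command neuron, and computes per-neuron activity-peak frequencies within
    retained (>= 50 s) forward states, inter-peak-interval randomness p
    values (BHY-corrected), and optionally all pairwise covariograms.
    """
    fr = ts.frame_rate_hz
    dffs, detr, fallbacks = preprocess_traces(ts, background)
    cmd_idx = ts.labels.index(command_neuron)
    cmd = detr[cmd_idx]
    deriv = _smooth_gradient(cmd, fr)
    phases = segment_neuron_phases(cmd, deriv, frame_rate_hz=fr)
    seg = infer_command_states(phases)
    seg.source_neuron = command_neuron
    fwd = filter_forward_states(seg)

    trains: dict[str, np.ndarray] = {}
    freqs: dict[str, list[float]] = {}
    for i, lab in enumerate(ts.labels):
        if lab == command_neuron:
            continue
        delta = auto_delta(detr[i], "immobilized_raw")
        pk = detect_peaks(detr[i], delta)
        times = pk.maxima / fr
        keep = np.zeros(times.size, dtype=bool)
        for s, e in fwd:
            keep |= (times >= s) & (times < e)
        trains[lab] = times[keep]
        from .population import peak_frequency_per_state

        freqs[lab] = peak_frequency_per_state(times, fwd)

    rng = stage_rng(seed, "ipi")
    ipi_p: dict[str, float] = {}
    for lab, times in trains.items():
        try:
            ipi_p[lab] = ipi_randomness_test(times, fwd, fr, n_resamples, rng=rng)
        except ValueError:
            ipi_p[lab] = float("nan")
    labs = [l for l in ipi_p if np.isfinite(ipi_p[l])]
    flags = bhy_correct([ipi_p[l] for l in labs]) if labs else np.zeros(0, bool)
    rhythmic = {l: bool(f) for l, f in zip(labs, flags)}

    covs = {}
    if pair_covariograms:
        crng = stage_rng(seed, "covariogram")
        labels = list(trains)
        for a in labels:
            for b in labels:
                if a == b or trains[a].size == 0:
                    continue
                covs[(a, b)] = covariogram(
                    EventTrain(trains[a], a, fr),
                    EventTrain(trains[b], b, fr),
                    fwd, n_resamples, rng=crng,
                )
    return {
        "segmentation": seg,
        "forward_states": fwd,
        "reverse_durations": state_durations(seg, "reverse"),
        "event_trains": trains,
        "peak_frequencies": freqs,
        "ipi_p_values": ipi_p,
        "rhythmic": rhythmic,
        "covariograms": covs,
        "detrend_fallbacks": dict(zip(ts.labels, fallbacks)),
        "detrended": detr,
    }


# ---------------------------------------------------------------------------
# synthetic benchmark
# ---------------------------------------------------------------------------

def run_synthetic_benchmark(seed: int = 0, duration_s: float = 600.0):
    """Generate a default behavior recording and score the full analysis."""
    cfg = BehaviorSimConfig(duration_s=duration_s, seed=seed)
    kym, bouts, gt = gen_kymogram(cfg)
    res = headcast_phase_analysis(
        kym, bouts, n_resamples=2000, rng=stage_rng(seed, "nesting")
    )
    score = match_ground_truth(res["events"], gt, kym.frame_rate_hz)
    periods = cycle_periods(res["events"], "propagated_full", kym.frame_rate_hz)
    return {
        "config_hash": config_hash(asdict(cfg)),
        "seed": seed,
        "n_ground_truth_bends": score["n_ground_truth"],
        "n_detected_events": len(res["events"]),
        "classification_agreement": score["agreement"],
        "n_head_casts": res["n_head_casts"],
        "n_propagated": res["n_propagated"],
        "median_propagated_cycle_s": float(np.median(periods)) if periods else None,
        "nesting_p_value": res["p_value"],
    }
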