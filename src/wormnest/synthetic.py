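"""Ground-truth simulators for nested locomotor and neural dynamics.

Three generators emulate the data the analysis stack consumes, with full
ground truth so every downstream stage is verifiable without recordings:

``gen_kymogram``
    Posture kymograms built from an alternating sequence of discrete head
    bends.  Each bend is a smooth flexion bump that travels posteriorly with
    a fixed per-segment delay; propagated-bends reach the tail (segment 24)
    while head-cast pairs stop at an anterior extent segment.  Cast episodes
    may only initiate while the body-wave phase lies inside a configurable
    gate *and* the current half-cycle leaves enough room for the episode —
    the window-of-opportunity mechanism, which makes slower waves carry more
    casts per unit time while the gate's phase boundaries stay fixed.
    During reversal bouts the wave travels tail to head and casts are
    suppressed.

``gen_traces``
    Calcium fluorescence for a population of neurons riding a slow
    forward/reverse command cycle: state-dependent event rates, double
    exponential event kernels, optional lagged coupling between neurons,
    multiplicative photobleaching, and additive Gaussian noise.  A
    ``command`` mode neuron follows the reverse state directly (an AVA-like
    command interneuron).

``gen_event_trains``
    Discrete event trains inside forward states, with optional lagged
    (excitatory) or suppressive coupling between pairs — a direct fixture
    for the covariogram statistics.

All generators draw from a single ``numpy.random.default_rng(seed)`` stream
per call; identical configs give bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .kymo import Kymogram, LocomotionBouts, N_ANGLES

__all__ = [
    "BehaviorSimConfig",
    "NeuronSpec",
    "NeuralSimConfig",
    "CouplingSpec",
    "GroundTruthBend",
    "BehaviorGroundTruth",
    "NeuralGroundTruth",
    "gen_kymogram",
    "gen_traces",
    "gen_event_trains",
]

TWO_PI = 2.0 * math.pi


# ---------------------------------------------------------------------------
# configs and ground-truth records
# ---------------------------------------------------------------------------

@dataclass
class BehaviorSimConfig:
    """Forward model of the three-timescale behavioral hierarchy.

    The propagated-bend wave runs at ``wave_freq_hz`` (bends at twice that
    rate, alternating dorsal/ventral) with lognormal cycle-to-cycle period
    jitter ``period_jitter_cv``.  Head-cast episodes (one pair of opposite
    casts, i.e. a half-cycle of the ``headcast_freq_hz`` oscillation) may
    initiate only at body-wave phases inside ``headcast_gate`` (radians,
    half-open; phase 0 = dorsal propagated-bend peak, pi = ventral) and only
    when the initiation leaves ``min_separation_s`` to the flanking
    propagated bends.  Episode occurrence per half-cycle is
    ``1 - exp(-headcast_attempt_rate_hz * usable_window)`` unless
    ``headcast_rate_per_cycle`` overrides it with a fixed probability.
    Reversal bouts arrive as a Poisson process; during them the wave travels
    tail to head and no casts are generated.
    """

    duration_s: float = 600.0
    frame_rate_hz: float = 10.0
    wave_freq_hz: float = 0.5
    wave_amp_rad: float = 0.5
    phase_lag_per_segment_rad: float = 0.4
    headcast_freq_hz: float = 1.0
    headcast_extent_segment: int = 8
    headcast_gate: tuple[float, float] = (0.0, math.pi)
    headcast_rate_per_cycle: float | None = None
    headcast_attempt_rate_hz: float = 1.0
    headcast_amp_rad: float = 0.5
    reversal_rate_hz: float = 0.01
    reversal_duration_s: float = 4.0
    noise_sd_rad: float = 0.05
    period_jitter_cv: float = 0.15
    min_separation_s: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "duration_s", "frame_rate_hz", "wave_freq_hz", "wave_amp_rad",
            "headcast_freq_hz", "reversal_duration_s",
        ):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be positive and finite, got {v!r}")
        for name in (
            "phase_lag_per_segment_rad", "headcast_attempt_rate_hz",
            "headcast_amp_rad", "reversal_rate_hz", "noise_sd_rad",
            "period_jitter_cv", "min_separation_s",
        ):
            v = getattr(self, name)
            if not (np.isfinite(v) and v >= 0):
                raise ValueError(f"{name} must be non-negative, got {v!r}")
        if not 1 <= self.headcast_extent_segment <= 13:
            raise ValueError("headcast_extent_segment must be in 1..13")
        lo, hi = self.headcast_gate
        if not (0 <= lo < hi <= TWO_PI):
            raise ValueError("headcast_gate must satisfy 0 <= lo < hi <= 2*pi")
        if self.headcast_rate_per_cycle is not None and not (
            0 <= self.headcast_rate_per_cycle <= 1
        ):
            raise ValueError("headcast_rate_per_cycle must be in [0, 1]")


@dataclass
class GroundTruthBend:
    """One generated head bend."""

    onset_s: float          # time the flexion peaks at its origin segment
    seed_time_s: float      # peak time at the tracer's seed angle (#2)
    sign: str               # "dorsal" or "ventral"
    class_label: str        # "propagated" or "head_cast"
    extent_segment: int     # posterior-most segment carrying the bump
    bout_label: str         # "forward" or "reverse"


@dataclass
class BehaviorGroundTruth:
    bends: list[GroundTruthBend]
    cast_initiation_phases: list[float]   # rad, one per episode
    cast_context_signs: list[str]         # preceding propagated bend's sign
    reversal_intervals_s: list[tuple[float, float]]
    config: BehaviorSimConfig


@dataclass
class NeuronSpec:
    """One simulated neuron.

    ``mode="events"``: sparse calcium events at state-dependent rates with a
    double-exponential kernel.  ``mode="command"``: the trace follows the
    reverse-state indicator with first-order rise/decay kinetics (a command
    interneuron).  ``coupled_to`` makes every event a lag-shifted copy of
    the partner's events (plus Gaussian jitter).
    """

    label: str
    rate_forward_hz: float = 0.04
    rate_reverse_hz: float = 0.0
    kernel_rise_s: float = 1.5
    kernel_decay_s: float = 6.0
    amplitude: float = 1.0
    baseline: float = 1.0
    coupled_to: str | None = None
    lag_s: float = 0.0
    jitter_s: float = 0.0
    min_interval_s: float = 0.0  # refractory gap between successive events
    mode: str = "events"


@dataclass
class NeuralSimConfig:
    duration_s: float = 1800.0
    frame_rate_hz: float = 3.0
    mean_forward_s: float = 100.0
    mean_reverse_s: float = 25.0
    state_duration_cv: float = 0.4
    neurons: list[NeuronSpec] = field(default_factory=list)
    bleach_tau_s: float = 900.0
    noise_sd: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        if not (self.duration_s > 0 and self.frame_rate_hz > 0):
            raise ValueError("duration and frame rate must be positive")
        if not self.bleach_tau_s > 0:
            raise ValueError("bleach_tau_s must be positive (np.inf for no bleach)")
        labels = [n.label for n in self.neurons]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate neuron labels")
        for n in self.neurons:
            if n.rate_forward_hz < 0 or n.rate_reverse_hz < 0:
                raise ValueError(f"{n.label}: rates must be >= 0")
            if not np.isfinite(n.lag_s):
                raise ValueError(f"{n.label}: lag must be finite")
            if n.coupled_to is not None and n.coupled_to not in labels:
                raise ValueError(
                    f"{n.label} coupled to undefined partner {n.coupled_to!r}"
                )
            if n.mode not in ("events", "command"):
                raise ValueError(f"{n.label}: unknown mode {n.mode!r}")


@dataclass
class NeuralGroundTruth:
    event_times: dict[str, np.ndarray]
    state_intervals_s: list[tuple[float, float, str]]
    coupling_lags: dict[str, tuple[str, float]]
    config: NeuralSimConfig


# ---------------------------------------------------------------------------
# behavior generator
# ---------------------------------------------------------------------------

def _draw_reversals(cfg: BehaviorSimConfig, rng: np.random.Generator):
    """Poisson reversal bouts, merged and clipped to the recording."""
    if cfg.reversal_rate_hz <= 0:
        return []
    t, out = 0.0, []
    min_dur = 1.5 / cfg.wave_freq_hz  # long enough for >= one reverse cycle
    while True:
        t += rng.exponential(1.0 / cfg.reversal_rate_hz)
        if t >= cfg.duration_s - min_dur - 2.0:
            break
        dur = max(min_dur, rng.exponential(cfg.reversal_duration_s))
        end = min(t + dur, cfg.duration_s - 1.0)
        if out and t <= out[-1][1] + 2.0:
            out[-1] = (out[-1][0], max(out[-1][1], end))
        else:
            out.append((t, end))
        t = end
    return out


@dataclass
class _Bump:
    time: float      # peak time at origin segment
    sign: int
    amp: float
    extent: int      # posterior-most segment (1-based)
    reverse: bool    # tail-to-head travel
    is_cast: bool


def _gate_windows(lo, hi, offset):
    """Intersect the gate with one half-cycle's phase span [offset, offset+pi)."""
    a = max(lo, offset)
    b = min(hi, offset + math.pi)
    return (a, b) if a < b else None


def gen_kymogram(cfg: BehaviorSimConfig):
    """Simulate a posture kymogram with full bend-level ground truth.

    Returns
    -------
    (Kymogram, LocomotionBouts, BehaviorGroundTruth)
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    fr = cfg.frame_rate_hz
    n_frames = int(round(cfg.duration_s * fr))
    tau = cfg.phase_lag_per_segment_rad / (TWO_PI * cfg.wave_freq_hz)
    prop_time = (N_ANGLES - 1) * tau
    half_period = 1.0 / (2.0 * cfg.wave_freq_hz)
    h_cast = 1.0 / (2.0 * cfg.headcast_freq_hz)  # inter-cast interval
    sep = cfg.min_separation_s
    sigma = math.sqrt(math.log(1.0 + cfg.period_jitter_cv**2))
    edge = 0.4  # quiet margin at bout edges, seconds

    reversals = _draw_reversals(cfg, rng)
    bouts_s: list[tuple[float, float, str]] = []
    prev = 0.0
    for s, e in reversals:
        if s > prev:
            bouts_s.append((prev, s, "forward"))
        bouts_s.append((s, e, "reverse"))
        prev = e
    if prev < cfg.duration_s:
        bouts_s.append((prev, cfg.duration_s, "forward"))

    bumps: list[_Bump] = []
    bends: list[GroundTruthBend] = []
    cast_phases: list[float] = []
    cast_ctx: list[str] = []
    glo, ghi = cfg.headcast_gate
    sign = 1 if rng.random() < 0.5 else -1  # global alternation chain

    for bs, be, lab in bouts_s:
        rev = lab == "reverse"
        # propagated-bend onsets at the origin segment (head for forward
        # bouts, tail for reverse bouts); full propagation must fit in-bout
        t = bs + edge
        last_ok = be - edge - prop_time
        onsets: list[float] = []
        while t <= last_ok:
            onsets.append(t)
            t += half_period * math.exp(sigma * rng.standard_normal())
        if len(onsets) < 2:
            # bout too short for a wave; draw nothing but keep rng use stable
            continue
        bout_signs = []
        for on in onsets:
            bout_signs.append(sign)
            sign = -sign

        for k, (on, s_k) in enumerate(zip(onsets, bout_signs)):
            bumps.append(_Bump(on, s_k, cfg.wave_amp_rad, N_ANGLES, rev, False))
            bends.append(GroundTruthBend(
                onset_s=on,
                seed_time_s=on + tau,
                sign="ventral" if s_k > 0 else "dorsal",
                class_label="propagated",
                extent_segment=N_ANGLES,
                bout_label=lab,
            ))
            if rev or k + 1 >= len(onsets):
                continue
            # head-cast opportunity in the half-cycle (on, next)
            nxt = onsets[k + 1]
            T_k = nxt - on
            # phase 0 = dorsal peak; this half-cycle spans [offset, offset+pi)
            offset = 0.0 if s_k < 0 else math.pi
            win = _gate_windows(glo, ghi, offset)
            if win is None:
                continue
            t_lo = on + (win[0] - offset) / math.pi * T_k
            t_hi = on + (win[1] - offset) / math.pi * T_k
            t_lo = max(t_lo, on + sep)
            t_hi = min(t_hi, nxt - sep - h_cast)
            L = t_hi - t_lo
            if L <= 0:
                continue
            if cfg.headcast_rate_per_cycle is not None:
                p = cfg.headcast_rate_per_cycle
            else:
                p = 1.0 - math.exp(-cfg.headcast_attempt_rate_hz * L)
            if rng.random() >= p:
                continue
            t0 = t_lo + rng.random() * L
            phase0 = offset + math.pi * (t0 - on) / T_k
            cast_phases.append(phase0 % TWO_PI)
            cast_ctx.append("ventral" if s_k > 0 else "dorsal")
            for ci, tc in enumerate((t0, t0 + h_cast)):
                c_sign = -s_k if ci == 0 else s_k
                bumps.append(_Bump(
                    tc, c_sign, cfg.headcast_amp_rad,
                    cfg.headcast_extent_segment, rev, True,
                ))
                bends.append(GroundTruthBend(
                    onset_s=tc,
                    seed_time_s=tc + tau,
                    sign="ventral" if c_sign > 0 else "dorsal",
                    class_label="head_cast",
                    extent_segment=cfg.headcast_extent_segment,
                    bout_label=lab,
                ))

    # rasterize: per column, cosine-chain interpolation between bend peaks
    t_grid = np.arange(n_frames) / fr
    angles = np.zeros((n_frames, N_ANGLES))
    pad = half_period
    for j in range(1, N_ANGLES + 1):
        nodes = []
        for b in bumps:
            if j > b.extent and not b.reverse:
                continue
            if b.reverse:
                pt = b.time + (N_ANGLES - j) * tau
            else:
                pt = b.time + (j - 1) * tau
            nodes.append((pt, b.sign * b.amp))
        if not nodes:
            continue
        nodes.sort()
        # relax to a straight posture (angle 0) inside long inter-bend gaps
        # (bout transitions) so every bend peak keeps a sharp flank
        relaxed = []
        for (t_a, v_a), (t_b, v_b) in zip(nodes, nodes[1:]):
            relaxed.append((t_a, v_a))
            if t_b - t_a > 2.0 * half_period:
                relaxed.append((t_a + half_period, 0.0))
                relaxed.append((t_b - half_period, 0.0))
        relaxed.append(nodes[-1])
        u = np.array([n[0] for n in relaxed])
        v = np.array([n[1] for n in relaxed])
        u = np.concatenate([[u[0] - pad], u, [u[-1] + pad]])
        v = np.concatenate([[0.0], v, [0.0]])
        idx = np.clip(np.searchsorted(u, t_grid, side="right") - 1, 0, u.size - 2)
        x = (t_grid - u[idx]) / (u[idx + 1] - u[idx])
        x = np.clip(x, 0.0, 1.0)
        angles[:, j - 1] = v[idx] + (v[idx + 1] - v[idx]) * 0.5 * (
            1.0 - np.cos(math.pi * x)
        )
    if cfg.noise_sd_rad > 0:
        angles = angles + rng.normal(0.0, cfg.noise_sd_rad, angles.shape)

    kym = Kymogram(angles=angles, frame_rate_hz=fr, ventral_positive=True)
    bouts = LocomotionBouts.from_reversals(reversals, n_frames, fr)
    bends.sort(key=lambda b: b.onset_s)
    gt = BehaviorGroundTruth(
        bends=bends,
        cast_initiation_phases=cast_phases,
        cast_context_signs=cast_ctx,
        reversal_intervals_s=reversals,
        config=cfg,
    )
    return kym, bouts, gt


# ---------------------------------------------------------------------------
# neural trace generator
# ---------------------------------------------------------------------------

def _draw_states(cfg: NeuralSimConfig, rng: np.random.Generator):
    sigma = math.sqrt(math.log(1.0 + cfg.state_duration_cv**2))
    out, t, lab = [], 0.0, "forward"
    while t < cfg.duration_s:
        mean = cfg.mean_forward_s if lab == "forward" else cfg.mean_reverse_s
        dur = mean * math.exp(sigma * rng.standard_normal() - sigma**2 / 2)
        end = min(t + dur, cfg.duration_s)
        out.append((t, end, lab))
        t = end
        lab = "reverse" if lab == "forward" else "forward"
    return out


def kernel_peak_delay(rise: float, decay: float) -> float:
    """Time from event onset to the double-exponential kernel's peak."""
    if rise >= decay:
        rise = 0.9 * decay
    return rise * decay / (decay - rise) * math.log(decay / rise)


def _event_kernel(t: np.ndarray, rise: float, decay: float) -> np.ndarray:
    """Double-exponential transient, normalized to unit peak."""
    if rise >= decay:
        rise = 0.9 * decay
    tp = np.maximum(t, 0.0)
    g = np.where(t >= 0, np.exp(-tp / decay) - np.exp(-tp / rise), 0.0)
    t_pk = rise * decay / (decay - rise) * math.log(decay / rise)
    peak = math.exp(-t_pk / decay) - math.exp(-t_pk / rise)
    return g / peak


def gen_traces(cfg: NeuralSimConfig):
    """Simulate a fluorescence TraceSet riding a forward/reverse command cycle.

    Returns
    -------
    (TraceSet, NeuralGroundTruth)
    """
    from .traces import TraceSet  # local import to avoid a cycle

    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    fr = cfg.frame_rate_hz
    n = int(round(cfg.duration_s * fr))
    t_grid = np.arange(n) / fr
    states = _draw_states(cfg, rng)

    state_rate = {}
    for s, e, lab in states:
        i0, i1 = int(round(s * fr)), int(round(e * fr))
        state_rate[(i0, min(i1, n))] = lab

    events: dict[str, np.ndarray] = {}
    lags: dict[str, tuple[str, float]] = {}
    # independent neurons first, then coupled copies
    order = sorted(cfg.neurons, key=lambda ns: ns.coupled_to is not None)
    for ns in order:
        if ns.mode == "command":
            events[ns.label] = np.array([])
            continue
        if ns.coupled_to is None:
            p = np.zeros(n)
            for (i0, i1), lab in state_rate.items():
                r = ns.rate_forward_hz if lab == "forward" else ns.rate_reverse_hz
                p[i0:i1] = r / fr
            hits = np.flatnonzero(rng.random(n) < p)
            te = hits / fr
            if ns.min_interval_s > 0 and te.size:
                kept = [te[0]]
                for t_ev in te[1:]:
                    if t_ev - kept[-1] >= ns.min_interval_s:
                        kept.append(t_ev)
                te = np.asarray(kept)
            events[ns.label] = te
        else:
            src = events[ns.coupled_to]
            jit = (
                rng.normal(0.0, ns.jitter_s, src.size)
                if ns.jitter_s > 0 else np.zeros(src.size)
            )
            te = np.sort(src + ns.lag_s + jit)
            events[ns.label] = te[(te >= 0) & (te < cfg.duration_s)]
            lags[ns.label] = (ns.coupled_to, ns.lag_s)

    F = np.zeros((len(cfg.neurons), n))
    bleach = (
        np.exp(-t_grid / cfg.bleach_tau_s)
        if np.isfinite(cfg.bleach_tau_s) else np.ones(n)
    )
    for i, ns in enumerate(cfg.neurons):
        if ns.mode == "command":
            x = np.zeros(n)
            target = np.zeros(n)
            for (i0, i1), lab in state_rate.items():
                if lab == "reverse":
                    target[i0:i1] = 1.0
            a_r = math.exp(-1.0 / (fr * ns.kernel_rise_s))
            a_d = math.exp(-1.0 / (fr * ns.kernel_decay_s))
            for k in range(1, n):
                a = a_r if target[k] > x[k - 1] else a_d
                x[k] = target[k] + (x[k - 1] - target[k]) * a
            sig = ns.baseline + ns.amplitude * x
        else:
            sig = np.full(n, ns.baseline)
            for te in events[ns.label]:
                i0 = int(math.floor(te * fr))
                i1 = min(n, i0 + int(10 * ns.kernel_decay_s * fr))
                if i1 <= i0:
                    continue
                sig[i0:i1] += ns.amplitude * _event_kernel(
                    t_grid[i0:i1] - te, ns.kernel_rise_s, ns.kernel_decay_s
                )
        F[i] = sig * bleach
    if cfg.noise_sd > 0:
        F = F + rng.normal(0.0, cfg.noise_sd, F.shape)

    ts = TraceSet(
        F=F,
        labels=[ns.label for ns in cfg.neurons],
        frame_rate_hz=fr,
        provenance=["raw:synthetic"],
    )
    gt = NeuralGroundTruth(
        event_times=events,
        state_intervals_s=states,
        coupling_lags=lags,
        config=cfg,
    )
    return ts, gt


# ---------------------------------------------------------------------------
# event-train generator
# ---------------------------------------------------------------------------

@dataclass
class CouplingSpec:
    """Pairwise event coupling: ``fraction`` of reference events are copied
    into the target at ``lag_s`` (+- ``jitter_s``); ``mode="suppress"``
    instead removes target events within ``suppress_halfwidth_s`` of the
    lagged reference events."""

    fraction: float = 0.0
    lag_s: float = 0.0
    jitter_s: float = 0.0
    mode: str = "excite"
    suppress_halfwidth_s: float = 10.0


def gen_event_trains(
    n_pairs: int,
    coupling: CouplingSpec,
    states: list[tuple[float, float]],
    *,
    rate_hz: float = 0.04,
    frame_rate_hz: float = 3.0,
    seed: int = 0,
):
    """Poisson event-train pairs inside forward states, optionally coupled.

    Events are Bernoulli draws on the frame grid (rate_hz / frame_rate_hz
    per frame), the discrete analog of a homogeneous Poisson process, so
    that conditional on the per-state counts the times are exactly uniform
    without replacement — the null the covariogram resampler assumes.

    Returns
    -------
    (pairs, coupled) : list of (ref_times, tgt_times) arrays in seconds,
    and the list of pair indices that carry coupling.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    rate_ref, rate_tgt = (
        rate_hz if isinstance(rate_hz, (tuple, list)) else (rate_hz, rate_hz)
    )
    if rate_ref < 0 or rate_tgt < 0:
        raise ValueError("rates must be >= 0")
    rng = np.random.default_rng(seed)
    fr = frame_rate_hz
    frames = []
    for s, e in states:
        frames.append(np.arange(int(round(s * fr)), int(round(e * fr))))
    frames = np.concatenate(frames) if frames else np.array([], dtype=int)

    def _poisson_train(rate: float) -> np.ndarray:
        hit = frames[rng.random(frames.size) < rate / fr]
        return hit / fr

    def _state_of(t: float):
        for s, e in states:
            if s <= t < e:
                return (s, e)
        return None

    pairs = []
    coupled = []
    for i in range(n_pairs):
        ref = _poisson_train(rate_ref)
        if coupling.fraction > 0 and coupling.mode == "excite":
            keep = rng.random(ref.size) < coupling.fraction
            jit = (
                rng.normal(0.0, coupling.jitter_s, int(keep.sum()))
                if coupling.jitter_s > 0 else 0.0
            )
            copies = ref[keep] + coupling.lag_s + jit
            # copies must stay in the same state as their source
            ok = np.array([
                _state_of(c) is not None and _state_of(c) == _state_of(r)
                for c, r in zip(np.atleast_1d(copies), ref[keep])
            ], dtype=bool)
            copies = np.atleast_1d(copies)[ok]
            base = _poisson_train(rate_tgt)
            base = base[rng.random(base.size) < (1.0 - coupling.fraction)]
            tgt = np.unique(np.concatenate([base, copies]))
            coupled.append(i)
        elif coupling.fraction > 0 and coupling.mode == "suppress":
            tgt = _poisson_train(rate_tgt)
            centers = ref + coupling.lag_s
            if centers.size and tgt.size:
                d = np.min(np.abs(tgt[:, None] - centers[None, :]), axis=1)
                drop = (d <= coupling.suppress_halfwidth_s) & (
                    rng.random(tgt.size) < coupling.fraction
                )
                tgt = tgt[~drop]
            coupled.append(i)
        else:
            tgt = _poisson_train(rate_tgt)
        # snap coupled copies to the frame grid for resampler comparability
        tgt = np.unique(np.round(tgt * fr) / fr)
        pairs.append((np.sort(ref), np.sort(tgt)))
    return pairs, coupled
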