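"""Fluorescence trace preprocessing.

Single-channel immobilized recordings: background-subtracted ΔF/F₀ with F₀
the trial mean, followed by two-step photobleaching correction (an
exponential fit to the full trace, then an exponential fit to its detected
peaks) with a variance-change fallback for the rare traces the second step
distorts.  Dual-channel moving recordings: the GCaMP/mCherry ratio R with R₀
the mean of the lowest 10% of ratio values, ΔR/R₀ = (R − R₀)/R₀, optionally
normalized by the recording's 95th percentile.  Derivatives for downstream
peak detection and PCA come from total-variation regularized differentiation,
which keeps transients sharp while suppressing frame noise.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.sparse.linalg import LinearOperator, cg

from .peaks import auto_delta, detect_peaks

__all__ = [
    "Trace",
    "TraceSet",
    "RatioTrace",
    "compute_dff",
    "detrend_two_step",
    "compute_drr",
    "tv_derivative",
    "ExponentialFitError",
]

VARIANCE_CHANGE_CUTOFF = 8.0  # relative variance inflation marking distortion


class ExponentialFitError(RuntimeError):
    """Nonlinear exponential fit failed to converge."""


@dataclass
class Trace:
    """Raw fluorescence of one neuron."""

    F: np.ndarray
    frame_rate_hz: float
    background: float | np.ndarray = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        self.F = np.asarray(self.F, dtype=float)


@dataclass
class TraceSet:
    """neurons x T fluorescence matrix with labels and provenance."""

    F: np.ndarray
    labels: list[str]
    frame_rate_hz: float
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.F = np.asarray(self.F, dtype=float)
        if self.F.ndim != 2 or self.F.shape[0] != len(self.labels):
            raise ValueError("F must be (n_neurons, T) matching labels")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate neuron labels")

    @property
    def n_neurons(self) -> int:
        return self.F.shape[0]

    @property
    def n_frames(self) -> int:
        return self.F.shape[1]

    def trace(self, label: str) -> np.ndarray:
        return self.F[self.labels.index(label)]


@dataclass
class RatioTrace:
    """Dual-channel (GCaMP, mCherry) recording of one neuron."""

    gcamp: np.ndarray
    mcherry: np.ndarray
    frame_rate_hz: float
    label: str = ""

    def __post_init__(self) -> None:
        self.gcamp = np.asarray(self.gcamp, dtype=float)
        self.mcherry = np.asarray(self.mcherry, dtype=float)
        if self.gcamp.shape != self.mcherry.shape:
            raise ValueError("channel length mismatch")

    @property
    def ratio(self) -> np.ndarray:
        r = np.full(self.gcamp.shape, np.nan)
        ok = self.mcherry > 0
        r[ok] = self.gcamp[ok] / self.mcherry[ok]
        return r


def compute_dff(t: Trace) -> np.ndarray:
    """Background-subtracted ΔF/F₀ with F₀ the mean over the whole trial.

    Missing frames (NaN) are excluded from the F₀ estimate and propagate.
    """
    f = t.F - np.asarray(t.background, dtype=float)
    f0 = np.nanmean(f)
    if not np.isfinite(f0) or f0 <= 0:
        raise ValueError(f"non-positive baseline F0={f0!r} after background subtraction")
    return (f - f0) / f0


def _fit_exponential(t: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Parameters (a, tau) of y ~ a*exp(-t/tau), log-linear initialized.

    The pure exponential (no offset) matches the multiplicative bleaching
    model; positive values are required for the log-linear start.
    """
    pos = np.maximum(y, 1e-9)
    A = np.column_stack([t, np.ones_like(t)])
    slope, intercept = np.linalg.lstsq(A, np.log(pos), rcond=None)[0]
    span = max(t[-1] - t[0], 1.0)
    tau0 = -1.0 / slope if slope < -1e-9 else 100.0 * span
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                lambda tt, a, tau: a * np.exp(-tt / tau),
                t, y,
                p0=[math.exp(intercept), min(max(tau0, 1e-3), 1e3 * span)],
                bounds=([0.0, 1e-3], [np.inf, 1e4 * span]),
                maxfev=10000,
            )
    except (RuntimeError, ValueError) as exc:
        raise ExponentialFitError(str(exc)) from exc
    return float(popt[0]), float(popt[1])


def _eval_exp(t: np.ndarray, params: tuple[float, float]) -> np.ndarray:
    a, tau = params
    return a * np.exp(-t / tau)


def detrend_two_step(
    dff: np.ndarray,
    frame_rate_hz: float,
    peak_delta_range="immobilized_raw",
):
    """Two-step photobleaching correction of a ΔF/F₀ trace.

    Step 1 divides out an exponential fitted to the full trace (bleaching is
    multiplicative); step 2 divides out an exponential fitted only to the
    detected peak values, flattening the envelope of the transients.  If
    step 2 inflates the variance by more than a relative factor of
    ``VARIANCE_CHANGE_CUTOFF`` (= 8), the trace is flagged distorted and the
    step-1 (single bleach-corrected) version is returned instead.

    Returns
    -------
    (detrended, used_fallback)
    """
    y = np.asarray(dff, dtype=float)
    t = np.arange(y.size) / frame_rate_hz
    ok = np.isfinite(y)
    if ok.sum() < 8:
        raise ValueError("too few finite samples to detrend")

    base = y[ok] + 1.0  # back to F/F0 scale for a multiplicative model
    try:
        p1 = _fit_exponential(t[ok], base)
    except ExponentialFitError:
        raise
    fit1 = _eval_exp(t[ok], p1)
    if np.any(fit1 <= 0):
        raise ExponentialFitError("step-1 exponential crosses zero")
    step1 = np.full(y.size, np.nan)
    step1[ok] = base / fit1 - 1.0

    # step 2: exponential through detected peak values
    delta = auto_delta(step1[ok], peak_delta_range)
    ps = detect_peaks(step1, delta)
    if ps.n_maxima < 3:
        return step1, False
    try:
        p2 = _fit_exponential(t[ps.maxima], step1[ps.maxima] + 1.0)
    except ExponentialFitError:
        return step1, True
    fit2 = _eval_exp(t[ok], p2)
    if np.any(fit2 <= 0):
        return step1, True
    step2 = np.full(y.size, np.nan)
    step2[ok] = (step1[ok] + 1.0) / fit2 - 1.0

    v_pre = np.nanvar(step1)
    v_post = np.nanvar(step2)
    rel_change = (v_post - v_pre) / v_pre if v_pre > 0 else np.inf
    if rel_change > VARIANCE_CHANGE_CUTOFF:
        return step1, True
    return step2, False


def compute_drr(rt: RatioTrace, normalize_p95: bool = False) -> np.ndarray:
    """ΔR/R₀ from a dual-channel recording.

    R = GCaMP/mCherry; R₀ is the mean of the lowest 10% of ratio values
    (non-positive mCherry frames are excluded from the pool and masked);
    ΔR/R₀ = (R − R₀)/R₀.  With ``normalize_p95`` the series is additionally
    divided by its 95th percentile.
    """
    r = rt.ratio
    pool = r[np.isfinite(r)]
    if pool.size == 0:
        raise ValueError("no valid ratio frames")
    k = max(1, int(math.ceil(0.1 * pool.size)))
    r0 = float(np.mean(np.sort(pool)[:k]))
    if r0 <= 0:
        raise ValueError(f"non-positive R0={r0!r}")
    drr = (r - r0) / r0
    if normalize_p95:
        p95 = np.nanpercentile(drr, 95)
        if p95 <= 0:
            raise ValueError("95th percentile of dR/R0 is non-positive")
        drr = drr / p95
    return drr


def tv_derivative(
    series,
    reg_param: float,
    frame_rate_hz: float,
    *,
    n_iter: int = 40,
    tol: float = 1e-6,
    eps: float = 1e-8,
) -> np.ndarray:
    """Total-variation regularized time derivative.

    Finds u minimizing ``0.5 * ||A u − (f − f[0])||² + reg_param * TV(u)``
    where A is the running integral, via lagged-diffusivity fixed-point
    iterations with conjugate-gradient inner solves.  The result is in
    series units per second and tolerates noise without smearing steps.

    Missing samples are linearly bridged before differentiation and
    propagated back to NaN in the output.
    """
    if not reg_param > 0:
        raise ValueError("reg_param must be positive")
    f = np.asarray(series, dtype=float).ravel()
    miss = ~np.isfinite(f)
    if miss.all():
        return np.full(f.shape, np.nan)
    if miss.any():
        idx = np.arange(f.size)
        f = f.copy()
        f[miss] = np.interp(idx[miss], idx[~miss], f[~miss])
    n = f.size
    dt = 1.0 / frame_rate_hz
    fhat = f - f[0]

    def A_mv(u):
        # trapezoid-free cumulative integral (left Riemann), matches A^T below
        return np.cumsum(u) * dt

    def AT_mv(w):
        return np.cumsum(w[::-1])[::-1] * dt

    u = np.gradient(f, dt)
    ATf = AT_mv(fhat)
    for _ in range(n_iter):
        du = np.diff(u)
        w = 1.0 / np.sqrt(du * du + eps)

        def L_mv(x, w=w):
            dx = np.diff(x)
            y = np.zeros_like(x)
            y[:-1] -= w * dx
            y[1:] += w * dx
            return y

        def H_mv(x):
            return AT_mv(A_mv(x)) + reg_param * L_mv(x)

        H = LinearOperator((n, n), matvec=H_mv, dtype=float)
        u_new, _info = cg(H, ATf, x0=u, rtol=1e-8, maxiter=200)
        delta = np.linalg.norm(u_new - u) / max(np.linalg.norm(u), 1e-12)
        u = u_new
        if delta < tol:
            break
    u = np.asarray(u, dtype=float)
    u[miss] = np.nan
    return u
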