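"""Population-level analysis of multi-neuron recordings.

PCA is run on detrended ΔF/F₀ traces *and* their time derivatives
simultaneously — each neuron contributes two variables, capturing both
instantaneous calcium level and its dynamics — after scaling each trace and
its derivative to equal variance.  Reconstruction quality per neuron group
(the Pearson correlation between a trace and its top-i PC reconstruction)
measures how well a cell class is captured by the dominant low-dimensional
dynamics.  Per-state summaries quantify command-state modulation: the
forward-minus-reverse mean activity difference and the activity-peak
frequency within each retained forward command state.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .states import StateSegmentation

__all__ = [
    "PCAResult",
    "normalize_equal_variance",
    "run_pca",
    "reconstruction_correlation",
    "mean_activity_difference",
    "peak_frequency_per_state",
]


@dataclass
class PCAResult:
    """Centered PCA of a (frames x variables) matrix.

    ``scores @ loadings + mean`` reproduces the input:  ``loadings`` is
    (components x variables), ``scores`` (frames x components),
    ``variance_explained`` in percent summing to 100 over all components.
    ``variable_map`` records, per neuron label, its (trace, derivative)
    column indices.
    """

    loadings: np.ndarray
    scores: np.ndarray
    variance_explained: np.ndarray
    mean: np.ndarray
    variable_map: dict[str, tuple[int, int]]

    @property
    def n_components(self) -> int:
        return self.loadings.shape[0]

    def reconstruct(self, top_i: int) -> np.ndarray:
        """Input reconstructed from the top ``top_i`` components plus mean."""
        if not 1 <= top_i <= self.n_components:
            raise ValueError(f"top_i must be in 1..{self.n_components}")
        return self.scores[:, :top_i] @ self.loadings[:top_i, :] + self.mean


def normalize_equal_variance(traces, derivs, labels=None):
    """Stack traces and derivatives as variables with equal per-pair variance.

    Parameters
    ----------
    traces, derivs : (n_neurons, T) arrays, aligned.
    labels : neuron labels (defaults to indices).

    Returns
    -------
    (matrix, variable_map, kept_labels): matrix is (T, 2*kept) with each
    trace and its derivative scaled to unit variance.  Zero-variance
    variables cause the neuron to be dropped with a warning.
    """
    X = np.asarray(traces, dtype=float)
    D = np.asarray(derivs, dtype=float)
    if X.shape != D.shape:
        raise ValueError("traces and derivatives must have matching shapes")
    if labels is None:
        labels = [str(i) for i in range(X.shape[0])]
    cols = []
    variable_map: dict[str, tuple[int, int]] = {}
    kept = []
    for i, lab in enumerate(labels):
        vx, vd = np.nanvar(X[i]), np.nanvar(D[i])
        if not (vx > 0 and vd > 0):
            warnings.warn(f"neuron {lab!r} has a zero-variance variable; dropped")
            continue
        variable_map[lab] = (len(cols), len(cols) + 1)
        cols.append(X[i] / np.sqrt(vx))
        cols.append(D[i] / np.sqrt(vd))
        kept.append(lab)
    if not cols:
        raise ValueError("no usable variables")
    return np.column_stack(cols), variable_map, kept


def run_pca(matrix, variable_map=None) -> PCAResult:
    """Centered PCA, components ordered by variance explained (descending)."""
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need >= 2 frames and >= 2 variables")
    if not np.isfinite(X).all():
        raise ValueError("matrix contains non-finite values")
    mean = X.mean(axis=0)
    Xc = X - mean
    # economical SVD: Xc = U S Vt; scores = U S, loadings = Vt
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    scores = U * S
    var = S**2
    var_pct = 100.0 * var / var.sum()
    return PCAResult(
        loadings=Vt,
        scores=scores,
        variance_explained=var_pct,
        mean=mean,
        variable_map=variable_map or {},
    )


def reconstruction_correlation(
    pca: PCAResult,
    group: list[str],
    top_i: int,
):
    """Mean +- SEM correlation between a group's traces and their top-i
    PC reconstruction.

    Only the trace variable of each neuron enters the correlation (the
    derivative participates in the PCA itself).  The correlation is
    insensitive to trace magnitude, unlike mean squared error.

    Returns
    -------
    (mean, sem, per_neuron) where per_neuron maps label -> r.
    """
    if not group:
        raise ValueError("empty neuron group")
    recon = pca.reconstruct(top_i)
    orig = pca.scores @ pca.loadings + pca.mean
    per = {}
    for lab in group:
        if lab not in pca.variable_map:
            raise KeyError(f"unknown neuron {lab!r}")
        col = pca.variable_map[lab][0]
        a, b = orig[:, col], recon[:, col]
        sa, sb = a.std(), b.std()
        per[lab] = float(np.corrcoef(a, b)[0, 1]) if sa > 0 and sb > 0 else 1.0
    vals = np.array(list(per.values()))
    sem = float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else 0.0
    return float(vals.mean()), sem, per


def mean_activity_difference(trace, seg: StateSegmentation, frame_rate_hz: float):
    """Mean activity in forward states minus mean in reverse states.

    Means are frame-weighted over all frames of each command class; turn
    frames are excluded.  Raises if either class is absent.
    """
    x = np.asarray(trace, dtype=float)
    fwd, rev = [], []
    for s, e, lab in seg.intervals:
        i0, i1 = int(round(s * frame_rate_hz)), int(round(e * frame_rate_hz))
        chunk = x[i0:min(i1, x.size)]
        chunk = chunk[np.isfinite(chunk)]
        if lab == "forward":
            fwd.append(chunk)
        elif lab == "reverse":
            rev.append(chunk)
    if not fwd or not rev:
        raise ValueError("both forward and reverse states are required")
    fwd = np.concatenate(fwd)
    rev = np.concatenate(rev)
    if fwd.size == 0 or rev.size == 0:
        raise ValueError("a state class has no finite frames")
    return float(fwd.mean() - rev.mean())


def peak_frequency_per_state(
    event_times_s,
    forward_states: list[tuple[float, float]],
) -> list[float]:
    """Activity-peak frequency within each retained forward command state.

    One value per state: number of peaks inside the state divided by its
    duration.  States with no peaks contribute 0 Hz (they are real
    observations, not missing data); peaks outside the states are ignored.
    """
    te = np.asarray(event_times_s, dtype=float)
    out = []
    for s, e in forward_states:
        n = int(np.count_nonzero((te >= s) & (te < e)))
        out.append(n / (e - s))
    return out
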