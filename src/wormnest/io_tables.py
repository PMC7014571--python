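"""Delimited-text readers/writers with schema validation.

All tabular artifacts are UTF-8, Unix-newline, comma- or tab-delimited text
(autodetected from the header line).  Metadata (frame rate, conventions,
provenance) lives in a commented ``# key: value`` block above the header.
Missing values use the explicit sentinel ``NA`` — never silent NaN coercion.
Writers are deterministic; readers are total on writer output.
"""

from __future__ import annotations

import io
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .kymo import Kymogram, N_ANGLES
from .states import StateSegmentation
from .traces import TraceSet

__all__ = [
    "SchemaError",
    "read_kymogram",
    "write_kymogram",
    "read_traces",
    "write_traces",
    "read_intervals",
    "write_intervals",
    "write_events",
]

SENTINEL = "NA"


class SchemaError(ValueError):
    """A file does not match its declared table schema."""


def _split_metadata(path) -> tuple[dict, str]:
    meta: dict = {}
    body_lines = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#"):
                stripped = line[1:].strip()
                if ":" in stripped:
                    k, v = stripped.split(":", 1)
                    meta[k.strip()] = v.strip()
            else:
                body_lines.append(line)
    return meta, "".join(body_lines)


def _detect_sep(header_line: str) -> str:
    return "\t" if "\t" in header_line else ","


def _read_table(path) -> tuple[dict, pd.DataFrame]:
    meta, body = _split_metadata(path)
    if not body.strip():
        return meta, pd.DataFrame()
    sep = _detect_sep(body.splitlines()[0])
    df = pd.read_csv(
        io.StringIO(body), sep=sep, na_values=[SENTINEL],
        keep_default_na=False, float_precision="round_trip",
    )
    return meta, df


def _meta_block(meta: dict) -> str:
    return "".join(f"# {k}: {v}\n" for k, v in meta.items())


def write_kymogram(k: Kymogram, path) -> None:
    """24 angle columns plus frame index; masked cells written as ``NA``."""
    meta = {
        "format": "wormnest-kymogram",
        "frame_rate_hz": repr(float(k.frame_rate_hz)),
        "ventral_positive": str(bool(k.ventral_positive)).lower(),
    }
    cols = [f"angle_{j:02d}" for j in range(1, N_ANGLES + 1)]
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(_meta_block(meta))
        fh.write("frame," + ",".join(cols) + "\n")
        for i in range(k.n_frames):
            cells = [
                SENTINEL if k.missing_mask[i, j] else repr(float(k.angles[i, j]))
                for j in range(N_ANGLES)
            ]
            fh.write(f"{i}," + ",".join(cells) + "\n")


def read_kymogram(path) -> Kymogram:
    meta, df = _read_table(path)
    if meta.get("format") not in (None, "wormnest-kymogram"):
        raise SchemaError(f"not a kymogram file: format={meta.get('format')!r}")
    if "frame_rate_hz" not in meta:
        raise SchemaError("missing frame_rate_hz metadata")
    angle_cols = [c for c in df.columns if c.startswith("angle_")]
    if len(angle_cols) != N_ANGLES:
        raise SchemaError(
            f"expected {N_ANGLES} angle columns, found {len(angle_cols)}"
        )
    vals = df[angle_cols].to_numpy(dtype=float)
    if not np.isfinite(vals[~np.isnan(vals)]).all():
        raise SchemaError("non-numeric cells in angle columns")
    mask = np.isnan(vals)
    return Kymogram(
        angles=vals,
        frame_rate_hz=float(meta["frame_rate_hz"]),
        missing_mask=mask,
        ventral_positive=meta.get("ventral_positive", "true") == "true",
    )


def write_traces(ts: TraceSet, path) -> None:
    """Neuron-per-column trace matrix with a label header row."""
    meta = {
        "format": "wormnest-traces",
        "frame_rate_hz": repr(float(ts.frame_rate_hz)),
        "provenance": json.dumps(ts.provenance),
    }
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(_meta_block(meta))
        fh.write("frame," + ",".join(ts.labels) + "\n")
        for i in range(ts.n_frames):
            cells = [
                SENTINEL if not np.isfinite(ts.F[j, i]) else repr(float(ts.F[j, i]))
                for j in range(ts.n_neurons)
            ]
            fh.write(f"{i}," + ",".join(cells) + "\n")


def read_traces(path) -> TraceSet:
    meta, body = _split_metadata(path)
    if "frame_rate_hz" not in meta:
        raise SchemaError("missing frame_rate_hz metadata")
    if body.strip():
        header = body.splitlines()[0]
        raw_cols = header.split(_detect_sep(header))
        if len(set(raw_cols)) != len(raw_cols):
            raise SchemaError("duplicate neuron labels in header")
    meta, df = _read_table(path)
    labels = [c for c in df.columns if c != "frame"]
    if not labels:
        raise SchemaError("no neuron-label columns")
    if len(set(labels)) != len(labels):
        raise SchemaError("duplicate neuron labels in header")
    F = df[labels].to_numpy(dtype=float).T
    prov = json.loads(meta.get("provenance", "[]"))
    return TraceSet(
        F=F,
        labels=labels,
        frame_rate_hz=float(meta["frame_rate_hz"]),
        provenance=prov,
    )


def write_intervals(intervals, path, labeled: bool = True) -> None:
    """(start_s, end_s[, label]) interval table."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("# format: wormnest-intervals\n")
        if labeled:
            fh.write("start_s,end_s,label\n")
            for s, e, lab in intervals:
                fh.write(f"{s!r},{e!r},{lab}\n")
        else:
            fh.write("start_s,end_s\n")
            for s, e in intervals:
                fh.write(f"{s!r},{e!r}\n")


def read_intervals(path):
    """Labeled or unlabeled interval table, validated sorted/non-overlapping.

    Returns a :class:`StateSegmentation` when labels are present, else a
    list of (start_s, end_s) tuples.  Empty files yield an empty result.
    """
    _, df = _read_table(path)
    if df.empty:
        return []
    for col in ("start_s", "end_s"):
        if col not in df.columns:
            raise SchemaError(f"missing required column {col!r}")
    starts = df["start_s"].to_numpy(dtype=float)
    ends = df["end_s"].to_numpy(dtype=float)
    if np.any(ends <= starts):
        raise SchemaError("empty or inverted intervals")
    if np.any(starts[1:] < ends[:-1]):
        raise SchemaError("intervals overlap or are unsorted")
    if "label" in df.columns:
        ivs = [
            (float(s), float(e), str(l))
            for s, e, l in zip(starts, ends, df["label"])
        ]
        try:
            return StateSegmentation(intervals=ivs)
        except ValueError as exc:
            raise SchemaError(str(exc)) from exc
    return [(float(s), float(e)) for s, e in zip(starts, ends)]


def write_events(events, frame_rate_hz: float, path) -> None:
    """HeadBendEvent table: onset_s, sign, final_segment, class, termination."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("# format: wormnest-headbends\n")
        fh.write(f"# frame_rate_hz: {frame_rate_hz!r}\n")
        fh.write("onset_s,sign,final_segment,class,termination_reason,bout\n")
        for ev in events:
            fh.write(
                f"{ev.onset_frame / frame_rate_hz!r},{ev.sign},"
                f"{ev.final_segment},{ev.class_label},"
                f"{ev.termination_reason},{ev.bout_label}\n"
            )
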