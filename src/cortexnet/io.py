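"""File formats: trace CSVs with JSON sidecars, event and histogram CSVs.

All files are UTF-8, comma-separated, '.' decimal, with one header-like
first row.  Traces are stored as a CSV whose first row holds the frame
times in seconds (first field ``time_s``) and whose remaining rows each
hold one cell: the cell ID string followed by that cell's fluorescence
samples.  A companion JSON sidecar (same path with ``.json`` extension)
records fps, duration, scenario/seed provenance and kernel parameters.
Write-then-read round-trips reproduce objects exactly up to float
formatting (times well below 1e-9 s).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .degreefit import DegreeHistogram
from .synthetic import EventTrain
from .transients import BurstTable, EventTable, TraceSet

__all__ = [
    "sidecar_path",
    "write_traces",
    "read_traces",
    "write_events",
    "read_events",
    "write_event_train",
    "read_event_train",
    "write_bursts",
    "write_degree_sequence",
    "read_histogram",
    "write_results",
]




class FileFormatError(ValueError):
    """A file violated the expected CSV dialect; message names file/line/field."""


def sidecar_path(path: str | Path) -> Path:
    return Path(path).with_suffix(".json")


def _fmt(x: float) -> str:
    # repr gives the shortest string that round-trips the float exactly
    return repr(float(x))


def write_traces(traces: TraceSet, path: str | Path) -> Path:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("time_s," + ",".join(_fmt(t) for t in traces.frame_times) + "\n")
        for cid, row in zip(traces.cell_ids, traces.F):
            fh.write(cid + "," + ",".join(_fmt(v) for v in row) + "\n")
    meta = {
        "fps": traces.fps,
        "duration_s": traces.duration_s,
        "n_cells": traces.n_cells,
        "meta": _jsonable(traces.meta),
    }
    sidecar_path(path).write_text(json.dumps(meta, indent=2, sort_keys=True))
    return path


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def read_traces(path: str | Path) -> TraceSet:
    path = Path(path)
    side = sidecar_path(path)
    if not side.exists():
        raise FileFormatError(f"{path}: missing JSON sidecar {side.name}")
    meta = json.loads(side.read_text())
    cell_ids: list[str] = []
    rows: list[np.ndarray] = []
    n_fields: int | None = None
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.rstrip("\n").split(",")
            if n_fields is None:
                if fields[0] != "time_s":
                    raise FileFormatError(
                        f"{path}:{lineno}: first field must be 'time_s', got {fields[0]!r}"
                    )
                n_fields = len(fields)
                continue
            if len(fields) != n_fields:
                raise FileFormatError(
                    f"{path}:{lineno}: ragged row ({len(fields)} fields, expected {n_fields})"
                )
            try:
                values = np.array([float(v) for v in fields[1:]])
            except ValueError as exc:
                raise FileFormatError(f"{path}:{lineno}: non-numeric sample: {exc}")
            if not np.all(np.isfinite(values)):
                raise FileFormatError(f"{path}:{lineno}: non-finite fluorescence value")
            cell_ids.append(fields[0])
            rows.append(values)
    if not rows:
        raise FileFormatError(f"{path}: no cell rows found")
    return TraceSet(
        cell_ids=cell_ids,
        F=np.vstack(rows),
        fps=float(meta["fps"]),
        duration_s=float(meta["duration_s"]),
        meta=meta.get("meta", {}),
    )


def _read_csv_records(
    path: Path, columns: tuple[str, ...], casts: tuple
) -> list[tuple]:
    records = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.rstrip("\n").split(",")
            if lineno == 1:
                if tuple(fields) != columns:
                    raise FileFormatError(
                        f"{path}:1: malformed header {fields!r}, expected {list(columns)}"
                    )
                continue
            if len(fields) != len(columns):
                raise FileFormatError(
                    f"{path}:{lineno}: ragged row ({len(fields)} fields, "
                    f"expected {len(columns)})"
                )
            rec = []
            for name, cast, raw in zip(columns, casts, fields):
                try:
                    val = cast(raw)
                except ValueError:
                    raise FileFormatError(
                        f"{path}:{lineno}: field {name!r}: cannot parse {raw!r}"
                    )
                if isinstance(val, float) and not np.isfinite(val):
                    raise FileFormatError(
                        f"{path}:{lineno}: field {name!r}: non-finite value"
                    )
                rec.append(val)
            records.append((lineno, tuple(rec)))
    return records


def write_events(events: EventTable, path: str | Path) -> Path:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("cell_id,onset_time_s,peak_dff\n")
        for row in events.events.itertuples(index=False):
            fh.write(f"{row.cell_id},{_fmt(row.onset_time_s)},{_fmt(row.peak_dff)}\n")
    meta = {"duration_s": events.duration_s, "cell_ids": list(events.cell_ids)}
    sidecar_path(path).write_text(json.dumps(meta, indent=2, sort_keys=True))
    return path


def read_events(path: str | Path, duration_s: float | None = None) -> EventTable:
    path = Path(path)
    side = sidecar_path(path)
    cell_ids: list[str] = []
    if side.exists():
        meta = json.loads(side.read_text())
        duration_s = duration_s if duration_s is not None else meta.get("duration_s")
        cell_ids = meta.get("cell_ids", [])
    recs = _read_csv_records(
        path, ("cell_id", "onset_time_s", "peak_dff"), (str, float, float)
    )
    for lineno, (cid, t, amp) in recs:
        if t < 0:
            raise FileFormatError(
                f"{path}:{lineno}: field 'onset_time_s': negative time {t}"
            )
        if amp <= 0:
            raise FileFormatError(
                f"{path}:{lineno}: field 'peak_dff': must be > 0, got {amp}"
            )
    rows = [r for _, r in recs]
    if duration_s is None:
        duration_s = max((r[1] for r in rows), default=0.0) + 1.0
    df = pd.DataFrame(rows, columns=["cell_id", "onset_time_s", "peak_dff"])
    if not cell_ids:
        cell_ids = sorted(df["cell_id"].unique())
    return EventTable(events=df, duration_s=float(duration_s), cell_ids=cell_ids)


def write_event_train(train: EventTrain, path: str | Path) -> Path:
    """Ground-truth generator events: columns cell_id, time_s, weight."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("cell_id,time_s,weight\n")
        for cid, t, w in train.all_events():
            fh.write(f"{cid},{_fmt(t)},{w}\n")
    meta = {
        "duration_s": train.duration_s,
        "cell_ids": list(train.cell_ids),
        "meta": _jsonable(train.meta),
    }
    sidecar_path(path).write_text(json.dumps(meta, indent=2, sort_keys=True))
    return path


def read_event_train(path: str | Path) -> EventTrain:
    path = Path(path)
    side = sidecar_path(path)
    if not side.exists():
        raise FileFormatError(f"{path}: missing JSON sidecar {side.name}")
    meta = json.loads(side.read_text())
    recs = _read_csv_records(path, ("cell_id", "time_s", "weight"), (str, float, int))
    for lineno, (cid, t, w) in recs:
        if t < 0:
            raise FileFormatError(f"{path}:{lineno}: field 'time_s': negative time {t}")
        if w < 1:
            raise FileFormatError(f"{path}:{lineno}: field 'weight': must be >= 1")
    cell_ids = list(meta["cell_ids"])
    times = {c: [] for c in cell_ids}
    weights = {c: [] for c in cell_ids}
    for _, (cid, t, w) in recs:
        if cid not in times:
            raise FileFormatError(f"{path}: unknown cell id {cid!r}")
        times[cid].append(t)
        weights[cid].append(w)
    return EventTrain(
        cell_ids=cell_ids,
        times={c: np.asarray(times[c]) for c in cell_ids},
        weights={c: np.asarray(weights[c], dtype=int) for c in cell_ids},
        duration_s=float(meta["duration_s"]),
        meta=meta.get("meta", {}),
    )


def write_bursts(bursts: BurstTable, path: str | Path) -> Path:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(
            "burst_start_s,burst_end_s,n_participating_cells,participation_fraction\n"
        )
        for row in bursts.bursts.itertuples(index=False):
            fh.write(
                f"{_fmt(row.burst_start_s)},{_fmt(row.burst_end_s)},"
                f"{row.n_participating_cells},{_fmt(row.participation_fraction)}\n"
            )
    meta = {
        "duration_s": bursts.duration_s,
        "n_cells": bursts.n_cells,
        "n_bursts": bursts.n_bursts,
        "burst_frequency_hz": bursts.burst_frequency_hz,
        "mean_burst_amplitude": _jsonable(bursts.mean_burst_amplitude),
    }
    sidecar_path(path).write_text(json.dumps(meta, indent=2, sort_keys=True))
    return path


def write_degree_sequence(degrees: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("neuron_id,k\n")
        for i, k in enumerate(np.asarray(degrees, dtype=int)):
            fh.write(f"n{i:04d},{k}\n")
    return path


def read_histogram(path: str | Path) -> DegreeHistogram:
    """Read either a (k, count) histogram CSV or a (neuron_id, k) sequence CSV."""
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split(",")
    if header == ["k", "count"]:
        recs = _read_csv_records(path, ("k", "count"), (int, int))
        return DegreeHistogram(counts={k: c for _, (k, c) in recs})
    if header == ["neuron_id", "k"]:
        recs = _read_csv_records(path, ("neuron_id", "k"), (str, int))
        return DegreeHistogram.from_sequence([k for _, (_, k) in recs])
    raise FileFormatError(
        f"{path}:1: malformed header {header!r}; expected ['k', 'count'] "
        "or ['neuron_id', 'k']"
    )


def write_results(payload: dict, path: str | Path) -> Path:
    """Write an analysis-result JSON; the exact config used must be embedded."""
    path = Path(path)
    path.write_text(json.dumps(_jsonable(payload), indent=2, sort_keys=True))
    return path
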