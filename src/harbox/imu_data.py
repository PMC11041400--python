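"""Domain types and I/O for smartphone IMU recordings.

A recording is a continuous 6-channel stream (3-axis acceleration in m/s²,
3-axis rotation rate in rad/s) sampled at a nominal rate, optionally
annotated with activity label spans.  This module owns the on-disk CSV and
JSON dialects, label application, and sliding-window segmentation.
"""

from __future__ import annotations

import enum
import io
import json
import math
import warnings
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import IO, Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ActivityLabel",
    "ChannelSet",
    "Recording",
    "LabelSpan",
    "Window",
    "Dataset",
    "FormatError",
    "DEFAULT_CHANNELS",
    "DEFAULT_WINDOW_LEN",
    "DEFAULT_STEP",
    "read_recording_csv",
    "write_recording_csv",
    "read_recording_json",
    "write_recording_json",
    "apply_labels",
    "segment_windows",
    "summarize",
]


class FormatError(ValueError):
    """Raised when an input stream does not conform to a supported dialect."""


class ActivityLabel(enum.Enum):
    """The six activity classes, ordered alphabetically by code.

    The enum order defines class indices everywhere: model outputs,
    confusion-matrix axes, and summary tables.
    """

    DWS = "dws"
    JOG = "jog"
    SIT = "sit"
    STD = "std"
    UPS = "ups"
    WLK = "wlk"

    @property
    def code(self) -> str:
        return self.value

    @property
    def display_name(self) -> str:
        return _DISPLAY_NAMES[self]

    @property
    def index(self) -> int:
        return _LABEL_ORDER.index(self)

    @classmethod
    def from_code(cls, code: str) -> "ActivityLabel":
        try:
            return cls(code.strip().lower())
        except ValueError:
            raise ValueError(
                f"unknown activity code {code!r}; expected one of "
                f"{[m.value for m in cls]}"
            ) from None


_LABEL_ORDER: tuple[ActivityLabel, ...] = tuple(ActivityLabel)
_DISPLAY_NAMES = {
    ActivityLabel.DWS: "downstairs",
    ActivityLabel.JOG: "jogging",
    ActivityLabel.SIT: "sitting",
    ActivityLabel.STD: "standing",
    ActivityLabel.UPS: "upstairs",
    ActivityLabel.WLK: "walking",
}

CLASS_ORDER: tuple[ActivityLabel, ...] = _LABEL_ORDER
N_CLASSES = len(CLASS_ORDER)


@dataclass(frozen=True)
class ChannelSet:
    """Ordered channel names with units and sensor-group tags.

    Groups must be contiguous in the ordering so a sensor mask always
    selects a contiguous block of rows.
    """

    names: tuple[str, ...]
    units: tuple[str, ...]
    sensor_group: tuple[str, ...]

    def __post_init__(self) -> None:
        if not (len(self.names) == len(self.units) == len(self.sensor_group)):
            raise ValueError("names, units and sensor_group must align")
        if len(set(self.names)) != len(self.names):
            raise ValueError("channel names must be unique")
        for g in self.sensor_group:
            if g not in ("accelerometer", "gyroscope", "magnetometer"):
                raise ValueError(f"unknown sensor group {g!r}")
        # contiguity: each group appears as one run
        seen: list[str] = []
        for g in self.sensor_group:
            if seen and seen[-1] != g:
                if g in seen:
                    raise ValueError("sensor groups must be contiguous")
                seen.append(g)
            elif not seen:
                seen.append(g)

    def __len__(self) -> int:
        return len(self.names)

    @property
    def groups(self) -> tuple[str, ...]:
        out: list[str] = []
        for g in self.sensor_group:
            if not out or out[-1] != g:
                out.append(g)
        return tuple(out)

    def group_indices(self, group: str) -> np.ndarray:
        return np.array(
            [i for i, g in enumerate(self.sensor_group) if g == group], dtype=int
        )

    def subset(self, groups: Iterable[str]) -> "ChannelSet":
        keep = [i for i, g in enumerate(self.sensor_group) if g in set(groups)]
        return ChannelSet(
            names=tuple(self.names[i] for i in keep),
            units=tuple(self.units[i] for i in keep),
            sensor_group=tuple(self.sensor_group[i] for i in keep),
        )


DEFAULT_CHANNELS = ChannelSet(
    names=("acc_x", "acc_y", "acc_z", "rot_roll", "rot_pitch", "rot_yaw"),
    units=("m/s^2",) * 3 + ("rad/s",) * 3,
    sensor_group=("accelerometer",) * 3 + ("gyroscope",) * 3,
)

#: 2.56 s at 50 Hz — the de-facto HAR window; 50 % overlap.
DEFAULT_WINDOW_LEN = 128
DEFAULT_STEP = 64


@dataclass(frozen=True)
class LabelSpan:
    """Half-open time interval [start, end) in seconds carrying one label."""

    start: float
    end: float
    label: ActivityLabel

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"span start {self.start} must be < end {self.end}")

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class Recording:
    """One participant's continuous multi-channel stream.

    ``samples`` has shape (n_channels, n_samples); sample ``i`` occurs at
    time ``t0 + i / sampling_rate``.
    """

    participant_id: str
    sampling_rate: float
    channels: ChannelSet
    samples: np.ndarray
    t0: float = 0.0
    label_spans: list[LabelSpan] | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be 2-D (channels x samples)")
        if self.samples.shape[0] != len(self.channels):
            raise ValueError(
                f"samples has {self.samples.shape[0]} rows but channel set "
                f"has {len(self.channels)}"
            )
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.sampling_rate

    def equals(self, other: "Recording", atol: float = 0.0) -> bool:
        if self.participant_id != other.participant_id:
            return False
        if not math.isclose(self.sampling_rate, other.sampling_rate, rel_tol=1e-9):
            return False
        if self.channels.names != other.channels.names:
            return False
        if self.samples.shape != other.samples.shape:
            return False
        if atol == 0.0:
            if not np.array_equal(self.samples, other.samples):
                return False
        elif not np.allclose(self.samples, other.samples, atol=atol):
            return False
        a, b = self.label_spans or [], other.label_spans or []
        if len(a) != len(b):
            return False
        return all(
            sa.label is sb.label
            and math.isclose(sa.start, sb.start, abs_tol=1e-9)
            and math.isclose(sa.end, sb.end, abs_tol=1e-9)
            for sa, sb in zip(a, b)
        )


@dataclass(frozen=True)
class Window:
    """Fixed-length labeled segment, the unit of training and evaluation."""

    values: np.ndarray  # (n_channels, window_len)
    label: ActivityLabel
    sampling_rate: float
    source_participant: str
    source_offset: int

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 2 or v.shape[1] < 1:
            raise ValueError("window values must be (channels x length>=1)")
        if np.isnan(v).any():
            raise ValueError("window contains missing values")

    @property
    def window_len(self) -> int:
        return self.values.shape[1]

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]


@dataclass
class Dataset:
    """A bag of windows sharing one channel set and window length."""

    windows: list[Window]
    channels: ChannelSet

    def __post_init__(self) -> None:
        if self.windows:
            lens = {w.window_len for w in self.windows}
            if len(lens) != 1:
                raise ValueError(f"windows have mixed lengths: {sorted(lens)}")
            chans = {w.n_channels for w in self.windows}
            if chans != {len(self.channels)}:
                raise ValueError("window channel count does not match channel set")

    def __len__(self) -> int:
        return len(self.windows)

    @property
    def window_len(self) -> int:
        if not self.windows:
            raise ValueError("empty dataset has no window length")
        return self.windows[0].window_len

    @property
    def class_counts(self) -> dict[ActivityLabel, int]:
        c = Counter(w.label for w in self.windows)
        return {lab: c.get(lab, 0) for lab in CLASS_ORDER}

    @property
    def participants(self) -> list[str]:
        return sorted({w.source_participant for w in self.windows})

    def stacked(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (X, y) with X shape (n, channels, length), y int class indices."""
        if not self.windows:
            return (
                np.zeros((0, len(self.channels), 0)),
                np.zeros(0, dtype=int),
            )
        X = np.stack([w.values for w in self.windows])
        y = np.array([w.label.index for w in self.windows], dtype=int)
        return X, y

    def subset(self, indices: Sequence[int]) -> "Dataset":
        return Dataset([self.windows[i] for i in indices], self.channels)


# ---------------------------------------------------------------------------
# CSV / JSON dialects
# ---------------------------------------------------------------------------

_CSV_COLUMNS = ("timestamp",) + DEFAULT_CHANNELS.names

DEFAULT_DIALECT: dict[str, str] = {c: c for c in _CSV_COLUMNS}
DEFAULT_DIALECT["label"] = "label"

_JITTER_TOLERANCE = 0.01  # warn when timestamp jitter exceeds 1 %


def _as_text_stream(source: IO | str | Path) -> IO:
    if isinstance(source, (str, Path)):
        return open(source, "r", encoding="utf-8")
    if isinstance(source, io.BufferedIOBase) or isinstance(source, io.RawIOBase):
        return io.TextIOWrapper(source, encoding="utf-8")
    return source


def _estimate_rate(timestamps: np.ndarray) -> float:
    deltas = np.diff(timestamps)
    if np.any(deltas <= 0):
        bad = int(np.argmax(deltas <= 0)) + 1
        raise FormatError(
            f"non-monotonic timestamps: row {bad} does not increase"
        )
    med = float(np.median(deltas))
    jitter = float(np.max(np.abs(deltas - med))) / med if med > 0 else 0.0
    if jitter > _JITTER_TOLERANCE:
        warnings.warn(
            f"timestamp jitter {jitter:.1%} exceeds {_JITTER_TOLERANCE:.0%}; "
            "sampling-rate estimate may be unreliable",
            stacklevel=3,
        )
    return 1.0 / med


def read_recording_csv(
    source: IO | str | Path,
    dialect: dict[str, str] | None = None,
    *,
    participant_id: str = "unknown",
    sampling_rate: float | None = None,
    channels: ChannelSet = DEFAULT_CHANNELS,
) -> Recording:
    """Parse a CSV export into a :class:`Recording`.

    ``dialect`` maps logical column names (``timestamp``, the six channel
    names, optionally ``label``) to the header names actually present.
    The sampling rate is the reciprocal of the median timestamp increment
    unless supplied explicitly.
    """
    dialect = dict(DEFAULT_DIALECT if dialect is None else dialect)
    stream = _as_text_stream(source)
    df = pd.read_csv(stream, dtype=str, skipinitialspace=True)
    for logical in ("timestamp",) + channels.names:
        col = dialect.get(logical, logical)
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r}")
    if len(df) < 2:
        raise FormatError("fewer than 2 samples: sampling rate is inestimable")

    def _numeric(logical: str) -> np.ndarray:
        col = dialect.get(logical, logical)
        raw = df[col]
        out = np.empty(len(raw), dtype=float)
        # python float() is correctly rounded (pandas' fast parser is not)
        for i, cell in enumerate(raw):
            if cell is None or (isinstance(cell, float) and math.isnan(cell)):
                raise FormatError(
                    f"missing value in column {col!r} at data row {i + 1}"
                )
            try:
                out[i] = float(cell)
            except ValueError:
                raise FormatError(
                    f"non-numeric value {cell!r} in column {col!r} "
                    f"at data row {i + 1}"
                ) from None
        return out

    ts = _numeric("timestamp")
    order = np.argsort(ts, kind="stable")
    reordered = not np.array_equal(order, np.arange(len(ts)))
    ts = ts[order]
    rate = sampling_rate if sampling_rate is not None else _estimate_rate(ts)
    if reordered:
        # rows were not in timestamp order; sort, then re-check monotonicity
        _estimate_rate(ts)
    rows = [_numeric(name)[order] for name in channels.names]
    samples = np.vstack(rows)

    spans: list[LabelSpan] | None = None
    label_col = dialect.get("label", "label")
    if label_col in df.columns:
        labels = df[label_col].iloc[order].to_numpy()
        spans = _labels_to_spans(labels, ts)
    return Recording(
        participant_id=participant_id,
        sampling_rate=rate,
        channels=channels,
        samples=samples,
        t0=float(ts[0]),
        label_spans=spans,
    )


def _labels_to_spans(labels: np.ndarray, ts: np.ndarray) -> list[LabelSpan]:
    """Collapse a per-sample label column into contiguous spans."""
    spans: list[LabelSpan] = []
    dt = float(np.median(np.diff(ts)))
    start_i = None
    current = None
    for i, raw in enumerate(list(labels) + [None]):
        code = None if raw is None or (isinstance(raw, float) and math.isnan(raw)) else str(raw)
        if code == "" or code == "nan":
            code = None
        if code != current:
            if current is not None and start_i is not None:
                spans.append(
                    LabelSpan(
                        start=float(ts[start_i]),
                        end=float(ts[i - 1]) + dt,
                        label=ActivityLabel.from_code(current),
                    )
                )
            current = code
            start_i = i if code is not None else None
    return spans


def write_recording_csv(rec: Recording, dest: IO | str | Path) -> None:
    """Write ``rec`` in the canonical CSV dialect (full float precision)."""
    close = False
    if isinstance(dest, (str, Path)):
        dest = open(dest, "w", encoding="utf-8", newline="")
        close = True
    try:
        per_sample = _per_sample_labels(rec)
        cols = {"timestamp": rec.times}
        for i, name in enumerate(rec.channels.names):
            cols[name] = rec.samples[i]
        df = pd.DataFrame(cols)
        if per_sample is not None:
            df["label"] = per_sample
        df.to_csv(dest, index=False, float_format="%.17g")
    finally:
        if close:
            dest.close()


def _per_sample_labels(rec: Recording) -> list[str] | None:
    if not rec.label_spans:
        return None
    out = [""] * rec.n_samples
    t = rec.times
    for span in rec.label_spans:
        mask = (t >= span.start) & (t < span.end)
        for i in np.nonzero(mask)[0]:
            out[i] = span.label.code
    return out


def read_recording_json(
    source: IO | str | Path,
    *,
    participant_id: str | None = None,
    channels: ChannelSet = DEFAULT_CHANNELS,
) -> Recording:
    """Parse a JSON export (record-per-sample or array-per-channel dialect)."""
    stream = _as_text_stream(source)
    doc = json.load(stream)
    if isinstance(doc, dict) and "channels" in doc:
        return _json_channel_arrays(doc, participant_id, channels)
    if isinstance(doc, list):
        return _json_records(doc, participant_id, channels)
    if isinstance(doc, dict) and "records" in doc:
        rec = _json_records(doc["records"], participant_id, channels, meta=doc)
        return rec
    raise FormatError(
        "unknown JSON shape: expected a 'channels' object, a 'records' "
        "object, or a top-level array of samples"
    )


def _json_channel_arrays(
    doc: dict, participant_id: str | None, channels: ChannelSet
) -> Recording:
    chans = doc["channels"]
    lengths = set()
    rows = []
    for name in channels.names:
        if name not in chans:
            raise FormatError(f"missing channel array {name!r}")
        arr = np.asarray(chans[name], dtype=float)
        lengths.add(arr.shape[0])
        rows.append(arr)
    if len(lengths) > 1:
        raise FormatError(f"unequal channel lengths: {sorted(lengths)}")
    rate = float(doc.get("sampling_rate", 0.0))
    if rate <= 0:
        raise FormatError("missing or non-positive 'sampling_rate'")
    spans = None
    if doc.get("label_spans"):
        spans = [
            LabelSpan(float(s["start"]), float(s["end"]), ActivityLabel.from_code(s["label"]))
            for s in doc["label_spans"]
        ]
    return Recording(
        participant_id=participant_id or doc.get("participant_id", "unknown"),
        sampling_rate=rate,
        channels=channels,
        samples=np.vstack(rows) if rows else np.zeros((len(channels), 0)),
        t0=float(doc.get("t0", 0.0)),
        label_spans=spans,
    )


def _json_records(
    records: list, participant_id: str | None, channels: ChannelSet, meta: dict | None = None
) -> Recording:
    if len(records) < 2:
        raise FormatError("fewer than 2 samples: sampling rate is inestimable")
    ts = []
    rows = {n: [] for n in channels.names}
    labels = []
    for i, r in enumerate(records):
        if "timestamp" not in r:
            raise FormatError(f"record {i} lacks 'timestamp'")
        ts.append(float(r["timestamp"]))
        for n in channels.names:
            if n not in r:
                raise FormatError(f"record {i} lacks channel {n!r}")
            rows[n].append(float(r[n]))
        labels.append(r.get("label"))
    ts_arr = np.asarray(ts)
    rate = None
    if meta and meta.get("sampling_rate"):
        rate = float(meta["sampling_rate"])
    if rate is None:
        rate = _estimate_rate(ts_arr)
    else:
        _estimate_rate(ts_arr)  # monotonicity check
    spans = None
    if any(l is not None for l in labels):
        spans = _labels_to_spans(np.asarray(labels, dtype=object), ts_arr)
    pid = participant_id or (meta or {}).get("participant_id", "unknown")
    return Recording(
        participant_id=pid,
        sampling_rate=rate,
        channels=channels,
        samples=np.vstack([np.asarray(rows[n]) for n in channels.names]),
        t0=float(ts_arr[0]),
        label_spans=spans,
    )


def write_recording_json(rec: Recording, dest: IO | str | Path) -> None:
    """Write the array-per-channel JSON dialect (the canonical emitted form)."""
    doc: dict = {
        "participant_id": rec.participant_id,
        "sampling_rate": rec.sampling_rate,
        "t0": rec.t0,
        "channels": {
            name: rec.samples[i].tolist() for i, name in enumerate(rec.channels.names)
        },
    }
    if rec.label_spans:
        doc["label_spans"] = [
            {"start": s.start, "end": s.end, "label": s.label.code}
            for s in rec.label_spans
        ]
    if isinstance(dest, (str, Path)):
        with open(dest, "w", encoding="utf-8") as fh:
            json.dump(doc, fh)
    else:
        json.dump(doc, dest)


# ---------------------------------------------------------------------------
# Labeling and windowing
# ---------------------------------------------------------------------------


def apply_labels(rec: Recording, spans: Sequence[LabelSpan]) -> Recording:
    """Return a copy of ``rec`` with validated ``spans`` attached.

    Spans must be pairwise non-overlapping and lie within the recording's
    time extent; samples outside every span are unlabeled.
    """
    spans = sorted(spans, key=lambda s: s.start)
    t_end = rec.t0 + rec.n_samples / rec.sampling_rate
    for s in spans:
        if s.start < rec.t0 - 1e-9 or s.end > t_end + 1e-9:
            raise ValueError(
                f"span [{s.start}, {s.end}) lies outside the recording "
                f"[{rec.t0}, {t_end})"
            )
    for a, b in zip(spans, spans[1:]):
        if b.start < a.end - 1e-12:
            raise ValueError(
                f"overlapping spans: [{a.start}, {a.end}) {a.label.code} and "
                f"[{b.start}, {b.end}) {b.label.code}"
            )
    return replace(rec, label_spans=list(spans))


def _sample_labels(rec: Recording) -> np.ndarray:
    """Per-sample class index, -1 where unlabeled."""
    out = np.full(rec.n_samples, -1, dtype=int)
    if not rec.label_spans:
        return out
    t = rec.times
    for span in rec.label_spans:
        out[(t >= span.start - 1e-12) & (t < span.end - 1e-12)] = span.label.index
    return out


def segment_windows(
    rec: Recording,
    window_len: int = DEFAULT_WINDOW_LEN,
    step: int = DEFAULT_STEP,
    label_policy: str = "pure",
) -> list[Window]:
    """Slide a window of ``window_len`` samples over ``rec`` at stride ``step``.

    ``pure`` keeps a window only when every sample carries one and the same
    label; ``majority`` keeps it when strictly more than half the samples
    share a label.  Candidate offsets are 0, step, 2·step, …; for a fully
    labeled recording of length L the count is floor((L − W)/S) + 1.
    """
    if step <= 0:
        raise ValueError("step must be >= 1")
    if window_len < 1:
        raise ValueError("window_len must be >= 1")
    if step > window_len:
        raise ValueError("step must not exceed window_len")
    if label_policy not in ("pure", "majority"):
        raise ValueError(f"unknown label_policy {label_policy!r}")
    L = rec.n_samples
    if L < window_len:
        return []
    labels = _sample_labels(rec)
    out: list[Window] = []
    n_unlabeled_dropped = 0
    for off in range(0, L - window_len + 1, step):
        seg = labels[off : off + window_len]
        lab_idx = _window_label(seg, label_policy)
        if lab_idx is None:
            n_unlabeled_dropped += 1
            continue
        out.append(
            Window(
                values=rec.samples[:, off : off + window_len].copy(),
                label=CLASS_ORDER[lab_idx],
                sampling_rate=rec.sampling_rate,
                source_participant=rec.participant_id,
                source_offset=off,
            )
        )
    return out


def _window_label(seg: np.ndarray, policy: str) -> int | None:
    if policy == "pure":
        first = seg[0]
        if first < 0 or not np.all(seg == first):
            return None
        return int(first)
    # majority: strictly more than half, unlabeled samples never win
    vals, counts = np.unique(seg[seg >= 0], return_counts=True)
    if len(vals) == 0:
        return None
    best = int(np.argmax(counts))
    if counts[best] * 2 > len(seg):
        return int(vals[best])
    return None


def summarize(ds: Dataset) -> dict:
    """Per-class and per-participant window tallies (all six classes listed)."""
    per_class = {lab.code: 0 for lab in CLASS_ORDER}
    per_participant: dict[str, int] = {}
    for w in ds.windows:
        per_class[w.label.code] += 1
        per_participant[w.source_participant] = (
            per_participant.get(w.source_participant, 0) + 1
        )
    return {
        "n_windows": len(ds.windows),
        "per_class": per_class,
        "per_participant": dict(sorted(per_participant.items())),
    }
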