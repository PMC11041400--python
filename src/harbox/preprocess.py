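"""Normalization, rate reduction, sensor masking, and dimension sampling.

These transforms sit between windowed data and the classifiers.  The
dimension sampler drives dimension-adaptive training: each batch is pushed
through a randomly drawn (target rate, sensor subset) configuration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Sequence

import numpy as np
from scipy.signal import decimate

from .imu_data import ChannelSet, Dataset, Window

__all__ = [
    "NormalizationStats",
    "SensorMask",
    "DimensionConfig",
    "fit_normalization",
    "normalize",
    "normalize_dataset",
    "resample",
    "mask_sensors",
    "sample_dimension_config",
    "channel_relevance",
    "default_dimension_space",
    "DEFAULT_RATES",
    "DEFAULT_MASKS",
]

_GROUPS = ("accelerometer", "gyroscope", "magnetometer")


@dataclass(frozen=True)
class SensorMask:
    """Subset of sensor groups currently available as model input."""

    available: frozenset[str]

    def __init__(self, available) -> None:
        avail = frozenset(available)
        unknown = avail - set(_GROUPS)
        if unknown:
            raise ValueError(f"unknown sensor groups: {sorted(unknown)}")
        object.__setattr__(self, "available", avail)

    def __contains__(self, group: str) -> bool:
        return group in self.available

    def short_name(self) -> str:
        abbrev = {"accelerometer": "acc", "gyroscope": "gyr", "magnetometer": "mag"}
        return "+".join(abbrev[g] for g in _GROUPS if g in self.available) or "none"


FULL_MASK = SensorMask({"accelerometer", "gyroscope"})


@dataclass(frozen=True)
class DimensionConfig:
    """A (target sampling rate, sensor subset) input-dimensionality pair."""

    rate: float
    mask: SensorMask

    def __post_init__(self) -> None:
        if not self.rate > 0:
            raise ValueError("rate must be positive")

    def short_name(self) -> str:
        rate = int(self.rate) if float(self.rate).is_integer() else self.rate
        return f"{rate}Hz/{self.mask.short_name()}"


DEFAULT_RATES = (50.0, 25.0, 10.0, 5.0)
DEFAULT_MASKS = (
    SensorMask({"accelerometer"}),
    SensorMask({"gyroscope"}),
    SensorMask({"accelerometer", "gyroscope"}),
)


def default_dimension_space() -> list[DimensionConfig]:
    """Rates {50, 25, 10, 5} Hz crossed with {acc, gyr, acc+gyr}."""
    return [
        DimensionConfig(rate=r, mask=m) for r in DEFAULT_RATES for m in DEFAULT_MASKS
    ]


@dataclass(frozen=True)
class NormalizationStats:
    """Per-channel mean and population standard deviation from training data."""

    mean: np.ndarray
    std: np.ndarray
    channel_names: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "mean", np.asarray(self.mean, dtype=float))
        object.__setattr__(self, "std", np.asarray(self.std, dtype=float))
        if self.mean.shape != self.std.shape:
            raise ValueError("mean and std shapes differ")
        if np.any(self.std < 0):
            raise ValueError("std must be non-negative")

    def to_json(self, dest: IO | str | Path) -> None:
        doc = {
            "mean": self.mean.tolist(),
            "std": self.std.tolist(),
            "channel_names": list(self.channel_names),
        }
        if isinstance(dest, (str, Path)):
            with open(dest, "w", encoding="utf-8") as fh:
                json.dump(doc, fh, indent=1)
        else:
            json.dump(doc, dest)

    @classmethod
    def from_json(cls, source: IO | str | Path) -> "NormalizationStats":
        if isinstance(source, (str, Path)):
            with open(source, "r", encoding="utf-8") as fh:
                doc = json.load(fh)
        else:
            doc = json.load(source)
        return cls(
            mean=np.asarray(doc["mean"]),
            std=np.asarray(doc["std"]),
            channel_names=tuple(doc["channel_names"]),
        )


def fit_normalization(train: Dataset) -> NormalizationStats:
    """Pooled per-channel mean/std over all samples of all training windows."""
    if not train.windows:
        raise ValueError("cannot fit normalization on an empty dataset")
    X, _ = train.stacked()  # (n, C, T)
    flat = X.transpose(1, 0, 2).reshape(X.shape[1], -1)
    return NormalizationStats(
        mean=flat.mean(axis=1),
        std=flat.std(axis=1),  # population convention (ddof=0)
        channel_names=train.channels.names,
    )


def normalize(w: Window, stats: NormalizationStats) -> Window:
    """Map each channel to (x − mean)/std; zero-variance channels go to 0."""
    if w.n_channels != stats.mean.shape[0]:
        raise ValueError(
            f"window has {w.n_channels} channels, stats has {stats.mean.shape[0]}"
        )
    std = np.where(stats.std > 0, stats.std, 1.0)
    vals = (w.values - stats.mean[:, None]) / std[:, None]
    vals[stats.std == 0] = 0.0
    return Window(
        values=vals,
        label=w.label,
        sampling_rate=w.sampling_rate,
        source_participant=w.source_participant,
        source_offset=w.source_offset,
    )


def normalize_dataset(ds: Dataset, stats: NormalizationStats) -> Dataset:
    return Dataset([normalize(w, stats) for w in ds.windows], ds.channels)


def resample(w: Window, target_rate: float, *, anti_alias: bool = False) -> Window:
    """Linearly interpolate a window onto a uniform grid at ``target_rate``.

    Output length is max(1, round(T·target/source)); for integer decimation
    factors this reduces to taking every k-th sample (phase 0).  Upsampling
    is refused.  ``anti_alias=True`` applies a zero-phase low-pass before
    integer decimation instead (opt-in).
    """
    if not 0 < target_rate <= w.sampling_rate + 1e-12:
        raise ValueError(
            f"target rate {target_rate} exceeds source rate {w.sampling_rate}"
        )
    if abs(target_rate - w.sampling_rate) < 1e-12:
        return w
    T = w.window_len
    out_len = max(1, round(T * target_rate / w.sampling_rate))
    factor = w.sampling_rate / target_rate
    if anti_alias and float(factor).is_integer() and factor > 1:
        vals = decimate(w.values, int(factor), axis=1, zero_phase=True)
        vals = vals[:, :out_len]
    else:
        # sample times of the coarse grid expressed in source-sample units
        src_idx = np.arange(out_len) * (w.sampling_rate / target_rate)
        src_idx = np.clip(src_idx, 0, T - 1)
        base = np.arange(T, dtype=float)
        vals = np.vstack([np.interp(src_idx, base, row) for row in w.values])
    return Window(
        values=vals,
        label=w.label,
        sampling_rate=target_rate,
        source_participant=w.source_participant,
        source_offset=w.source_offset,
    )


def mask_sensors(
    w: Window,
    mask: SensorMask,
    channels: ChannelSet,
    mode: str = "drop",
) -> Window:
    """Remove (``drop``) or zero (``zero_fill``) unavailable sensor rows.

    ``drop`` shrinks the channel axis (for the dimension-adaptive model);
    ``zero_fill`` keeps the full shape (for the fixed-dimension model).
    """
    if not mask.available:
        raise ValueError("no sensors available (empty mask)")
    if mode not in ("drop", "zero_fill"):
        raise ValueError(f"unknown mode {mode!r}")
    present = [g for g in channels.groups if g in mask]
    if set(channels.groups) <= mask.available:
        return w
    if mode == "drop":
        keep = np.concatenate([channels.group_indices(g) for g in present])
        vals = w.values[np.sort(keep)]
    else:
        vals = w.values.copy()
        for g in channels.groups:
            if g not in mask:
                vals[channels.group_indices(g)] = 0.0
    return Window(
        values=vals,
        label=w.label,
        sampling_rate=w.sampling_rate,
        source_participant=w.source_participant,
        source_offset=w.source_offset,
    )


def sample_dimension_config(
    rng: np.random.Generator, space: Sequence[DimensionConfig]
) -> DimensionConfig:
    """Draw one configuration uniformly at random (reproducible via ``rng``)."""
    if len(space) == 0:
        raise ValueError("dimension space is empty")
    return space[int(rng.integers(len(space)))]


def channel_relevance(ds: Dataset) -> list[tuple[str, float]]:
    """Rank channels by share of total pooled variance (descending).

    A cheap variance screening that flags near-constant channels as
    uninformative; scores sum to 1.  Ties break by channel order.
    """
    if len(ds.windows) < 2:
        raise ValueError("need at least 2 windows to estimate channel relevance")
    X, _ = ds.stacked()
    flat = X.transpose(1, 0, 2).reshape(X.shape[1], -1)
    var = flat.var(axis=1)
    total = var.sum()
    scores = var / total if total > 0 else np.full(len(var), 1.0 / len(var))
    order = sorted(
        range(len(scores)), key=lambda i: (-scores[i], i)
    )
    return [(ds.channels.names[i], float(scores[i])) for i in order]
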