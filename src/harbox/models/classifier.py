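"""The two classifier variants.

``simple``: fixed-dimension CNN–LSTM — temporal convolution blocks over the
full (channels × window_len) input, an LSTM over the pooled time axis, a
dense layer, and a softmax head.  Rejects any input whose shape differs
from the training shape.

``dana``: dimension-adaptive — the same convolution stack applied to each
sensor channel independently with shared weights, a dimension-adaptive
pooling layer collapsing the (channel, time) axes to a fixed grid, then
LSTM over the pooled time bins.  Accepts any channel count and any window
length of at least one sample.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from ..imu_data import CLASS_ORDER, ActivityLabel, Window
from ..preprocess import NormalizationStats
from .dap import DapSpec, dap_pool, dap_pool_backward
from .layers import (
    Adam,
    Conv1d,
    Dense,
    Dropout,
    LSTM,
    MaxPool1d,
    ReLU,
    softmax,
    softmax_cross_entropy,
)

__all__ = ["ModelSpec", "Classifier", "build_classifier", "predict_proba", "classify"]


@dataclass(frozen=True)
class ModelSpec:
    """Architecture hyperparameters for either classifier variant."""

    variant: str = "simple"
    n_classes: int = 6
    input_channels: int = 6
    window_len: int = 128
    conv_blocks: tuple[tuple[int, int], ...] = ((64, 5), (64, 5))
    recurrent_units: int = 64
    dense_units: int = 64
    dropout_rate: float = 0.25
    dap: DapSpec | None = None

    def __post_init__(self) -> None:
        if self.variant not in ("simple", "dana"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if self.variant == "dana" and self.dap is None:
            object.__setattr__(self, "dap", DapSpec())
        if self.variant == "simple" and self.dap is not None:
            raise ValueError("simple variant takes no DapSpec")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["conv_blocks"] = [list(b) for b in self.conv_blocks]
        if self.dap is not None:
            d["dap"] = {
                "out_time_bins": self.dap.out_time_bins,
                "out_channel_bins": self.dap.out_channel_bins,
            }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        d = dict(d)
        d["conv_blocks"] = tuple(tuple(b) for b in d["conv_blocks"])
        if d.get("dap"):
            d["dap"] = DapSpec(**d["dap"])
        return cls(**d)


class Classifier:
    """A built (possibly trained) model plus its preprocessing sidecar."""

    def __init__(self, spec: ModelSpec, seed: int = 0):
        self.spec = spec
        self.seed = seed
        self.class_order: tuple[ActivityLabel, ...] = CLASS_ORDER[: spec.n_classes]
        self.preprocessing: NormalizationStats | None = None
        rng = np.random.default_rng(seed)
        self._build(rng)

    # -- construction -----------------------------------------------------
    def _build(self, rng: np.random.Generator) -> None:
        s = self.spec
        conv_in = s.input_channels if s.variant == "simple" else 1
        self.conv_layers: list = []
        c_prev = conv_in
        for filters, kernel in s.conv_blocks:
            self.conv_layers += [
                Conv1d(c_prev, filters, kernel, rng),
                ReLU(),
                MaxPool1d(2),
            ]
            c_prev = filters
        self._conv_out_filters = c_prev
        if s.variant == "simple":
            lstm_in = c_prev
        else:
            lstm_in = c_prev * s.dap.out_channel_bins
        self.lstm = LSTM(lstm_in, s.recurrent_units, rng)
        self.dropout = Dropout(s.dropout_rate)
        self.dense1 = Dense(s.recurrent_units, s.dense_units, rng)
        self.dense_relu = ReLU()
        self.dense2 = Dense(s.dense_units, s.n_classes, rng)

    @property
    def layers(self) -> list:
        return self.conv_layers + [
            self.lstm,
            self.dropout,
            self.dense1,
            self.dense_relu,
            self.dense2,
        ]

    def n_parameters(self) -> int:
        return sum(p.size for l in self.layers for p in l.params.values())

    # -- forward / backward ----------------------------------------------
    def forward_logits(self, X: np.ndarray, train: bool = False) -> np.ndarray:
        """Logits for a batch X of shape (B, C, T)."""
        from .layers import DTYPE

        X = np.asarray(X, dtype=DTYPE)
        if X.ndim != 3:
            raise ValueError("batch must be 3-D (batch, channels, time)")
        s = self.spec
        if s.variant == "simple":
            if X.shape[1] != s.input_channels or X.shape[2] != s.window_len:
                raise ValueError(
                    f"simple variant requires fixed input "
                    f"({s.input_channels} x {s.window_len}), got "
                    f"({X.shape[1]} x {X.shape[2]})"
                )
            h = X
            for layer in self.conv_layers:
                h = layer.forward(h, train)
            h = h.transpose(0, 2, 1)  # (B, T', F)
            self._lstm_in_shape = h.shape
        else:
            B, C, T = X.shape
            if C < 1 or T < 1:
                raise ValueError("dana input must have >=1 channel and sample")
            h = X.reshape(B * C, 1, T)
            for layer in self.conv_layers:
                h = layer.forward(h, train)
            F, Tc = h.shape[1], h.shape[2]
            h = h.reshape(B, C, F, Tc).transpose(0, 2, 1, 3)  # (B, F, C, T')
            self._pre_dap_shape = (B, C, F, Tc)
            pooled = dap_pool(h, s.dap)  # (B, F, Cb, Tb)
            h = pooled.transpose(0, 3, 2, 1)  # (B, Tb, Cb, F)
            self._lstm_in_shape = (h.shape[0], h.shape[1], h.shape[2] * h.shape[3])
            h = h.reshape(self._lstm_in_shape)
        h = self.lstm.forward(h, train)
        h = self.dropout.forward(h, train)
        h = self.dense1.forward(h, train)
        h = self.dense_relu.forward(h, train)
        return self.dense2.forward(h, train)

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.dense2.backward(dlogits)
        d = self.dense_relu.backward(d)
        d = self.dense1.backward(d)
        d = self.dropout.backward(d)
        d = self.lstm.backward(d)
        s = self.spec
        if s.variant == "simple":
            d = d.reshape(self._lstm_in_shape).transpose(0, 2, 1)
        else:
            B, C, F, Tc = self._pre_dap_shape
            Cb, Tb = s.dap.out_channel_bins, s.dap.out_time_bins
            d = d.reshape(B, Tb, Cb, F).transpose(0, 3, 2, 1)  # (B, F, Cb, Tb)
            d = dap_pool_backward(d, C, Tc, s.dap)  # (B, F, C, T')
            d = d.transpose(0, 2, 1, 3).reshape(B * C, F, Tc)
        for layer in reversed(self.conv_layers):
            d = layer.backward(d)

    # -- persistence ------------------------------------------------------
    def save(self, directory: str | Path) -> None:
        """Write a self-contained bundle: spec, weights, preprocessing."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        with open(directory / "spec.json", "w", encoding="utf-8") as fh:
            json.dump({"model": self.spec.to_dict(), "seed": self.seed}, fh, indent=1)
        arrays = {}
        for li, layer in enumerate(self.layers):
            for k, v in layer.params.items():
                arrays[f"layer{li}.{k}"] = v
        np.savez(directory / "weights.npz", **arrays)
        if self.preprocessing is not None:
            self.preprocessing.to_json(directory / "normalization.json")

    @classmethod
    def load(cls, directory: str | Path) -> "Classifier":
        directory = Path(directory)
        with open(directory / "spec.json", "r", encoding="utf-8") as fh:
            doc = json.load(fh)
        model = cls(ModelSpec.from_dict(doc["model"]), seed=doc.get("seed", 0))
        with np.load(directory / "weights.npz") as arrs:
            for li, layer in enumerate(model.layers):
                for k in layer.params:
                    layer.params[k] = arrs[f"layer{li}.{k}"].copy()
        norm_path = directory / "normalization.json"
        if norm_path.exists():
            model.preprocessing = NormalizationStats.from_json(norm_path)
        return model


def build_classifier(spec: ModelSpec, seed: int = 0) -> Classifier:
    """Construct an untrained classifier; initialization is seed-reproducible."""
    return Classifier(spec, seed=seed)


def _stack_windows(windows: Sequence[Window]) -> list[tuple[np.ndarray, list[int]]]:
    """Group windows by shape so variable-dimension batches stay rectangular."""
    groups: dict[tuple[int, int], list[int]] = {}
    for i, w in enumerate(windows):
        groups.setdefault(w.values.shape, []).append(i)
    out = []
    for shape, idx in groups.items():
        out.append((np.stack([windows[i].values for i in idx]), idx))
    return out


def predict_proba(model: Classifier, windows: Sequence[Window]) -> np.ndarray:
    """Class-probability matrix (n_windows × n_classes); rows sum to 1."""
    n = len(windows)
    out = np.zeros((n, model.spec.n_classes))
    if n == 0:
        return out
    for X, idx in _stack_windows(windows):
        probs = softmax(model.forward_logits(X, train=False))
        out[idx] = probs
    return out


def classify(model: Classifier, windows: Sequence[Window]) -> list[ActivityLabel]:
    """Argmax of :func:`predict_proba`; ties break toward earlier class order."""
    probs = predict_proba(model, windows)
    return [model.class_order[int(np.argmax(row))] for row in probs]
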