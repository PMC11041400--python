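"""Training loop, subject-wise splitting, and the robustness evaluations.

Evaluation protocols mirror the study design: within-dataset accuracy,
cross-dataset accuracy (normalizing the foreign data with the *training*
domain's statistics), and a sampling-rate × sensor-subset grid probing one
trained model under degraded input dimensionality.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Sequence

import numpy as np

from .imu_data import CLASS_ORDER, ActivityLabel, Dataset
from .models.classifier import Classifier
from .models.layers import Adam, softmax, softmax_cross_entropy
from .preprocess import (
    DimensionConfig,
    NormalizationStats,
    SensorMask,
    default_dimension_space,
    fit_normalization,
    sample_dimension_config,
)

__all__ = [
    "TrainConfig",
    "ConfusionMatrix",
    "EvaluationGrid",
    "EvalResult",
    "split_by_participant",
    "train",
    "evaluate",
    "cross_evaluate",
    "dimension_grid_evaluate",
    "report",
    "render_report",
    "load_report",
]


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 100
    batch_size: int = 64
    learning_rate: float = 1e-3
    seed: int = 0
    dimension_adaptive: bool = False
    dimension_space: tuple[DimensionConfig, ...] = ()

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.dimension_adaptive and not self.dimension_space:
            object.__setattr__(
                self, "dimension_space", tuple(default_dimension_space())
            )


@dataclass
class ConfusionMatrix:
    """6x6 tally; rows are true classes, columns predictions, fixed order."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=int)
        n = len(CLASS_ORDER)
        if c.shape != (n, n) or (c < 0).any():
            raise ValueError(f"counts must be a non-negative {n}x{n} matrix")
        self.counts = c

    @classmethod
    def from_predictions(
        cls, y_true: np.ndarray, y_pred: np.ndarray
    ) -> "ConfusionMatrix":
        n = len(CLASS_ORDER)
        c = np.zeros((n, n), dtype=int)
        np.add.at(c, (np.asarray(y_true, int), np.asarray(y_pred, int)), 1)
        return cls(c)

    @property
    def n_total(self) -> int:
        return int(self.counts.sum())

    @property
    def accuracy(self) -> float:
        total = self.counts.sum()
        return float(np.trace(self.counts) / total) if total else float("nan")

    def row_normalized(self) -> np.ndarray:
        """Per-true-class rates; rows with no support become NaN."""
        sums = self.counts.sum(axis=1, keepdims=True).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(sums > 0, self.counts / sums, np.nan)

    def macro_f1(self) -> float:
        c = self.counts.astype(float)
        tp = np.diag(c)
        fp = c.sum(axis=0) - tp
        fn = c.sum(axis=1) - tp
        denom = 2 * tp + fp + fn
        f1 = np.divide(2 * tp, denom, out=np.zeros_like(tp), where=denom > 0)
        support = c.sum(axis=1) > 0
        return float(f1[support].mean()) if support.any() else float("nan")

    def to_dict(self) -> dict:
        return {"counts": self.counts.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "ConfusionMatrix":
        return cls(np.asarray(d["counts"]))


@dataclass
class EvalResult:
    accuracy: float
    cm: ConfusionMatrix
    model_id: str = "model"
    dataset_id: str = "dataset"
    train_dataset_id: str | None = None
    dim: DimensionConfig | None = None

    def to_dict(self) -> dict:
        d = {
            "kind": "evaluation",
            "model_id": self.model_id,
            "dataset_id": self.dataset_id,
            "accuracy": self.accuracy,
            "macro_f1": self.cm.macro_f1(),
            "confusion": self.cm.counts.tolist(),
        }
        if self.train_dataset_id is not None:
            d["train_dataset_id"] = self.train_dataset_id
        if self.dim is not None:
            d["dimension"] = self.dim.short_name()
        return d


@dataclass
class EvaluationGrid:
    """Accuracy per (rate, sensor-subset) cell for one trained model."""

    cells: dict[DimensionConfig, float]
    model_id: str = "model"
    dataset_id: str = "dataset"

    def __post_init__(self) -> None:
        for cfg, acc in self.cells.items():
            if not 0.0 <= acc <= 1.0:
                raise ValueError(f"accuracy {acc} for {cfg.short_name()} not in [0,1]")

    def to_dict(self) -> dict:
        return {
            "kind": "grid",
            "model_id": self.model_id,
            "dataset_id": self.dataset_id,
            "cells": {cfg.short_name(): acc for cfg, acc in self.cells.items()},
        }


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------


def split_by_participant(
    ds: Dataset, test_fraction: float, seed: int
) -> tuple[Dataset, Dataset]:
    """Partition whole participants into train/test (no identity leakage)."""
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must be in (0, 1)")
    people = ds.participants
    if len(people) < 2:
        raise ValueError(
            "need at least 2 participants for a subject-wise split; "
            "use a window-level split explicitly for single-participant data"
        )
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(people))
    n_test = min(len(people) - 1, max(1, round(test_fraction * len(people))))
    test_people = set(order[:n_test])
    train_idx = [
        i for i, w in enumerate(ds.windows) if w.source_participant not in test_people
    ]
    test_idx = [
        i for i, w in enumerate(ds.windows) if w.source_participant in test_people
    ]
    return ds.subset(train_idx), ds.subset(test_idx)


# ---------------------------------------------------------------------------
# Dimension transforms on stacked arrays (fast path used by train/evaluate)
# ---------------------------------------------------------------------------


def _resample_batch(X: np.ndarray, src_rate: float, tgt_rate: float) -> np.ndarray:
    """Vectorized linear interpolation of (B, C, T) onto the coarse grid."""
    if abs(src_rate - tgt_rate) < 1e-12:
        return X
    T = X.shape[2]
    out_len = max(1, round(T * tgt_rate / src_rate))
    src_idx = np.clip(np.arange(out_len) * (src_rate / tgt_rate), 0, T - 1)
    lo = np.floor(src_idx).astype(int)
    hi = np.minimum(lo + 1, T - 1)
    frac = src_idx - lo
    return X[:, :, lo] * (1.0 - frac) + X[:, :, hi] * frac


def _upsample_batch(X: np.ndarray, out_len: int) -> np.ndarray:
    """Linear re-expansion back to a fixed length (for the fixed-dim model)."""
    T = X.shape[2]
    if T == out_len:
        return X
    src_idx = np.linspace(0, T - 1, out_len)
    lo = np.floor(src_idx).astype(int)
    hi = np.minimum(lo + 1, T - 1)
    frac = src_idx - lo
    return X[:, :, lo] * (1.0 - frac) + X[:, :, hi] * frac


def _apply_dimension_batch(
    X: np.ndarray,
    dim: DimensionConfig,
    ds: Dataset,
    variant: str,
    native_rate: float,
) -> np.ndarray:
    """Degrade a stacked batch to a DimensionConfig.

    dana consumes drop-mode (fewer rows, shorter time axis); the simple
    variant keeps its fixed shape, so missing sensors are zero-filled and
    reduced rates are emulated by down- then re-up-sampling.
    """
    if dim.rate > native_rate + 1e-9:
        raise ValueError(f"target rate {dim.rate} exceeds native rate {native_rate}")
    if not dim.mask.available:
        raise ValueError("no sensors available (empty mask)")
    orig_len = X.shape[2]
    Xr = _resample_batch(X, native_rate, dim.rate)
    chans = ds.channels
    missing = [g for g in chans.groups if g not in dim.mask]
    if variant == "dana":
        if missing:
            keep = np.sort(
                np.concatenate(
                    [chans.group_indices(g) for g in chans.groups if g in dim.mask]
                )
            )
            Xr = Xr[:, keep, :]
        return Xr
    Xr = _upsample_batch(Xr, orig_len)
    if missing:
        Xr = Xr.copy()
        for g in missing:
            Xr[:, chans.group_indices(g), :] = 0.0
    return Xr


def _normalized_arrays(
    ds: Dataset, stats: NormalizationStats
) -> tuple[np.ndarray, np.ndarray]:
    X, y = ds.stacked()
    std = np.where(stats.std > 0, stats.std, 1.0)
    Xn = (X - stats.mean[None, :, None]) / std[None, :, None]
    Xn[:, stats.std == 0, :] = 0.0
    return Xn.astype(np.float32), y


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


def train(
    model: Classifier,
    train_ds: Dataset,
    cfg: TrainConfig,
) -> tuple[Classifier, list[dict]]:
    """Train in place; returns the model and a per-epoch loss/accuracy history.

    If the model has no preprocessing attached yet, normalization stats are
    fitted on ``train_ds`` and stored on the model.  With
    ``cfg.dimension_adaptive`` every batch is pushed through a freshly
    sampled (rate, sensor-subset) configuration before the forward pass.
    """
    if len(train_ds) == 0:
        raise ValueError("training dataset is empty")
    if cfg.dimension_adaptive and model.spec.variant == "simple":
        raise ValueError(
            "dimension-adaptive training requires the dana variant; the "
            "simple model is fixed-dimension"
        )
    if model.preprocessing is None:
        model.preprocessing = fit_normalization(train_ds)
    X, y = _normalized_arrays(train_ds, model.preprocessing)
    native_rate = train_ds.windows[0].sampling_rate
    rng = np.random.default_rng(cfg.seed)
    model.dropout.rng = rng
    optimizer = Adam(model.layers, lr=cfg.learning_rate)
    n = X.shape[0]
    history: list[dict] = []
    space = list(cfg.dimension_space)
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        correct = 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            Xb, yb = X[idx], y[idx]
            if cfg.dimension_adaptive:
                dim = sample_dimension_config(rng, space)
                Xb = _apply_dimension_batch(
                    Xb, dim, train_ds, model.spec.variant, native_rate
                )
            logits = model.forward_logits(Xb, train=True)
            loss, dlogits = softmax_cross_entropy(logits, yb)
            model.backward(dlogits)
            optimizer.step()
            losses.append(loss * len(idx))
            correct += int((logits.argmax(axis=1) == yb).sum())
        history.append(
            {
                "epoch": epoch + 1,
                "loss": float(np.sum(losses) / n),
                "accuracy": correct / n,
            }
        )
    return model, history


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------


def _predict_indices(
    model: Classifier, X: np.ndarray, batch: int = 512
) -> np.ndarray:
    preds = []
    for start in range(0, X.shape[0], batch):
        logits = model.forward_logits(X[start : start + batch], train=False)
        preds.append(logits.argmax(axis=1))
    return np.concatenate(preds) if preds else np.zeros(0, dtype=int)


def evaluate(
    model: Classifier,
    test_ds: Dataset,
    dim: DimensionConfig | None = None,
    *,
    stats: NormalizationStats | None = None,
    model_id: str = "model",
    dataset_id: str = "dataset",
) -> EvalResult:
    """Window accuracy and confusion matrix, optionally under a DimensionConfig.

    Test windows are normalized with the model's stored training statistics
    unless ``stats`` overrides them.
    """
    if len(test_ds) == 0:
        raise ValueError("test dataset is empty")
    stats = stats or model.preprocessing
    if stats is None:
        raise ValueError("model has no preprocessing statistics attached")
    X, y = _normalized_arrays(test_ds, stats)
    if dim is not None:
        X = _apply_dimension_batch(
            X, dim, test_ds, model.spec.variant, test_ds.windows[0].sampling_rate
        )
    y_pred = _predict_indices(model, X)
    cm = ConfusionMatrix.from_predictions(y, y_pred)
    return EvalResult(
        accuracy=cm.accuracy,
        cm=cm,
        model_id=model_id,
        dataset_id=dataset_id,
        dim=dim,
    )


def cross_evaluate(
    model: Classifier,
    test_ds: Dataset,
    *,
    train_dataset_id: str = "train-domain",
    test_dataset_id: str = "test-domain",
    model_id: str = "model",
    dim: DimensionConfig | None = None,
) -> EvalResult:
    """Evaluate on a foreign dataset using the training domain's normalization."""
    res = evaluate(model, test_ds, dim, model_id=model_id, dataset_id=test_dataset_id)
    res.train_dataset_id = train_dataset_id
    return res


def dimension_grid_evaluate(
    model: Classifier,
    test_ds: Dataset,
    rates: Sequence[float],
    masks: Sequence[SensorMask],
    *,
    model_id: str = "model",
    dataset_id: str = "dataset",
) -> EvaluationGrid:
    """One accuracy cell per (rate, mask) pair, probing a single trained model."""
    if not rates or not masks:
        raise ValueError("rates and masks must be non-empty")
    cells: dict[DimensionConfig, float] = {}
    for rate in rates:
        for mask in masks:
            dim = DimensionConfig(rate=float(rate), mask=mask)
            res = evaluate(model, test_ds, dim)
            cells[dim] = res.accuracy
    return EvaluationGrid(cells=cells, model_id=model_id, dataset_id=dataset_id)


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------


def report(
    results: Sequence[EvalResult | EvaluationGrid],
    json_path: str | Path | None = None,
    text_path: str | Path | None = None,
) -> dict:
    """Machine-readable summary of evaluation results (round-trip exact)."""
    if not results:
        raise ValueError("no results to report")
    doc = {
        "class_order": [lab.code for lab in CLASS_ORDER],
        "results": [r.to_dict() for r in results],
    }
    if json_path is not None:
        with open(json_path, "w", encoding="utf-8") as fh:
            json.dump(doc, fh, indent=1)
    if text_path is not None:
        with open(text_path, "w", encoding="utf-8") as fh:
            fh.write(render_report(doc))
    return doc


def load_report(source: IO | str | Path) -> dict:
    if isinstance(source, (str, Path)):
        with open(source, "r", encoding="utf-8") as fh:
            return json.load(fh)
    return json.load(source)


def render_report(doc: dict) -> str:
    """Human-readable tables for a report document."""
    lines: list[str] = []
    codes = doc["class_order"]
    for rec in doc["results"]:
        if rec["kind"] == "grid":
            lines.append(
                f"== grid: model={rec['model_id']} dataset={rec['dataset_id']} =="
            )
            for name, acc in rec["cells"].items():
                lines.append(f"  {name:<16} accuracy {acc:.4f}")
        else:
            pair = (
                f"{rec.get('train_dataset_id', rec['dataset_id'])} -> "
                f"{rec['dataset_id']}"
            )
            dimtxt = f" dim={rec['dimension']}" if "dimension" in rec else ""
            lines.append(
                f"== evaluation: model={rec['model_id']} ({pair}){dimtxt} =="
            )
            lines.append(
                f"  accuracy {rec['accuracy']:.4f}  macro-F1 {rec['macro_f1']:.4f}"
            )
            header = "  true\\pred " + " ".join(f"{c:>5}" for c in codes)
            lines.append(header)
            for code, row in zip(codes, rec["confusion"]):
                lines.append(
                    f"  {code:>9} " + " ".join(f"{v:>5d}" for v in row)
                )
        lines.append("")
    return "\n".join(lines)
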