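"""Dimension-adaptive pooling: bin-average any (C, T) map to a fixed grid.

Output cell (i, j) averages input rows [floor(i·C/Cb), floor((i+1)·C/Cb))
and columns [floor(j·T/Tb), floor((j+1)·T/Tb)).  When a requested bin count
exceeds the input size the floor boundaries would produce empty bins, so
each bin end is clamped to at least start+1 — bins then replicate input
elements and every input element still belongs to at least one bin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["DapSpec", "dap_pool", "bin_edges", "dap_pool_backward"]


@dataclass(frozen=True)
class DapSpec:
    """Fixed output grid of the dimension-adaptive pooling layer."""

    out_time_bins: int = 8
    out_channel_bins: int = 6

    def __post_init__(self) -> None:
        if self.out_time_bins < 1 or self.out_channel_bins < 1:
            raise ValueError("bin counts must be >= 1")


def bin_edges(n: int, bins: int) -> list[tuple[int, int]]:
    """Half-open [start, end) index ranges of each pooling bin."""
    edges = []
    for i in range(bins):
        start = (i * n) // bins
        end = max(start + 1, ((i + 1) * n) // bins)
        edges.append((start, end))
    return edges


def dap_pool(feature_map: np.ndarray, spec: DapSpec) -> np.ndarray:
    """Pool a (C, T) matrix — or a batch (..., C, T) — to (Cb, Tb).

    Leading axes are preserved; the last two are pooled.
    """
    fm = np.asarray(feature_map)
    if not np.issubdtype(fm.dtype, np.floating):
        fm = fm.astype(float)
    if fm.ndim < 2:
        raise ValueError("feature map must have at least 2 dimensions")
    C, T = fm.shape[-2], fm.shape[-1]
    if C < 1 or T < 1:
        raise ValueError("feature map must be non-empty in both axes")
    rows = bin_edges(C, spec.out_channel_bins)
    cols = bin_edges(T, spec.out_time_bins)
    # cumulative-sum trick: bin sums in O(C*T + Cb*Tb)
    cs = fm.cumsum(axis=-2).cumsum(axis=-1)
    cs = np.pad(cs, [(0, 0)] * (fm.ndim - 2) + [(1, 0), (1, 0)])
    r0 = np.array([r[0] for r in rows])
    r1 = np.array([r[1] for r in rows])
    c0 = np.array([c[0] for c in cols])
    c1 = np.array([c[1] for c in cols])
    sums = (
        cs[..., r1[:, None], c1[None, :]]
        - cs[..., r0[:, None], c1[None, :]]
        - cs[..., r1[:, None], c0[None, :]]
        + cs[..., r0[:, None], c0[None, :]]
    )
    areas = (r1 - r0)[:, None] * (c1 - c0)[None, :]
    return sums / areas


def dap_pool_backward(
    dy: np.ndarray, in_channels: int, in_time: int, spec: DapSpec
) -> np.ndarray:
    """Gradient of ``dap_pool`` w.r.t. its input (batched like the forward)."""
    rows = bin_edges(in_channels, spec.out_channel_bins)
    cols = bin_edges(in_time, spec.out_time_bins)
    dx = np.zeros(dy.shape[:-2] + (in_channels, in_time), dtype=dy.dtype)
    for i, (r0, r1) in enumerate(rows):
        for j, (c0, c1) in enumerate(cols):
            area = (r1 - r0) * (c1 - c0)
            dx[..., r0:r1, c0:c1] += dy[..., i : i + 1, j : j + 1] / area
    return dx
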