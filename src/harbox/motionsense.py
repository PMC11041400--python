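"""Optional adapter for a locally downloaded MotionSense-style folder layout.

Expects the device-motion directory structure: one sub-folder per activity
trial named ``<code>_<trial>`` (e.g. ``wlk_7``) containing ``sub_<n>.csv``
files with per-sample ``userAcceleration.{x,y,z}`` and
``rotationRate.{x,y,z}`` columns.  The public archive is never downloaded
or required by the test suite; callers opt in with ``external_data=True``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .imu_data import (
    DEFAULT_CHANNELS,
    ActivityLabel,
    LabelSpan,
    Recording,
)

__all__ = ["load_motionsense_dir"]

_ACC_COLS = ("userAcceleration.x", "userAcceleration.y", "userAcceleration.z")
_ROT_COLS = ("rotationRate.x", "rotationRate.y", "rotationRate.z")
_G = 9.81  # MotionSense user acceleration is in g units


def load_motionsense_dir(
    root: str | Path,
    *,
    external_data: bool = False,
    rate: float = 50.0,
) -> list[Recording]:
    """Read every trial folder into per-participant labeled recordings.

    Trials of one participant are concatenated in folder order, each trial
    contributing one label span.  Refuses to run unless ``external_data``
    is set, keeping the required pipeline free of external downloads.
    """
    if not external_data:
        raise ValueError(
            "MotionSense is external data; pass external_data=True to "
            "confirm you are loading a locally downloaded copy"
        )
    root = Path(root)
    trial_dirs = sorted(
        d for d in root.iterdir() if d.is_dir() and "_" in d.name
    )
    if not trial_dirs:
        raise FileNotFoundError(f"no trial folders under {root}")
    per_participant: dict[str, list[tuple[ActivityLabel, np.ndarray]]] = {}
    for trial in trial_dirs:
        code = trial.name.split("_")[0]
        try:
            label = ActivityLabel.from_code(code)
        except ValueError:
            continue
        for csv in sorted(trial.glob("sub_*.csv")):
            df = pd.read_csv(csv)
            block = np.vstack(
                [df[c].to_numpy() * _G for c in _ACC_COLS]
                + [df[c].to_numpy() for c in _ROT_COLS]
            )
            per_participant.setdefault(csv.stem, []).append((label, block))
    recordings = []
    for pid, blocks in sorted(per_participant.items()):
        samples = np.concatenate([b for _, b in blocks], axis=1)
        spans = []
        t = 0.0
        for label, block in blocks:
            dur = block.shape[1] / rate
            spans.append(LabelSpan(start=t, end=t + dur, label=label))
            t += dur
        recordings.append(
            Recording(
                participant_id=pid,
                sampling_rate=rate,
                channels=DEFAULT_CHANNELS,
                samples=samples,
                t0=0.0,
                label_spans=spans,
            )
        )
    return recordings
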