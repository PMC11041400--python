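import io

import numpy as np
import pytest

from harbox.imu_data import (
    DEFAULT_CHANNELS,
    ActivityLabel,
    Dataset,
    LabelSpan,
    Recording,
    Window,
    apply_labels,
)


def make_recording(
    n_samples=500,
    rate=50.0,
    participant_id="p000",
    seed=0,
    label=ActivityLabel.WLK,
):
    """A labeled single-activity recording with reproducible random samples."""
    rng = np.random.default_rng(seed)
    rec = Recording(
        participant_id=participant_id,
        sampling_rate=rate,
        channels=DEFAULT_CHANNELS,
        samples=rng.normal(size=(6, n_samples)),
    )
    span = LabelSpan(0.0, n_samples / rate, label)
    return apply_labels(rec, [span])


def make_window(values, label=ActivityLabel.WLK, rate=50.0, participant="p000"):
    return Window(
        values=np.asarray(values, dtype=float),
        label=label,
        sampling_rate=rate,
        source_participant=participant,
        source_offset=0,
    )


def make_dataset(n_windows=12, n_channels=6, window_len=32, seed=0, n_participants=3):
    """Random-valued dataset cycling through labels and participants."""
    rng = np.random.default_rng(seed)
    labels = list(ActivityLabel)
    windows = [
        Window(
            values=rng.normal(size=(n_channels, window_len)),
            label=labels[i % len(labels)],
            sampling_rate=50.0,
            source_participant=f"p{i % n_participants:03d}",
            source_offset=i,
        )
        for i in range(n_windows)
    ]
    return Dataset(windows, DEFAULT_CHANNELS)


@pytest.fixture
def labeled_recording():
    return make_recording()


@pytest.fixture
def small_dataset():
    return make_dataset()


@pytest.fixture
def csv_stream():
    def _make(rows, header="timestamp,acc_x,acc_y,acc_z,rot_roll,rot_pitch,rot_yaw"):
        return io.StringIO(header + "\n" + "\n".join(rows) + ("\n" if rows else ""))

    return _make


@pytest.fixture(scope="session")
def trained_simple_model():
    """A quickly trained fixed-dimension model shared across tests.

    4 synthetic participants, 12 epochs: enough to be far better than
    chance without dominating suite runtime.
    """
    from harbox.models.classifier import ModelSpec, build_classifier
    from harbox.synthetic import synth_dataset
    from harbox.train_eval import TrainConfig, split_by_participant, train

    ds = synth_dataset(4, seed=42)
    train_ds, test_ds = split_by_participant(ds, 0.25, seed=0)
    model = build_classifier(ModelSpec(variant="simple"), seed=0)
    model, history = train(model, train_ds, TrainConfig(epochs=12, seed=0))
    return model, train_ds, test_ds, history


@pytest.fixture(scope="session")
def trained_dana_model():
    """A briefly dimension-adaptively trained dana model shared across tests."""
    from harbox.models.classifier import ModelSpec, build_classifier
    from harbox.synthetic import synth_dataset
    from harbox.train_eval import TrainConfig, split_by_participant, train

    ds = synth_dataset(4, seed=42)
    train_ds, test_ds = split_by_participant(ds, 0.25, seed=0)
    model = build_classifier(ModelSpec(variant="dana"), seed=0)
    model, _ = train(
        model, train_ds, TrainConfig(epochs=6, seed=0, dimension_adaptive=True)
    )
    return model, train_ds, test_ds
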