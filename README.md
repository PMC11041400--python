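# harbox

A trainable, open toolbox for human-activity recognition from smartphone
IMU streams. It turns raw 6-channel accelerometer + gyroscope recordings
(CSV or JSON exports) into labeled fixed-length windows and trains one of
two classifiers:

- **simple** — a fixed-dimension CNN–LSTM: temporal convolution blocks over
  the full `6 × 128` window, an LSTM over the pooled time axis, and a
  softmax head. Fast to train (minutes on one CPU) but requires a fixed
  input shape.
- **dana** — a dimension-adaptive variant: the convolution stack is applied
  per sensor channel with shared weights and a dimension-adaptive pooling
  (DAP) layer collapses any (channel × time) feature map to a fixed grid,
  so one model handles varying sampling rates and sensor subsets.
  Dimension-adaptive training pushes every batch through a randomly drawn
  (rate, sensor-subset) configuration.

Evaluation supports within-dataset accuracy, cross-dataset accuracy (with
training-domain normalization), 6×6 confusion matrices, and a sampling-rate
× sensor-subset robustness grid probing a single trained model.

Because the original study data is not distributable, the package ships a
synthetic IMU generator that emulates a ~300 s six-activity course
(walking, jogging, sitting, stairs up, standing, stairs down) at 50 Hz per
participant, with per-participant cadence jitter and a controllable domain
shift (rotated wearing orientation, scaled amplitudes, shifted cadences)
for cross-domain experiments. The neural layers (conv1d, LSTM, DAP, Adam)
are implemented in numpy with manual backpropagation — no deep-learning
framework required.

## Layout

| module | contents |
| --- | --- |
| `harbox.imu_data` | activity labels, channel sets, recordings, label spans, CSV/JSON I/O, sliding-window segmentation |
| `harbox.preprocess` | z-score normalization, linear-interpolation rate reduction, sensor masking (drop / zero-fill), dimension-configuration sampling, variance-share channel screening |
| `harbox.models` | DAP primitive, numpy NN layers, the two classifier variants, model bundles |
| `harbox.train_eval` | training loop, subject-wise splitting, evaluate / cross-evaluate / grid-evaluate, reporting |
| `harbox.synthetic` | the course generator and domain-shift model |
| `harbox.cli` | `harbox` command-line entry point |
| `harbox.motionsense` | optional adapter for a locally downloaded MotionSense-style directory (opt-in, never required) |

## CLI

```sh
# generate 8 synthetic participants (CSV dialect, labeled)
harbox synth --out data/ --n 8 --seed 1

# train the fixed-dimension model (100 epochs by default)
harbox train --data data/ --out run/ --variant simple --epochs 100 --seed 1

# or the dimension-adaptive model
harbox train --data data/ --out run-dana/ --variant dana --dimension-adaptive

# evaluate / cross-evaluate / robustness grid
harbox eval --bundle run/model --data data/ --out run/eval
harbox cross-eval --bundle run/model --data other/ --train-name mydata --out run/cross
harbox grid --bundle run-dana/model --data data/ --out run/grid \
    --rates 50,25,10,5 --masks acc,gyr,acc+gyr

# re-render a machine-readable summary as text tables
harbox report run/eval/summary.json
```

Commands accept a YAML config file (`--config`); explicit flags override
file values. Each run writes its effective configuration, a config hash,
and a log next to its outputs; equal configs produce identical outputs.

## File dialects

CSV: header `timestamp,acc_x,acc_y,acc_z,rot_roll,rot_pitch,rot_yaw[,label]`,
timestamps in seconds, acceleration in m/s², rotation rate in rad/s. The
sampling rate is estimated as the reciprocal of the median timestamp
increment (warning above 1 % jitter). JSON: either an array-per-channel
document (`{"sampling_rate": 50, "channels": {...}}`, the emitted form) or
a record-per-sample array.
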