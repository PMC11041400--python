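import io
import json
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from harbox.imu_data import (
    DEFAULT_CHANNELS,
    ActivityLabel,
    ChannelSet,
    Dataset,
    FormatError,
    LabelSpan,
    Recording,
    apply_labels,
    read_recording_csv,
    read_recording_json,
    segment_windows,
    summarize,
    write_recording_csv,
    write_recording_json,
)
from conftest import make_recording, make_window


class TestActivityLabel:
    def test_exactly_six_members_in_alphabetical_order(self):
        codes = [lab.code for lab in ActivityLabel]
        assert codes == ["dws", "jog", "sit", "std", "ups", "wlk"]
        assert codes == sorted(codes)

    def test_indices_are_stable(self):
        assert ActivityLabel.DWS.index == 0
        assert ActivityLabel.WLK.index == 5

    def test_display_names(self):
        assert ActivityLabel.JOG.display_name == "jogging"
        assert ActivityLabel.UPS.display_name == "upstairs"

    def test_from_code_rejects_unknown(self):
        with pytest.raises(ValueError, match="unknown activity"):
            ActivityLabel.from_code("run")


class TestChannelSet:
    def test_default_has_six_channels_in_order(self):
        assert DEFAULT_CHANNELS.names == (
            "acc_x", "acc_y", "acc_z", "rot_roll", "rot_pitch", "rot_yaw",
        )
        assert len(DEFAULT_CHANNELS) == 6

    def test_groups_contiguous(self):
        assert DEFAULT_CHANNELS.groups == ("accelerometer", "gyroscope")

    def test_non_contiguous_groups_rejected(self):
        with pytest.raises(ValueError, match="contiguous"):
            ChannelSet(
                names=("a", "b", "c"),
                units=("m/s^2",) * 3,
                sensor_group=("accelerometer", "gyroscope", "accelerometer"),
            )

    def test_subset_keeps_order(self):
        sub = DEFAULT_CHANNELS.subset(["gyroscope"])
        assert sub.names == ("rot_roll", "rot_pitch", "rot_yaw")


class TestReadCsv:
    def test_rate_estimated_from_median_delta(self, csv_stream):
        rows = [f"{i*0.02:.2f},1,2,3,4,5,6" for i in range(4)]
        rec = read_recording_csv(csv_stream(rows))
        assert rec.sampling_rate == pytest.approx(50.0)
        assert rec.n_samples == 4
        assert rec.samples[0, 0] == 1.0

    def test_header_only_is_an_error(self, csv_stream):
        with pytest.raises(FormatError, match="fewer than 2 samples"):
            read_recording_csv(csv_stream([]))

    def test_non_numeric_cell_cites_row(self, csv_stream):
        rows = ["0.00,1,2,3,4,5,6", "0.02,1,2,3,4,5,6", "0.04,NaNtext,2,3,4,5,6"]
        with pytest.raises(FormatError, match="row 3"):
            read_recording_csv(csv_stream(rows))

    def test_missing_column_named(self, csv_stream):
        stream = io.StringIO("timestamp,acc_x\n0.0,1\n0.02,1\n")
        with pytest.raises(FormatError, match="acc_y"):
            read_recording_csv(stream)

    def test_non_monotonic_timestamps_rejected(self, csv_stream):
        rows = ["0.00,1,2,3,4,5,6", "0.02,1,2,3,4,5,6", "0.02,1,2,3,4,5,6"]
        with pytest.raises(FormatError, match="non-monotonic"):
            read_recording_csv(csv_stream(rows))

    def test_jitter_warns(self, csv_stream):
        rows = ["0.00,1,2,3,4,5,6", "0.02,1,2,3,4,5,6", "0.06,1,2,3,4,5,6"]
        with pytest.warns(UserWarning, match="jitter"):
            read_recording_csv(csv_stream(rows))

    def test_label_column_becomes_spans(self, csv_stream):
        header = "timestamp,acc_x,acc_y,acc_z,rot_roll,rot_pitch,rot_yaw,label"
        rows = [f"{i*0.02:.2f},1,2,3,4,5,6,{'wlk' if i < 2 else 'jog'}" for i in range(4)]
        rec = read_recording_csv(csv_stream(rows, header))
        assert len(rec.label_spans) == 2
        assert rec.label_spans[0].label is ActivityLabel.WLK
        assert rec.label_spans[1].label is ActivityLabel.JOG

    def test_dialect_renames_columns(self):
        stream = io.StringIO(
            "t,ax,ay,az,gx,gy,gz\n" + "\n".join(f"{i*0.1},1,2,3,4,5,6" for i in range(3))
        )
        dialect = {
            "timestamp": "t", "acc_x": "ax", "acc_y": "ay", "acc_z": "az",
            "rot_roll": "gx", "rot_pitch": "gy", "rot_yaw": "gz",
        }
        rec = read_recording_csv(stream, dialect)
        assert rec.sampling_rate == pytest.approx(10.0)


class TestReadJson:
    def test_channel_array_dialect(self):
        doc = {
            "sampling_rate": 50,
            "channels": {n: list(range(100)) for n in DEFAULT_CHANNELS.names},
        }
        rec = read_recording_json(io.StringIO(json.dumps(doc)))
        assert rec.n_samples == 100
        assert rec.sampling_rate == 50.0

    def test_unequal_channel_lengths(self):
        doc = {
            "sampling_rate": 50,
            "channels": {n: [0.0] * 100 for n in DEFAULT_CHANNELS.names},
        }
        doc["channels"]["rot_yaw"] = [0.0] * 99
        with pytest.raises(FormatError, match="unequal channel lengths"):
            read_recording_json(io.StringIO(json.dumps(doc)))

    def test_record_per_sample_dialect(self):
        records = [
            dict({"timestamp": i * 0.02}, **{n: float(i) for n in DEFAULT_CHANNELS.names})
            for i in range(10)
        ]
        rec = read_recording_json(io.StringIO(json.dumps(records)))
        assert rec.n_samples == 10
        assert rec.sampling_rate == pytest.approx(50.0)

    def test_unknown_shape_rejected(self):
        with pytest.raises(FormatError, match="unknown JSON shape"):
            read_recording_json(io.StringIO('{"foo": 1}'))


class TestRoundTrips:
    def test_csv_round_trip_preserves_values_exactly(self, labeled_recording):
        buf = io.StringIO()
        write_recording_csv(labeled_recording, buf)
        buf.seek(0)
        back = read_recording_csv(buf, participant_id="p000")
        assert np.array_equal(back.samples, labeled_recording.samples)
        assert back.equals(labeled_recording)

    def test_json_round_trip_exact(self, labeled_recording):
        buf = io.StringIO()
        write_recording_json(labeled_recording, buf)
        buf.seek(0)
        back = read_recording_json(buf)
        assert back.equals(labeled_recording)

    def test_csv_to_json_equivalence(self, labeled_recording):
        cbuf = io.StringIO()
        write_recording_csv(labeled_recording, cbuf)
        cbuf.seek(0)
        via_csv = read_recording_csv(cbuf, participant_id="p000")
        jbuf = io.StringIO()
        write_recording_json(via_csv, jbuf)
        jbuf.seek(0)
        assert read_recording_json(jbuf).equals(via_csv)


class TestApplyLabels:
    def test_full_cover(self):
        rec = make_recording(n_samples=15000, rate=50.0).__class__(
            participant_id="p",
            sampling_rate=50.0,
            channels=DEFAULT_CHANNELS,
            samples=np.zeros((6, 15000)),
        )
        labels = list(ActivityLabel)
        spans = [LabelSpan(i * 50.0, (i + 1) * 50.0, labels[i]) for i in range(6)]
        rec = apply_labels(rec, spans)
        from harbox.imu_data import _sample_labels

        assert (_sample_labels(rec) >= 0).all()

    def test_overlap_names_both_spans(self, labeled_recording):
        spans = [
            LabelSpan(0.0, 10.0, ActivityLabel.WLK),
            LabelSpan(5.0, 15.0 if labeled_recording.duration >= 15 else 9.0, ActivityLabel.JOG),
        ]
        rec = make_recording(n_samples=1000)
        with pytest.raises(ValueError, match="overlap"):
            apply_labels(rec, spans)

    def test_out_of_range_span(self):
        rec = make_recording(n_samples=100)  # 2 s
        with pytest.raises(ValueError, match="outside"):
            apply_labels(rec, [LabelSpan(310.0, 320.0, ActivityLabel.SIT)])

    def test_span_invariant_start_before_end(self):
        with pytest.raises(ValueError, match="start"):
            LabelSpan(5.0, 5.0, ActivityLabel.SIT)


def _brute_count(L, W, S):
    """Independent window-count oracle: explicit offset enumeration."""
    count = 0
    off = 0
    while off + W <= L:
        count += 1
        off += S
    return count


class TestSegmentWindows:
    def test_paper_scale_example(self):
        rec = make_recording(n_samples=15000, rate=50.0)
        wins = segment_windows(rec, 128, 64)
        assert len(wins) == (15000 - 128) // 64 + 1 == 233

    def test_too_short_returns_empty(self):
        rec = make_recording(n_samples=100)
        assert segment_windows(rec, 128, 64) == []

    def test_bad_step_rejected(self, labeled_recording):
        with pytest.raises(ValueError, match="step"):
            segment_windows(labeled_recording, 128, 0)

    def test_step_above_window_rejected(self, labeled_recording):
        with pytest.raises(ValueError, match="step"):
            segment_windows(labeled_recording, 16, 32)

    @given(
        L=st.integers(1, 400),
        W=st.integers(1, 400),
        S=st.integers(1, 400),
    )
    @settings(max_examples=60, deadline=None)
    def test_count_matches_closed_form(self, L, W, S):
        W = min(W, L)
        S = min(S, W)
        rec = make_recording(n_samples=L)
        wins = segment_windows(rec, W, S)
        closed = (L - W) // S + 1 if L >= W else 0
        assert len(wins) == closed == _brute_count(L, W, S)

    def test_windows_are_exact_slices_of_parent(self, labeled_recording):
        for w in segment_windows(labeled_recording, 64, 32):
            sl = labeled_recording.samples[:, w.source_offset : w.source_offset + 64]
            assert np.array_equal(w.values, sl)

    def test_pure_policy_drops_boundary_window(self):
        rec = make_recording(n_samples=200)
        rec = apply_labels(
            rec,
            [LabelSpan(0.0, 2.0, ActivityLabel.WLK), LabelSpan(2.0, 4.0, ActivityLabel.JOG)],
        )
        wins = segment_windows(rec, 64, 64, "pure")
        # offset 64 straddles sample 100 (the 2 s boundary) -> dropped
        offsets = [w.source_offset for w in wins]
        assert 64 not in offsets
        assert 0 in offsets and 128 in offsets

    def test_majority_policy_labels_dominant_class(self):
        rec = make_recording(n_samples=200)
        # 70 % walk / 30 % jog inside the first window
        rec = apply_labels(
            rec,
            [
                LabelSpan(0.0, 0.9, ActivityLabel.WLK),
                LabelSpan(0.9, 4.0, ActivityLabel.JOG),
            ],
        )
        wins = segment_windows(rec, 64, 64, "majority")
        first = [w for w in wins if w.source_offset == 0][0]
        assert first.label is ActivityLabel.WLK

    def test_majority_needs_strict_majority(self):
        rec = make_recording(n_samples=128)
        rec = apply_labels(
            rec,
            [
                LabelSpan(0.0, 0.64, ActivityLabel.WLK),
                LabelSpan(0.64, 1.28, ActivityLabel.JOG),
            ],
        )
        assert segment_windows(rec, 64, 64, "majority") == []


class TestDatasetAndSummarize:
    def test_empty_dataset_all_zero(self):
        ds = Dataset([], DEFAULT_CHANNELS)
        s = summarize(ds)
        assert s["n_windows"] == 0
        assert set(s["per_class"].values()) == {0}
        assert len(s["per_class"]) == 6

    def test_counts(self):
        wlk = [make_window(np.zeros((6, 8)), ActivityLabel.WLK) for _ in range(10)]
        jog = [make_window(np.zeros((6, 8)), ActivityLabel.JOG) for _ in range(5)]
        ds = Dataset(wlk + jog, DEFAULT_CHANNELS)
        s = summarize(ds)
        assert s["per_class"]["wlk"] == 10
        assert s["per_class"]["jog"] == 5
        assert s["per_class"]["sit"] == 0
        assert s["n_windows"] == 15

    def test_shuffle_invariance(self, small_dataset):
        rng = np.random.default_rng(3)
        shuffled = Dataset(
            [small_dataset.windows[i] for i in rng.permutation(len(small_dataset))],
            small_dataset.channels,
        )
        assert summarize(shuffled)["per_class"] == summarize(small_dataset)["per_class"]

    def test_mixed_window_lengths_rejected(self):
        w1 = make_window(np.zeros((6, 8)))
        w2 = make_window(np.zeros((6, 16)))
        with pytest.raises(ValueError, match="mixed lengths"):
            Dataset([w1, w2], DEFAULT_CHANNELS)

    def test_class_counts_sum(self, small_dataset):
        assert sum(small_dataset.class_counts.values()) == len(small_dataset)

    def test_window_rejects_nan(self):
        vals = np.zeros((6, 8))
        vals[2, 3] = np.nan
        with pytest.raises(ValueError, match="missing"):
            make_window(vals)
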