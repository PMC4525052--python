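import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from plasticlsm.datasets import (
    CONST,
    InputSample,
    LabeledTimeSeries,
    SampleSet,
    VideoClip,
    generate_motion_like,
    generate_tri_function,
    generate_vowel_like,
    normalize_features,
    preprocess_motion,
    read_vowels_ascii,
    segment_series,
)


class TestTriFunction:
    def test_switch_frequency_matches_probability(self):
        """Empirical switch rate at 50k steps is within 3 SE of switch_prob."""
        p = 0.05
        series = generate_tri_function(50_000, p, seed=7)
        # a switch always lands on one of the other two generators, so label
        # changes count switch events exactly
        switches = np.sum(np.diff(series.labels) != 0)
        rate = switches / (len(series) - 1)
        se = np.sqrt(p * (1 - p) / (len(series) - 1))
        assert abs(rate - p) < 3 * se
        # mean segment length is geometric: 1/p
        seg_len = len(series) / (switches + 1)
        assert abs(seg_len - 1 / p) < 3.0

    def test_no_switching_is_one_constant_generator(self):
        series = generate_tri_function(200, 0.0, seed=12)
        assert len(np.unique(series.labels)) == 1
        if series.labels[0] == CONST:
            assert np.allclose(series.values, series.values[0])

    def test_values_normalized_and_labels_valid(self):
        series = generate_tri_function(5_000, 0.05, seed=3)
        assert len(series.values) == len(series.labels) == 5_000
        assert series.values.min() >= 0.0 and series.values.max() <= 1.0
        assert set(np.unique(series.labels)) <= {0, 1, 2}

    def test_sine_segment_is_periodic(self):
        """A switch-free sine series autocorrelates strongly at its period."""
        for seed in range(30):
            series = generate_tri_function(2_000, 0.0, seed=seed)
            if series.labels[0] == 0:  # sine
                break
        else:
            pytest.fail("no sine-initial seed found")
        x = series.values - series.values.mean()
        ac = np.array([
            np.corrcoef(x[:-lag], x[lag:])[0, 1] for lag in range(5, 60)
        ])
        best_lag = 5 + int(np.argmax(ac))
        assert ac.max() > 0.95
        assert 10 <= best_lag <= 51

    def test_seed_determinism(self):
        a = generate_tri_function(1_000, 0.05, seed=5)
        b = generate_tri_function(1_000, 0.05, seed=5)
        assert np.array_equal(a.values, b.values)
        assert np.array_equal(a.labels, b.labels)

    def test_rejects_bad_arguments(self):
        with pytest.raises(ValueError):
            generate_tri_function(0, 0.05, seed=1)
        with pytest.raises(ValueError):
            generate_tri_function(100, 1.5, seed=1)


class TestSegmentSeries:
    def test_window_count(self):
        series = generate_tri_function(100, 0.05, seed=1)
        out = segment_series(series, frames_per_sample=10)
        assert len(out) == 10
        assert all(s.n_frames == 10 and s.n_attributes == 1 for s in out.samples)

    def test_majority_label_and_tie_break(self):
        vals = np.linspace(0, 1, 10)
        series = LabeledTimeSeries(
            values=vals, labels=np.array([0, 0, 0, 1, 1, 1, 1, 2, 2, 2])
        )
        assert segment_series(series, 10).samples[0].label == 1
        # 5-5 tie between labels 2 and 0: label 2 appears first
        series = LabeledTimeSeries(
            values=vals, labels=np.array([2, 2, 0, 0, 2, 0, 2, 0, 2, 0])
        )
        assert segment_series(series, 10).samples[0].label == 2

    def test_uniform_series_gives_one_label(self):
        series = generate_tri_function(500, 0.0, seed=2)
        out = segment_series(series, 10)
        assert len(set(s.label for s in out.samples)) == 1

    def test_split_is_stratified_and_deterministic(self):
        series = generate_tri_function(20_000, 0.05, seed=4)
        out = segment_series(series, 10, split_seed=9)
        labels = out.labels
        for c in np.unique(labels):
            for part in ("train", "test"):
                assert np.any((labels == c) & (out.split == part))
        again = segment_series(series, 10, split_seed=9)
        assert np.array_equal(out.split, again.split)

    def test_too_short_series_raises(self):
        series = generate_tri_function(5, 0.05, seed=1)
        with pytest.raises(ValueError):
            segment_series(series, 10)


class TestVowelLike:
    def test_emulates_task_shape(self):
        out = generate_vowel_like(9, 40, 12, (7, 29), seed=0)
        assert len(out) == 360
        assert out.n_classes == 9
        for s in out.samples:
            assert 7 <= s.n_frames <= 29
            assert s.n_attributes == 12
            assert s.frames.min() >= 0 and s.frames.max() <= 1

    def test_zero_separation_collapses_templates(self):
        out = generate_vowel_like(
            3, 2, 4, (10, 10), class_sep=0.0, noise=0.0, seed=1
        )
        frames = [s.frames for s in out.samples]
        for f in frames[1:]:
            assert np.allclose(f, frames[0])

    def test_seed_determinism(self):
        a = generate_vowel_like(3, 5, 6, (7, 12), seed=8)
        b = generate_vowel_like(3, 5, 6, (7, 12), seed=8)
        for sa, sb in zip(a.samples, b.samples):
            assert np.array_equal(sa.frames, sb.frames) and sa.label == sb.label

    def test_rejects_negative_separation(self):
        with pytest.raises(ValueError):
            generate_vowel_like(3, 5, 6, (7, 12), class_sep=-1.0, seed=0)


class TestMotion:
    def test_clips_deterministic_and_bounded(self):
        a = generate_motion_like(6, seed=3)
        b = generate_motion_like(6, seed=3)
        for ca, cb in zip(a, b):
            assert np.array_equal(ca.frames, cb.frames)
        assert all(c.frames.min() >= 0 and c.frames.max() <= 1 for c in a)

    def test_opposite_motions_activate_different_pixels(self):
        clips = generate_motion_like(6, n_classes=6, noise=0.0, seed=5)
        masks = {}
        for c in (clips[0], clips[3]):  # directions pi apart
            sample = preprocess_motion(c, downsample_factor=0.5)
            active = sample.frames.reshape(-1, 15, 20).max(axis=0)
            ys, xs = np.nonzero(active)
            masks[c.label] = (ys.mean(), xs.mean())
        # pooled motion-mask centroids sit on opposite sides horizontally
        assert abs(masks[0][1] - masks[3][1]) > 2.0

    def test_hand_enumerated_difference_and_threshold(self):
        """3-frame toy clip checked against a direct loop over the defining
        difference/threshold equations."""
        rng = np.random.default_rng(0)
        frames = rng.uniform(size=(3, 8, 8)).round(2)
        clip = VideoClip(frames=frames, label=0)
        out = preprocess_motion(clip, downsample_factor=1.0, threshold_frac=0.2)
        # independent enumeration
        diffs = []
        for t in range(2):
            d = np.empty((8, 8))
            for i in range(8):
                for j in range(8):
                    d[i, j] = abs(frames[t + 1, i, j] - frames[t, i, j])
            diffs.append(d.reshape(-1))
        m = np.stack(diffs)
        expected = (m >= 0.2 * m.max()).astype(float)
        assert np.array_equal(out.frames, expected)

    def test_identical_frames_give_zero_columns(self):
        frames = np.tile(np.linspace(0, 1, 64).reshape(8, 8), (3, 1, 1))
        out = preprocess_motion(VideoClip(frames=frames, label=0),
                                downsample_factor=1.0)
        assert np.all(out.frames == 0)

    def test_output_is_binary_with_n_minus_1_columns(self):
        clips = generate_motion_like(3, n_frames=7, seed=2)
        for c in clips:
            out = preprocess_motion(c)
            assert out.n_frames == 6
            assert set(np.unique(out.frames)) <= {0.0, 1.0}

    def test_single_frame_clip_rejected(self):
        with pytest.raises(ValueError):
            VideoClip(frames=np.zeros((1, 8, 8)), label=0)


class TestNormalizeFeatures:
    def _set(self, columns):
        samples = [InputSample(frames=np.array(columns), label=0),
                   InputSample(frames=np.array(columns) * 0 + columns[0], label=1)]
        split = np.array(["train", "test"])
        return SampleSet(samples=samples, n_classes=2, split=split)

    def test_hand_min_max(self):
        s = SampleSet(
            samples=[InputSample(frames=[[2.0], [4.0], [6.0]], label=0)],
            n_classes=1, split=np.array(["train"]),
        )
        out = normalize_features(s)
        assert np.allclose(out.samples[0].frames.ravel(), [0.0, 0.5, 1.0])

    def test_idempotent_on_unit_range(self):
        s = SampleSet(
            samples=[InputSample(frames=[[0.0, 1.0], [1.0, 0.0]], label=0)],
            n_classes=1, split=np.array(["train"]),
        )
        out = normalize_features(s)
        assert np.allclose(out.samples[0].frames, s.samples[0].frames)

    def test_constant_attribute_maps_to_zero(self):
        s = SampleSet(
            samples=[InputSample(frames=[[3.0, 1.0], [3.0, 2.0]], label=0)],
            n_classes=1, split=np.array(["train"]),
        )
        out = normalize_features(s)
        assert np.allclose(out.samples[0].frames[:, 0], 0.0)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(seed=st.integers(0, 2**20), n=st.integers(50, 400))
def test_generators_are_seed_deterministic(seed, n):
    a = generate_tri_function(n, 0.05, seed=seed)
    b = generate_tri_function(n, 0.05, seed=seed)
    assert np.array_equal(a.values, b.values)
    assert a.values.min() >= 0.0 and a.values.max() <= 1.0


class TestIO:
    def test_sample_set_roundtrip(self, tmp_path):
        out = generate_vowel_like(2, 3, 4, (3, 5), seed=1)
        out.to_directory(tmp_path / "set")
        back = SampleSet.from_directory(tmp_path / "set")
        assert len(back) == len(out)
        for sa, sb in zip(out.samples, back.samples):
            assert np.allclose(sa.frames, sb.frames) and sa.label == sb.label
        assert list(back.split) == list(out.split)

    def test_vowels_ascii_reader(self, tmp_path):
        rng = np.random.default_rng(0)

        def write(path, n_blocks):
            lines = []
            for _ in range(n_blocks):
                for _ in range(rng.integers(2, 5)):
                    lines.append(" ".join(f"{x:.4f}" for x in rng.uniform(size=3)))
                lines.append("")
            path.write_text("\n".join(lines))

        write(tmp_path / "train.txt", 4)
        write(tmp_path / "test.txt", 6)
        out = read_vowels_ascii(
            tmp_path / "train.txt", tmp_path / "test.txt",
            train_sizes=(2, 2), test_sizes=(3, 3),
        )
        assert len(out) == 10
        assert list(out.labels[:4]) == [0, 0, 1, 1]
        assert list(out.split[:4]) == ["train"] * 4
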