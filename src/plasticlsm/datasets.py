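"""Synthetic sensory inputs for liquid-state-machine experiments.

Three families of input are generated here, each emulating one of the
temporal classification tasks the model family is usually exercised on:

* a one-dimensional *tri-function* signal — a Markov switching process that
  alternates between a sine wave of random period, a chaotic tent map and a
  random constant, with the active generator as the class label;
* *vowel-like* multivariate frame sequences — smooth class-specific feature
  templates plus noise, with variable frame counts per sample, shaped like
  cepstral-coefficient utterance data;
* *motion-like* video clips — a moving rectangle on a noisy background,
  with class-dependent trajectories, feeding the frame-differencing
  preprocessor that converts raw pixel arrays into sparse binary features.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "LabeledTimeSeries",
    "InputSample",
    "SampleSet",
    "VideoClip",
    "generate_tri_function",
    "segment_series",
    "generate_vowel_like",
    "generate_motion_like",
    "preprocess_motion",
    "normalize_features",
    "read_vowels_ascii",
]

#: generator ids for the tri-function signal
SINE, TENT, CONST = 0, 1, 2


@dataclass
class LabeledTimeSeries:
    """A one-dimensional signal with a per-step class label.

    ``values`` is the signal amplitude rescaled to [0, 1]; ``labels[i]`` is
    the id of the generator active at step ``i`` (0 sine, 1 tent map,
    2 constant).  ``generator_params`` records the drawn sine period, the
    tent-map slope and the last constant level, for reproducibility.
    """

    values: np.ndarray
    labels: np.ndarray
    generator_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.values.shape != self.labels.shape:
            raise ValueError("values and labels must have equal length")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class InputSample:
    """One unit of input: a (n_frames, n_attributes) matrix plus a label."""

    frames: np.ndarray
    label: int

    def __post_init__(self) -> None:
        self.frames = np.atleast_2d(np.asarray(self.frames, dtype=float))

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_attributes(self) -> int:
        return self.frames.shape[1]


@dataclass
class SampleSet:
    """A labelled collection of :class:`InputSample` with a train/test split.

    ``split`` holds the string ``"train"`` or ``"test"`` per sample; every
    class appears in both partitions and the assignment is a function of
    ``seed``.
    """

    samples: list
    n_classes: int
    split: np.ndarray
    seed: int | None = None

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def labels(self) -> np.ndarray:
        return np.array([s.label for s in self.samples], dtype=int)

    def subset(self, which: str) -> list:
        return [s for s, t in zip(self.samples, self.split) if t == which]

    def indices(self, which: str) -> np.ndarray:
        return np.flatnonzero(self.split == which)

    def to_directory(self, path: str | Path) -> None:
        """Serialize to per-sample CSV files plus a manifest."""
        import pandas as pd

        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        rows = []
        for i, s in enumerate(self.samples):
            fname = f"sample_{i:05d}.csv"
            np.savetxt(path / fname, s.frames, delimiter=",")
            rows.append(
                {"file": fname, "label": s.label, "split": self.split[i]}
            )
        manifest = pd.DataFrame(rows)
        manifest.attrs["seed"] = self.seed
        manifest["seed"] = self.seed
        manifest.to_csv(path / "manifest.csv", index=False)

    @classmethod
    def from_directory(cls, path: str | Path) -> "SampleSet":
        import pandas as pd

        path = Path(path)
        manifest = pd.read_csv(path / "manifest.csv")
        samples = []
        for _, row in manifest.iterrows():
            frames = np.loadtxt(path / row["file"], delimiter=",", ndmin=2)
            samples.append(InputSample(frames=frames, label=int(row["label"])))
        seed = int(manifest["seed"].iloc[0]) if "seed" in manifest else None
        return cls(
            samples=samples,
            n_classes=int(manifest["label"].nunique()),
            split=manifest["split"].to_numpy(),
            seed=seed,
        )


@dataclass
class VideoClip:
    """A sequence of 2-D pixel-intensity frames in [0, 1] with a class label."""

    frames: np.ndarray  # (n_frames, height, width)
    label: int

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be (n_frames, height, width)")
        if self.frames.shape[0] < 2:
            raise ValueError("a clip needs at least 2 frames")


def generate_tri_function(
    n_steps: int, switch_prob: float = 0.05, seed: int = 0
) -> LabeledTimeSeries:
    """Generate the switching tri-function benchmark signal.

    At every step the active generator switches, with probability
    ``switch_prob``, to one of the other two generators with fresh
    parameters.  The three generators are (0) a sine of period drawn
    uniformly from [10, 50] steps, (1) the chaotic tent map
    ``x <- 1.8 * min(x, 1 - x)`` iterated from a uniform start, and (2) a
    constant drawn uniformly from [0, 1].  The concatenated signal is
    min-max rescaled to [0, 1] globally.

    Segment lengths are geometric with mean ``1 / switch_prob``
    (about 20 steps at the default 0.05).
    """
    if n_steps < 1:
        raise ValueError(f"n_steps must be >= 1, got {n_steps}")
    if not 0 <= switch_prob < 1:
        raise ValueError(f"switch_prob must be in [0, 1), got {switch_prob}")
    rng = np.random.default_rng(seed)

    values = np.empty(n_steps)
    labels = np.empty(n_steps, dtype=int)

    gen = int(rng.integers(3))
    period = rng.uniform(10.0, 50.0)
    tent_x = rng.uniform()
    const = rng.uniform()
    phase = 0  # steps since segment start (sine argument)

    for t in range(n_steps):
        if t > 0 and rng.uniform() < switch_prob:
            gen = (gen + 1 + int(rng.integers(2))) % 3  # one of the other two
            period = rng.uniform(10.0, 50.0)
            tent_x = rng.uniform()
            const = rng.uniform()
            phase = 0
        if gen == SINE:
            values[t] = np.sin(2.0 * np.pi * phase / period)
        elif gen == TENT:
            values[t] = tent_x
            tent_x = 1.8 * min(tent_x, 1.0 - tent_x)
        else:
            values[t] = const
        labels[t] = gen
        phase += 1

    lo, hi = values.min(), values.max()
    if hi > lo:
        values = (values - lo) / (hi - lo)
    else:
        values = np.zeros_like(values)
    return LabeledTimeSeries(
        values=values,
        labels=labels,
        generator_params={
            "sine_period_range": (10.0, 50.0),
            "tent_slope": 1.8,
            "last_constant": const,
            "seed": seed,
        },
    )


def segment_series(
    series: LabeledTimeSeries,
    frames_per_sample: int = 10,
    split_seed: int = 0,
) -> SampleSet:
    """Cut a labelled signal into fixed non-overlapping window samples.

    Each window of ``frames_per_sample`` consecutive steps becomes one
    :class:`InputSample` with a single attribute per frame.  The sample label
    is the majority step label of the window, ties broken in favour of the
    label appearing earliest in the window.  Samples are then split 50/50
    into train/test, stratified per class.
    """
    if frames_per_sample < 1:
        raise ValueError("frames_per_sample must be >= 1")
    n = len(series) // frames_per_sample
    if n < 1:
        raise ValueError("series shorter than one window")

    samples = []
    for k in range(n):
        sl = slice(k * frames_per_sample, (k + 1) * frames_per_sample)
        window_vals = series.values[sl]
        window_labs = series.labels[sl]
        counts = np.bincount(window_labs, minlength=3)
        best = counts.max()
        # earliest-appearing label among those tied for the majority
        label = next(
            int(l) for l in window_labs if counts[l] == best
        )
        samples.append(
            InputSample(frames=window_vals.reshape(-1, 1), label=label)
        )
    labels = np.array([s.label for s in samples])
    split = _stratified_half_split(labels, split_seed)
    return SampleSet(
        samples=samples,
        n_classes=int(labels.max()) + 1,
        split=split,
        seed=split_seed,
    )


def _stratified_half_split(labels: np.ndarray, seed: int) -> np.ndarray:
    """Assign half of each class to train, half to test, deterministically."""
    rng = np.random.default_rng(seed)
    split = np.empty(len(labels), dtype=object)
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        rng.shuffle(idx)
        half = (len(idx) + 1) // 2
        split[idx[:half]] = "train"
        split[idx[half:]] = "test"
    return split.astype("U5")


def generate_vowel_like(
    n_classes: int = 9,
    n_per_class: int = 40,
    n_features: int = 12,
    frame_range: tuple[int, int] = (7, 29),
    class_sep: float = 1.0,
    noise: float = 0.05,
    seed: int = 0,
) -> SampleSet:
    """Generate multivariate frame sequences with class-specific templates.

    Each class has a smooth per-feature temporal template — a shared base
    curve plus a class-specific offset curve scaled by ``class_sep`` — both
    built from low-order random Fourier components.  A sample evaluates its
    class template at ``n`` uniformly spaced time points (``n`` uniform in
    ``frame_range``) and adds Gaussian noise; features are clipped to [0, 1].
    ``class_sep=0`` collapses all class templates onto the shared base, so a
    downstream classifier can do no better than chance.
    """
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    if not (1 <= frame_range[0] <= frame_range[1] <= 100):
        raise ValueError("frame_range must lie within [1, 100]")
    if class_sep < 0:
        raise ValueError("class_sep must be non-negative")
    rng = np.random.default_rng(seed)

    n_harmonics = 3
    # shared base curve and per-class offset curves, per feature
    base_amp = rng.normal(size=(n_features, n_harmonics))
    base_phase = rng.uniform(0, 2 * np.pi, size=(n_features, n_harmonics))
    cls_amp = rng.normal(size=(n_classes, n_features, n_harmonics))
    cls_phase = rng.uniform(
        0, 2 * np.pi, size=(n_classes, n_features, n_harmonics)
    )

    def template(c: int, t: np.ndarray) -> np.ndarray:
        # t in [0,1], returns (len(t), n_features)
        out = np.full((len(t), n_features), 0.5)
        for h in range(n_harmonics):
            freq = 2 * np.pi * (h + 1)
            out += (0.25 / n_harmonics) * (
                base_amp[:, h] * np.sin(freq * t[:, None] + base_phase[:, h])
            )
            out += (0.25 / n_harmonics) * class_sep * (
                cls_amp[c, :, h]
                * np.sin(freq * t[:, None] + cls_phase[c, :, h])
            )
        return out

    samples = []
    for c in range(n_classes):
        for _ in range(n_per_class):
            n = int(rng.integers(frame_range[0], frame_range[1] + 1))
            t = np.linspace(0.0, 1.0, n)
            frames = template(c, t) + rng.normal(scale=noise, size=(n, n_features))
            samples.append(
                InputSample(frames=np.clip(frames, 0.0, 1.0), label=c)
            )
    labels = np.array([s.label for s in samples])
    split = _stratified_half_split(labels, seed)
    return SampleSet(samples=samples, n_classes=n_classes, split=split, seed=seed)


def generate_motion_like(
    n_clips: int,
    n_classes: int = 6,
    resolution: tuple[int, int] = (40, 30),
    n_frames: int = 12,
    noise: float = 0.05,
    seed: int = 0,
) -> list[VideoClip]:
    """Generate video clips of a moving bright rectangle on a noisy background.

    Class ``c`` moves its rectangle along direction ``2*pi*c/n_classes``;
    clips cycle through the classes.  Pixel values are in [0, 1].
    """
    w, h = resolution
    if w < 8 or h < 8:
        raise ValueError("resolution must be at least 8x8")
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    rng = np.random.default_rng(seed)

    clips = []
    for k in range(n_clips):
        c = k % n_classes
        angle = 2 * np.pi * c / n_classes
        dx, dy = np.cos(angle), np.sin(angle)
        rw, rh = max(2, w // 8), max(2, h // 8)
        # start near the centre so the trajectory stays in frame
        x0 = w / 2 + rng.uniform(-w / 8, w / 8)
        y0 = h / 2 + rng.uniform(-h / 8, h / 8)
        step = min(w, h) / (3.0 * n_frames)
        frames = rng.uniform(0.0, noise, size=(n_frames, h, w))
        for t in range(n_frames):
            cx = int(np.clip(x0 + dx * step * t * 3, rw, w - rw - 1))
            cy = int(np.clip(y0 + dy * step * t * 3, rh, h - rh - 1))
            frames[t, cy - rh // 2 : cy + rh // 2 + 1,
                   cx - rw // 2 : cx + rw // 2 + 1] = 1.0
        clips.append(VideoClip(frames=frames, label=c))
    return clips


def _block_downsample(frame: np.ndarray, factor: int) -> np.ndarray:
    """Average non-overlapping factor x factor pixel blocks."""
    if factor <= 1:
        return frame
    h, w = frame.shape
    h2, w2 = h // factor, w // factor
    trimmed = frame[: h2 * factor, : w2 * factor]
    return trimmed.reshape(h2, factor, w2, factor).mean(axis=(1, 3))


def preprocess_motion(
    clip: VideoClip,
    downsample_factor: float = 0.2,
    threshold_frac: float = 0.2,
) -> InputSample:
    """Convert a raw clip into sparse binary motion features.

    Frames are spatially downsampled by block-averaging each axis by
    ``round(1 / downsample_factor)``, then the absolute per-pixel difference
    of consecutive frames is taken; entries at or above
    ``threshold_frac * max`` (max over the whole difference stack) become 1,
    the rest 0.  The output has ``n_frames - 1`` feature frames, one per
    consecutive pair.
    """
    if not 0 < threshold_frac < 1:
        raise ValueError("threshold_frac must be in (0, 1)")
    if clip.frames.shape[0] < 2:
        raise ValueError("clip must have at least 2 frames")
    factor = max(1, round(1.0 / downsample_factor))
    small = np.stack([_block_downsample(f, factor) for f in clip.frames])
    diffs = np.abs(np.diff(small, axis=0))  # (n_frames-1, h2, w2)
    m = diffs.reshape(diffs.shape[0], -1)
    peak = m.max()
    if peak > 0:
        binary = (m >= threshold_frac * peak).astype(float)
    else:
        binary = np.zeros_like(m)
    return InputSample(frames=binary, label=clip.label)


def normalize_features(sample_set: SampleSet) -> SampleSet:
    """Min-max normalize every attribute to [0, 1] over the whole set.

    The min and max are taken per attribute across all frames of all
    samples.  Attributes that are constant over the set map to 0.
    """
    if len(sample_set) == 0:
        raise ValueError("sample set is empty")
    stacked = np.concatenate([s.frames for s in sample_set.samples], axis=0)
    lo = stacked.min(axis=0)
    hi = stacked.max(axis=0)
    span = hi - lo
    safe = np.where(span > 0, span, 1.0)
    samples = [
        InputSample(
            frames=np.where(span > 0, (s.frames - lo) / safe, 0.0),
            label=s.label,
        )
        for s in sample_set.samples
    ]
    return SampleSet(
        samples=samples,
        n_classes=sample_set.n_classes,
        split=sample_set.split.copy(),
        seed=sample_set.seed,
    )


def read_vowels_ascii(
    train_path: str | Path,
    test_path: str | Path,
    train_sizes: tuple[int, ...] = (30,) * 9,
    test_sizes: tuple[int, ...] = (31, 35, 88, 44, 29, 24, 40, 50, 29),
) -> SampleSet:
    """Read the nine-speaker vowel utterance set in its ASCII frame format.

    Each file holds blocks of space-separated attribute rows (one row per
    audio frame), blank-line separated, one block per utterance.  Speaker
    labels are assigned from the per-speaker block counts given in
    ``train_sizes`` / ``test_sizes`` (the published ordering).
    """

    def read_blocks(path: str | Path) -> list:
        blocks, current = [], []
        for line in Path(path).read_text().splitlines():
            if line.strip():
                current.append([float(x) for x in line.split()])
            elif current:
                blocks.append(np.array(current))
                current = []
        if current:
            blocks.append(np.array(current))
        return blocks

    samples, split = [], []
    for path, sizes, tag in (
        (train_path, train_sizes, "train"),
        (test_path, test_sizes, "test"),
    ):
        blocks = read_blocks(path)
        if len(blocks) != sum(sizes):
            raise ValueError(
                f"{path}: expected {sum(sizes)} samples, found {len(blocks)}"
            )
        i = 0
        for speaker, size in enumerate(sizes):
            for _ in range(size):
                samples.append(InputSample(frames=blocks[i], label=speaker))
                split.append(tag)
                i += 1
    return SampleSet(
        samples=samples,
        n_classes=len(train_sizes),
        split=np.array(split),
        seed=None,
    )
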