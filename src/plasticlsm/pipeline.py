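"""End-to-end experiment orchestration.

An experiment runs three phases on one task/rule combination:

1. **Pre-training** — for a fixed number of iterations, a uniformly random
   training sample is presented frame-by-frame (30 ms of membrane
   simulation per frame, plasticity applied between frames), then network
   activity is reset.  Weight/ISI snapshots are captured after 1, 100 and
   1000 presentations.
2. **Collection** — the pre-trained weights become the baseline; every
   sample (train and test) is presented once with plasticity still active;
   its state vector and weight delta (weights − baseline) are recorded, and
   the weights are rolled back to the baseline before the next sample.
3. **Readout training** — one-vs-all LMS perceptrons are trained on the
   train-split state vectors and evaluated by winner-takes-all on both
   splits.

The analysis statistics (class-distance matrix, diagonal dominance,
synaptic interference) are computed from the collected deltas.  Every
stochastic choice flows from a named seed derived from the experiment seed,
so a report is fully reproducible from its configuration.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, asdict

import numpy as np

from . import _kernels, analysis, datasets, readout as readout_mod
from .datasets import SampleSet
from .network import (
    Network,
    InputProjection,
    NumericalDivergenceError,
    SpikeRecord,
    build_input_projection,
    build_network,
    isi_histogram,
)
from .plasticity import BCMState, PlasticityConfig, Rule
from .readout import StateVector, collect_state_vector, train_readouts, wta_error

__all__ = [
    "ExperimentConfig",
    "ExperimentReport",
    "SampleRunner",
    "pretrain",
    "collect_states_and_deltas",
    "run_experiment",
]

SNAPSHOT_ITERATIONS = (1, 100, 1000)


@dataclass
class ExperimentConfig:
    """Full parameterization of one experiment run.

    Defaults are the standard operating point: a 135-neuron reservoir at
    10% connectivity, 10,000 pre-training iterations, 30-ms frames with
    input scale 20, 100,000 LMS readout iterations at mu = 0.005, state
    vectors from a tau = 6 ms filter over the final 50 steps.  ``seed``
    deterministically derives the data/topology/pretrain/readout sub-seeds.
    """

    task: str = "tri_func"
    rule: Rule = Rule.NONE
    n_neurons: int = 135
    connectivity: float = 0.1
    pretrain_iterations: int = 10_000
    frame_duration_ms: int = 30
    input_scale: float = 20.0
    readout_iterations: int = 100_000
    mu: float = 0.005
    tau_filter_ms: float = 6.0
    t_window: int = 50
    seed: int = 0
    # tri-function task parameters
    n_steps: int = 50_000
    switch_prob: float = 0.05
    frames_per_sample: int = 10
    # vowel-like task parameters
    n_classes: int = 9
    n_per_class: int = 40
    n_features: int = 12
    frame_range: tuple = (7, 29)
    class_sep: float = 1.0
    # motion-like task parameters
    n_clips: int = 120
    resolution: tuple = (40, 30)
    n_video_frames: int = 12
    plasticity: PlasticityConfig | None = None

    def __post_init__(self) -> None:
        self.rule = Rule(self.rule) if not isinstance(self.rule, Rule) else self.rule
        if self.plasticity is None:
            self.plasticity = PlasticityConfig.for_rule(self.rule)
        else:
            self.plasticity.rule = self.rule

    def sub_seeds(self) -> dict:
        names = ("data", "split", "topology", "projection", "pretrain", "readout")
        state = np.random.SeedSequence(self.seed).generate_state(len(names))
        return {n: int(s % 2**31) for n, s in zip(names, state)}

    def echo(self) -> dict:
        d = asdict(self)
        d["rule"] = self.rule.value
        d["plasticity"]["rule"] = self.plasticity.rule.value
        d["seeds"] = self.sub_seeds()
        return d


@dataclass
class ExperimentReport:
    """Everything one run produces, reconstructible from config + seeds."""

    config: dict
    train_error: float
    test_error: float
    cumulative_error: float
    interference: analysis.InterferenceReport | None
    distance_matrix: analysis.DistanceMatrix | None
    diagonal_dominance: float | None
    snapshots: list
    readout_weights: np.ndarray
    runtime_s: float
    failure: str | None = None


class SampleRunner:
    """Presents samples through the compiled simulation kernel.

    Owns the scratch buffers and the running plasticity state; one instance
    per (network, projection, rule) with state persisting across phases.
    """

    def __init__(
        self,
        network: Network,
        projection: InputProjection,
        config: PlasticityConfig,
        frame_duration: int = 30,
    ):
        self.network = network
        self.projection = projection
        self.config = config
        self.frame_duration = frame_duration
        self.bcm = BCMState.zeros(network.n_neurons)
        n = network.n_neurons
        self._spike_cap = 0
        self._spike_n = np.empty(0, dtype=np.int64)
        self._spike_t = np.empty(0, dtype=np.int64)
        self._used_a = np.zeros(frame_duration, dtype=np.bool_)
        self._used_b = np.zeros(frame_duration, dtype=np.bool_)
        self._delta_scratch = np.zeros(len(network.synapses))
        self._err = np.zeros(1, dtype=np.int64)

    def present(self, frames: np.ndarray) -> SpikeRecord:
        """Present one sample (all frames); returns its spike record."""
        frames = np.atleast_2d(np.asarray(frames, dtype=float))
        n_frames = frames.shape[0]
        duration = n_frames * self.frame_duration
        cap = duration * self.network.n_neurons
        if cap > self._spike_cap:
            self._spike_cap = cap
            self._spike_n = np.empty(cap, dtype=np.int64)
            self._spike_t = np.empty(cap, dtype=np.int64)
        net = self.network
        arr = net.kernel_arrays()
        cfg = self.config
        n_spikes = _kernels.simulate_sample(
            arr["v"], arr["u"], arr["a_arr"], arr["b_arr"], arr["c_arr"],
            arr["d_arr"], arr["i_inj"], arr["i_rec"],
            arr["pre"], arr["post"], arr["w"], arr["w_lo"], arr["w_hi"],
            arr["out_off"], arr["out_syn"],
            self.projection.attribute, self.projection.target,
            self.projection.weight, self.projection.scale,
            frames, self.frame_duration,
            cfg.rule.code, cfg.A_plus, cfg.A_minus,
            cfg.tau_plus, cfg.tau_minus, cfg.eps_w, cfg.theta_decay,
            self.bcm.theta, self.bcm.vmin, self.bcm.vmax, self.bcm.xmax,
            self._spike_n, self._spike_t, 0,
            self._used_a, self._used_b, self._delta_scratch, self._err,
        )
        if n_spikes < 0:
            raise NumericalDivergenceError(
                f"membrane potential diverged at neuron {self._err[0]}"
            )
        return SpikeRecord(
            neurons=self._spike_n[:n_spikes].copy(),
            times=self._spike_t[:n_spikes].copy(),
            n_neurons=net.n_neurons,
            duration=duration,
        )


def pretrain(
    network: Network,
    sample_set: SampleSet,
    config: ExperimentConfig,
    runner: SampleRunner | None = None,
    snapshot_at: tuple = SNAPSHOT_ITERATIONS,
) -> tuple[SampleRunner, list]:
    """Phase 1: adapt recurrent weights on random training samples.

    Returns the runner (whose plasticity state carries into collection) and
    the list of weight/ISI snapshots.
    """
    seeds = config.sub_seeds()
    if runner is None:
        projection = build_input_projection(
            _n_attributes(sample_set), network.n_neurons,
            seed=seeds["projection"], scale=config.input_scale,
            dense=config.task != "motion_like",
        )
        runner = SampleRunner(
            network, projection, config.plasticity, config.frame_duration_ms
        )
    train_samples = sample_set.subset("train")
    rng = np.random.default_rng(seeds["pretrain"])
    snapshots = []
    for it in range(1, config.pretrain_iterations + 1):
        sample = train_samples[rng.integers(len(train_samples))]
        try:
            record = runner.present(sample.frames)
        except NumericalDivergenceError as exc:
            raise NumericalDivergenceError(
                f"pre-training iteration {it}: {exc}"
            ) from exc
        network.reset_activity()
        if it in snapshot_at:
            snap = analysis.weight_snapshot(network, at_iteration=it)
            snap["isi"] = isi_histogram(record)
            snapshots.append(snap)
    return runner, snapshots


def collect_states_and_deltas(
    network: Network,
    sample_set: SampleSet,
    config: ExperimentConfig,
    runner: SampleRunner,
) -> tuple[list, list]:
    """Phase 2: per-sample state vectors and baseline-relative weight deltas.

    Plasticity stays active but each sample's weight change is rolled back
    to the stored baseline before the next presentation, so every delta is
    measured against the same pre-trained weights and the network leaves
    this phase bit-identical to how it entered.
    """
    baseline = network.weights.copy()
    states: list[StateVector] = []
    deltas: list[analysis.WeightDelta] = []
    for sample, split in zip(sample_set.samples, sample_set.split):
        record = runner.present(sample.frames)
        sv = collect_state_vector(
            record, label=sample.label,
            tau=config.tau_filter_ms, window=config.t_window,
        )
        states.append(sv)
        deltas.append(
            analysis.WeightDelta(
                delta=network.weights - baseline,
                label=sample.label,
                split=str(split),
            )
        )
        network.weights[:] = baseline
        network.reset_activity()
    return states, deltas


def make_task_data(config: ExperimentConfig) -> SampleSet:
    """Generate the configured task's sample set from the data seed."""
    seeds = config.sub_seeds()
    if config.task == "tri_func":
        series = datasets.generate_tri_function(
            config.n_steps, config.switch_prob, seed=seeds["data"]
        )
        return datasets.segment_series(
            series, config.frames_per_sample, split_seed=seeds["split"]
        )
    if config.task == "vowel_like":
        return datasets.generate_vowel_like(
            n_classes=config.n_classes, n_per_class=config.n_per_class,
            n_features=config.n_features, frame_range=tuple(config.frame_range),
            class_sep=config.class_sep, seed=seeds["data"],
        )
    if config.task == "motion_like":
        clips = datasets.generate_motion_like(
            config.n_clips, n_classes=6,
            resolution=tuple(config.resolution),
            n_frames=config.n_video_frames, seed=seeds["data"],
        )
        samples = [datasets.preprocess_motion(c) for c in clips]
        labels = np.array([s.label for s in samples])
        split = datasets._stratified_half_split(labels, seeds["split"])
        return SampleSet(
            samples=samples, n_classes=int(labels.max()) + 1,
            split=split, seed=seeds["split"],
        )
    raise ValueError(f"unknown task {config.task!r}")


def _n_attributes(sample_set: SampleSet) -> int:
    return sample_set.samples[0].n_attributes


def run_experiment(config: ExperimentConfig) -> ExperimentReport:
    """Run all three phases plus the analyses for one configuration."""
    t0 = time.perf_counter()
    seeds = config.sub_seeds()
    sample_set = make_task_data(config)
    network = build_network(
        config.n_neurons, config.connectivity, seed=seeds["topology"]
    )
    projection = build_input_projection(
        _n_attributes(sample_set), config.n_neurons,
        seed=seeds["projection"], scale=config.input_scale,
        dense=config.task != "motion_like",
    )
    runner = SampleRunner(
        network, projection, config.plasticity, config.frame_duration_ms
    )

    failure = None
    snapshots: list = []
    try:
        if config.rule is not Rule.NONE and config.pretrain_iterations > 0:
            _, snapshots = pretrain(
                network, sample_set, config, runner=runner
            )
        states, deltas = collect_states_and_deltas(
            network, sample_set, config, runner
        )
    except NumericalDivergenceError as exc:
        return ExperimentReport(
            config=config.echo(), train_error=np.nan, test_error=np.nan,
            cumulative_error=np.nan, interference=None, distance_matrix=None,
            diagonal_dominance=None, snapshots=snapshots,
            readout_weights=np.empty(0),
            runtime_s=time.perf_counter() - t0, failure=str(exc),
        )

    train_idx = sample_set.indices("train")
    test_idx = sample_set.indices("test")
    train_states = [states[i] for i in train_idx]
    test_states = [states[i] for i in test_idx]

    readouts, training = train_readouts(
        train_states,
        n_classes=sample_set.n_classes,
        n_iterations=config.readout_iterations,
        mu=config.mu,
        seed=seeds["readout"],
    )
    test_error = wta_error(readouts, test_states)

    if config.rule is not Rule.NONE:
        interference = analysis.interference_report(deltas)
        means_x = analysis.class_mean_delta(deltas, split="train")
        means_y = analysis.class_mean_delta(deltas, split="test")
        dm = analysis.class_distance_matrix(means_x, means_y)
        dd = analysis.diagonal_dominance(dm)
    else:
        interference, dm, dd = None, None, None

    return ExperimentReport(
        config=config.echo(),
        train_error=training.final_train_error,
        test_error=test_error,
        cumulative_error=float(training.cumulative_error[-1]),
        interference=interference,
        distance_matrix=dm,
        diagonal_dominance=dd,
        snapshots=snapshots,
        readout_weights=readouts.weights,
        runtime_s=time.perf_counter() - t0,
        failure=failure,
    )
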