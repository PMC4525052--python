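"""Linear readouts: spike-train filtering, LMS training, winner-takes-all.

A sample's reservoir response is summarized as a *state vector*: each
neuron's binary spike train over the final ``window`` (default 50) steps of
the sample is run through a decaying-exponential trace
``r(t) = r(t-1) exp(-1/tau) + spike(t)`` (tau = 6 ms) and the maximum of the
trace is taken, capturing the strongest burst rather than a mean rate.

One perceptron readout per class maps state vectors to a scalar by a plain
dot product (no bias).  Readouts are trained by least-mean-squares:
``w_i <- w_i + mu (y_d - y_o) x_i`` with mu = 0.005, the matching-class
readout driven toward 1 and all others toward 0, on uniformly random draws
from the training states.  Classification takes the argmax over readouts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .network import SpikeRecord

__all__ = [
    "StateVector",
    "ReadoutSet",
    "TrainingReport",
    "filter_state",
    "collect_state_vector",
    "readout_output",
    "lms_update",
    "train_readouts",
    "classify_wta",
    "wta_error",
]

DEFAULT_TAU_MS = 6.0
DEFAULT_WINDOW = 50
DEFAULT_MU = 0.005


@dataclass
class StateVector:
    """Filtered per-neuron activations for one sample, plus its class label."""

    values: np.ndarray
    label: int


@dataclass
class ReadoutSet:
    """One trained readout weight row per class."""

    weights: np.ndarray  # (n_classes, n_neurons)
    mu: float = DEFAULT_MU

    @property
    def n_classes(self) -> int:
        return self.weights.shape[0]


@dataclass
class TrainingReport:
    """Cumulative training error trace and final train/test WTA error."""

    cumulative_error: np.ndarray
    final_train_error: float
    test_error: float | None = None

    def summary(self) -> str:
        lines = [
            f"iterations:        {len(self.cumulative_error)}",
            f"cumulative error:  {self.cumulative_error[-1]:.4f}",
            f"final train error: {self.final_train_error:.4f}",
        ]
        if self.test_error is not None:
            lines.append(f"test error:        {self.test_error:.4f}")
        return "\n".join(lines)


def filter_state(
    spike_steps: np.ndarray,
    tau: float = DEFAULT_TAU_MS,
    window: int = DEFAULT_WINDOW,
) -> float:
    """Max of the decaying-exponential trace of one spike train.

    ``spike_steps`` are firing step indices within the window
    (0 <= step < window).  Returns 0 for an empty train; a single spike
    yields 1 (the trace peak); spikes at consecutive steps accumulate as
    ``1 + exp(-1/tau) + ...``.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    if window < 1:
        raise ValueError("window must be >= 1")
    spikes = np.zeros(window)
    steps = np.asarray(spike_steps, dtype=int)
    if steps.size:
        spikes[steps] = 1.0
    decay = np.exp(-1.0 / tau)
    r = 0.0
    peak = 0.0
    for t in range(window):
        r = r * decay + spikes[t]
        if r > peak:
            peak = r
    return peak


def collect_state_vector(
    record: SpikeRecord,
    label: int = -1,
    tau: float = DEFAULT_TAU_MS,
    window: int = DEFAULT_WINDOW,
) -> StateVector:
    """Filter the final ``window`` steps of a sample's spike record, per neuron.

    Records shorter than the window are left-padded with silence.
    """
    t0 = max(0, record.duration - window)
    raster = record.binary_matrix(t0, record.duration)  # (n_neurons, <=window)
    if raster.shape[1] < window:
        pad = np.zeros((record.n_neurons, window - raster.shape[1]))
        raster = np.hstack([pad, raster])
    decay = np.exp(-1.0 / tau)
    trace = np.zeros(record.n_neurons)
    peak = np.zeros(record.n_neurons)
    for t in range(window):
        trace = trace * decay + raster[:, t]
        peak = np.maximum(peak, trace)
    return StateVector(values=peak, label=label)


def readout_output(sv: np.ndarray | StateVector, weights: np.ndarray) -> float:
    """Linear readout output: dot product of state and weights, no bias."""
    x = sv.values if isinstance(sv, StateVector) else np.asarray(sv, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if x.shape != weights.shape:
        raise ValueError(
            f"dimension mismatch: state {x.shape} vs weights {weights.shape}"
        )
    return float(x @ weights)


def lms_update(
    weights: np.ndarray,
    sv: np.ndarray | StateVector,
    y_desired: float,
    y_actual: float,
    mu: float = DEFAULT_MU,
) -> np.ndarray:
    """One LMS step: ``w_i + mu (y_d - y_o) x_i`` (returns the new row)."""
    if mu <= 0:
        raise ValueError("mu must be positive")
    x = sv.values if isinstance(sv, StateVector) else np.asarray(sv, dtype=float)
    return weights + mu * (y_desired - y_actual) * x


def train_readouts(
    states: list,
    n_classes: int | None = None,
    n_iterations: int = 100_000,
    mu: float = DEFAULT_MU,
    seed: int = 0,
) -> tuple[ReadoutSet, TrainingReport]:
    """Train one-vs-all readouts by LMS on random draws from ``states``.

    Every class in ``range(n_classes)`` must be present.  The cumulative
    winner-takes-all error over the training run is tracked; the final
    training error is the WTA error of the trained readouts over all of
    ``states``.
    """
    X = np.stack([s.values for s in states])
    labels = np.array([s.label for s in states], dtype=np.int64)
    if n_classes is None:
        n_classes = int(labels.max()) + 1
    present = np.unique(labels)
    missing = sorted(set(range(n_classes)) - set(present.tolist()))
    if missing:
        raise ValueError(f"classes missing from training states: {missing}")

    rng = np.random.default_rng(seed)
    draws = rng.integers(0, len(states), size=n_iterations)
    weights = np.zeros((n_classes, X.shape[1]))
    cum = np.zeros(n_iterations)
    _kernels.lms_train(weights, X, labels, draws, mu, cum)
    readouts = ReadoutSet(weights=weights, mu=mu)

    preds = np.array([classify_wta(readouts, x) for x in X])
    train_err = float(np.mean(preds != labels))
    report = TrainingReport(
        cumulative_error=cum, final_train_error=train_err
    )
    return readouts, report


def classify_wta(readouts: ReadoutSet, sv: np.ndarray | StateVector) -> int:
    """Winner-takes-all class: argmax readout output, ties to lowest index."""
    x = sv.values if isinstance(sv, StateVector) else np.asarray(sv, dtype=float)
    return int(np.argmax(readouts.weights @ x))


def wta_error(readouts: ReadoutSet, states: list) -> float:
    """Misclassification fraction of WTA predictions over ``states``."""
    preds = np.array([classify_wta(readouts, s) for s in states])
    labels = np.array([s.label for s in states])
    return float(np.mean(preds != labels))
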