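"""Class-specific weight-adaptation distances and synaptic interference.

Both statistics start from per-sample *weight deltas*: the change in the
full synapse weight vector caused by presenting one sample against a fixed
baseline (the sample's adaptation is rolled back before the next sample, so
deltas are independent).

**Class-distance matrix.**  Samples are divided into two sets (train/test);
per-class mean deltas are formed in each; entry (a, b) of the matrix is the
sum of absolute differences between class a's mean delta in one set and
class b's in the other:

    Dist(a, b) = sum_i |dW_i(a, X) - dW_i(b, Y)|

Low diagonal entries mean the plasticity-driven adaptation is reproducibly
class-specific.  ``diagonal_dominance`` quantifies that: the fraction of
classes whose diagonal entry is their row minimum.

**Interference.**  For class t, with dW_t its mean delta and dW_o the
unweighted mean of the other classes' mean deltas, the per-class
interference is the fraction of synapses whose class-t adaptation both
opposes the others in sign *and* is smaller in magnitude than the
other-class average scaled by the class count C_n:

    I_t = (1/N) sum_i [dW_t,i * dW_o,i < 0] [|dW_t,i| < |dW_o,i| * C_n]

and the total interference is the mean of I_t over classes.  Both brackets
are required, making this a conservative count of adaptations that other
classes actively overwrite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import Network

__all__ = [
    "WeightDelta",
    "ClassMeanDelta",
    "DistanceMatrix",
    "InterferenceReport",
    "class_mean_delta",
    "class_distance_matrix",
    "diagonal_dominance",
    "interference_per_class",
    "interference_total",
    "interference_report",
    "weight_snapshot",
]


@dataclass
class WeightDelta:
    """Per-synapse weight change from one sample presentation."""

    delta: np.ndarray
    label: int
    split: str = "train"

    def __post_init__(self) -> None:
        self.delta = np.asarray(self.delta, dtype=float)
        if not np.all(np.isfinite(self.delta)):
            raise ValueError("weight delta contains non-finite entries")


@dataclass
class ClassMeanDelta:
    """Per-class mean weight deltas for one sample set."""

    means: np.ndarray  # (n_classes, n_synapses)
    n_samples: np.ndarray  # per class
    classes: np.ndarray

    @property
    def n_classes(self) -> int:
        return self.means.shape[0]


@dataclass
class DistanceMatrix:
    """Class x class inter-set distances between mean weight adaptations."""

    dist: np.ndarray
    classes: np.ndarray

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(self.dist, index=self.classes, columns=self.classes).to_csv(path)


@dataclass
class InterferenceReport:
    """Per-class and total synaptic interference, each in [0, 1]."""

    per_class: np.ndarray
    total: float
    n_classes: int

    def to_csv(self, path) -> None:
        import pandas as pd

        df = pd.DataFrame(
            {"class": list(range(self.n_classes)) + ["total"],
             "interference": list(self.per_class) + [self.total]}
        )
        df.to_csv(path, index=False)


def class_mean_delta(
    deltas: list, split: str | None = None
) -> ClassMeanDelta:
    """Arithmetic mean delta per class over one split's samples.

    ``split=None`` pools all samples.  Every class present anywhere in
    ``deltas`` must have at least one sample in the selected split.
    """
    selected = [d for d in deltas if split is None or d.split == split]
    all_classes = np.unique([d.label for d in deltas])
    n_syn = len(deltas[0].delta)
    means = np.zeros((len(all_classes), n_syn))
    counts = np.zeros(len(all_classes), dtype=int)
    for d in selected:
        idx = int(np.searchsorted(all_classes, d.label))
        means[idx] += d.delta
        counts[idx] += 1
    empty = all_classes[counts == 0]
    if len(empty):
        raise ValueError(
            f"no samples for class(es) {empty.tolist()} in split {split!r}"
        )
    means /= counts[:, None]
    return ClassMeanDelta(means=means, n_samples=counts, classes=all_classes)


def class_distance_matrix(
    means_x: ClassMeanDelta,
    means_y: ClassMeanDelta,
    metric: str = "l1",
) -> DistanceMatrix:
    """Inter-set class distance matrix over mean weight adaptations.

    The default is the sum of absolute coordinate differences; ``metric="l2"``
    gives the Euclidean variant for sensitivity checks.
    """
    if means_x.means.shape != means_y.means.shape or not np.array_equal(
        means_x.classes, means_y.classes
    ):
        raise ValueError("mismatched class sets or synapse counts")
    diff = means_x.means[:, None, :] - means_y.means[None, :, :]
    if metric == "l1":
        dist = np.abs(diff).sum(axis=2)
    elif metric == "l2":
        dist = np.sqrt((diff**2).sum(axis=2))
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return DistanceMatrix(dist=dist, classes=means_x.classes.copy())


def diagonal_dominance(dm: DistanceMatrix | np.ndarray) -> float:
    """Fraction of classes whose diagonal entry is their row minimum.

    Ties count as dominant.  1.0 means every class's adaptation is closer
    to itself across the two sets than to any other class.
    """
    dist = dm.dist if isinstance(dm, DistanceMatrix) else np.asarray(dm, dtype=float)
    if dist.ndim != 2 or dist.shape[0] != dist.shape[1]:
        raise ValueError("distance matrix must be square")
    diag = np.diagonal(dist)
    return float(np.mean(diag <= dist.min(axis=1)))


def interference_per_class(
    mean_this: np.ndarray, mean_others: np.ndarray, n_classes: int
) -> float:
    """Fraction of synapses where other classes overwrite this class's change.

    Counts synapses whose adaptation opposes the other-class average in sign
    and is smaller in magnitude than that average scaled by ``n_classes``.
    """
    mean_this = np.asarray(mean_this, dtype=float)
    mean_others = np.asarray(mean_others, dtype=float)
    if mean_this.shape != mean_others.shape:
        raise ValueError("mean delta vectors must have equal length")
    if mean_this.size == 0:
        raise ValueError("no synapses")
    if n_classes < 2:
        raise ValueError("need at least 2 classes")
    opposed = mean_this * mean_others < 0
    overwhelmed = np.abs(mean_this) < np.abs(mean_others) * n_classes
    return float(np.mean(opposed & overwhelmed))


def interference_total(per_class: np.ndarray) -> float:
    """Mean per-class interference."""
    per_class = np.asarray(per_class, dtype=float)
    if per_class.size < 2:
        raise ValueError("need at least 2 classes")
    return float(per_class.mean())


def interference_report(deltas: list) -> InterferenceReport:
    """Full interference computation from a collection of weight deltas.

    Pools all samples (both splits), forms per-class mean deltas, and for
    each class compares it against the unweighted mean of the other classes'
    means.
    """
    cmd = class_mean_delta(deltas, split=None)
    n_classes = cmd.n_classes
    per_class = np.empty(n_classes)
    for t in range(n_classes):
        others = np.delete(cmd.means, t, axis=0).mean(axis=0)
        per_class[t] = interference_per_class(cmd.means[t], others, n_classes)
    return InterferenceReport(
        per_class=per_class,
        total=interference_total(per_class),
        n_classes=n_classes,
    )


def weight_snapshot(
    network: Network | np.ndarray,
    at_iteration: int = 0,
    n_bins: int = 80,
    bound_tol: float = 0.5,
) -> dict:
    """Histogram of current weights plus bound-occupancy fractions.

    ``frac_zero`` / ``frac_max`` / ``frac_min`` are the shares of synapses
    within ``bound_tol`` of 0, +10 and -10 respectively.
    """
    w = network.weights if isinstance(network, Network) else np.asarray(network)
    counts, edges = np.histogram(w, bins=n_bins, range=(-10.5, 10.5))
    return {
        "iteration": at_iteration,
        "counts": counts,
        "bin_edges": edges,
        "weights": w.copy(),
        "frac_zero": float(np.mean(np.abs(w) <= bound_tol)),
        "frac_max": float(np.mean(np.abs(w - 10.0) <= bound_tol)),
        "frac_min": float(np.mean(np.abs(w + 10.0) <= bound_tol)),
        "mean": float(w.mean()),
        "n_synapses": int(w.size),
    }
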