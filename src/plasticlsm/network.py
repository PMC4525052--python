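"""Recurrent spiking network construction and membrane simulation.

The circuit is a sparse random recurrent network of quadratic
integrate-and-fire neurons (the two-variable membrane model with
``v' = 0.04 v^2 + 5 v + 140 - u + I`` and recovery ``u' = a (b v - u)``,
spike emitted and reset applied when v exceeds 30 mV).  Excitatory and
inhibitory neurons are mixed 4:1; synapses are drawn with uniformly random
endpoints (self-connections and duplicates permitted) and Gaussian initial
weights, N(6, 0.5) excitatory and N(-5, 0.5) inhibitory, clamped to
[-10, 10] whenever plasticity acts on them.  Recurrent transmission is a
delta-impulse current delivered one 1-ms step after the presynaptic spike.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels

__all__ = [
    "NeuronParams",
    "EXCITATORY",
    "INHIBITORY",
    "SynapseTable",
    "InputProjection",
    "SpikeRecord",
    "Network",
    "NumericalDivergenceError",
    "build_network",
    "build_input_projection",
    "isi_histogram",
]

SPIKE_THRESHOLD_MV = 30.0
W_MAX = 10.0
W_MIN = -10.0


class NumericalDivergenceError(RuntimeError):
    """Raised when a neuron's membrane state leaves the finite range."""


@dataclass(frozen=True)
class NeuronParams:
    """Membrane parameters (a: recovery rate 1/ms, b: sensitivity,
    c: reset potential mV, d: reset recovery increment)."""

    a: float
    b: float
    c: float
    d: float
    is_excitatory: bool


#: regular-spiking excitatory cell
EXCITATORY = NeuronParams(a=0.2, b=0.2, c=-65.0, d=8.0, is_excitatory=True)
#: fast inhibitory cell
INHIBITORY = NeuronParams(a=0.1, b=0.2, c=-65.0, d=2.0, is_excitatory=False)


@dataclass
class SynapseTable:
    """Flat synapse arrays: endpoints, weights and per-synapse clamp bounds.

    Excitatory synapses clamp to [0, 10] and inhibitory to [-10, 0], so a
    synapse keeps its sign under plasticity (Dale's principle).
    """

    pre: np.ndarray
    post: np.ndarray
    weight: np.ndarray
    is_excitatory: np.ndarray

    def __len__(self) -> int:
        return len(self.weight)

    @property
    def w_lo(self) -> np.ndarray:
        return np.where(self.is_excitatory, 0.0, W_MIN)

    @property
    def w_hi(self) -> np.ndarray:
        return np.where(self.is_excitatory, W_MAX, 0.0)


@dataclass
class InputProjection:
    """Random projection of input attributes onto reservoir neurons.

    Each connection injects ``weight * attribute * scale`` as current for
    the duration of a frame.  For dense tasks each attribute gets
    ``round(0.2 * n_neurons)`` connections; very high-dimensional inputs
    (e.g. pixel features) use one connection per attribute with weights
    scaled down by 0.25.
    """

    attribute: np.ndarray  # attribute index per connection
    target: np.ndarray  # neuron index per connection
    weight: np.ndarray
    scale: float = 20.0


@dataclass
class SpikeRecord:
    """Spike events as parallel (neuron, time_ms) arrays over ``duration`` steps."""

    neurons: np.ndarray
    times: np.ndarray
    n_neurons: int
    duration: int

    def per_neuron(self) -> list:
        """Firing times per neuron, each strictly increasing."""
        return [self.times[self.neurons == k] for k in range(self.n_neurons)]

    def binary_matrix(self, t0: int = 0, t1: int | None = None) -> np.ndarray:
        """(n_neurons, t1 - t0) 0/1 spike raster for a time slice."""
        if t1 is None:
            t1 = self.duration
        mat = np.zeros((self.n_neurons, t1 - t0))
        mask = (self.times >= t0) & (self.times < t1)
        mat[self.neurons[mask], self.times[mask] - t0] = 1.0
        return mat

    def to_event_list(self, path) -> None:
        np.savetxt(path, np.column_stack([self.neurons, self.times]),
                   fmt="%d", header="neuron_id time_ms")


class Network:
    """A recurrent spiking reservoir: topology plus per-neuron dynamic state."""

    def __init__(self, params: list, synapses: SynapseTable):
        self.n_neurons = len(params)
        self.params = params
        self.synapses = synapses
        self.a = np.array([p.a for p in params])
        self.b = np.array([p.b for p in params])
        self.c = np.array([p.c for p in params])
        self.d = np.array([p.d for p in params])
        self.is_excitatory = np.array([p.is_excitatory for p in params])
        # CSR-style adjacency over presynaptic neuron for spike delivery
        order = np.argsort(synapses.pre, kind="stable")
        self._out_syn = order.astype(np.int64)
        counts = np.bincount(synapses.pre, minlength=self.n_neurons)
        self._out_off = np.concatenate([[0], np.cumsum(counts)]).astype(np.int64)
        self._syn_lo = synapses.w_lo.copy()
        self._syn_hi = synapses.w_hi.copy()
        self.v = np.empty(self.n_neurons)
        self.u = np.empty(self.n_neurons)
        self.i_inj = np.zeros(self.n_neurons)
        self.i_rec = np.zeros(self.n_neurons)
        self.reset_activity()

    # -- state management ---------------------------------------------------

    def reset_activity(self) -> None:
        """Return membranes to rest (v <- c, u <- b*v) and clear all currents.

        Synaptic weights are untouched.
        """
        self.v[:] = self.c
        self.u[:] = self.b * self.c
        self.i_inj[:] = 0.0
        self.i_rec[:] = 0.0

    @property
    def weights(self) -> np.ndarray:
        return self.synapses.weight

    # -- simulation ---------------------------------------------------------

    def inject_frame(self, frame: np.ndarray, projection: InputProjection) -> None:
        """Set the injected current for one frame of input.

        Each input connection contributes ``weight * value * scale`` to its
        target neuron's summed input current, which persists for the frame.
        """
        frame = np.asarray(frame, dtype=float)
        n_attr = int(projection.attribute.max()) + 1 if len(projection.attribute) else 0
        if frame.shape[0] < n_attr:
            raise ValueError(
                f"frame has {frame.shape[0]} attributes, projection expects {n_attr}"
            )
        self.i_inj[:] = 0.0
        np.add.at(
            self.i_inj,
            projection.target,
            projection.weight * frame[projection.attribute] * projection.scale,
        )

    def step_membrane(self, dt: float = 1.0) -> np.ndarray:
        """Advance every membrane one Euler step; return boolean spike flags.

        The membrane is updated before the spike test; spiking neurons reset
        (v <- c, u <- u + d) and their outgoing weights are delivered as
        recurrent current on the *next* step.
        """
        cur = self.i_inj + self.i_rec
        v_new = self.v + dt * (
            0.04 * self.v**2 + 5.0 * self.v + 140.0 - self.u + cur
        )
        u_new = self.u + dt * self.a * (self.b * self.v - self.u)
        bad = ~np.isfinite(v_new) | (np.abs(v_new) > 1e8)
        if bad.any():
            k = int(np.flatnonzero(bad)[0])
            raise NumericalDivergenceError(
                f"membrane potential diverged at neuron {k}"
            )
        spikes = v_new > SPIKE_THRESHOLD_MV
        self.v = np.where(spikes, self.c, v_new)
        self.u = np.where(spikes, u_new + self.d, u_new)
        self.i_rec[:] = 0.0
        if spikes.any():
            syn = self.synapses
            for k in np.flatnonzero(spikes):
                sl = self._out_syn[self._out_off[k] : self._out_off[k + 1]]
                np.add.at(self.i_rec, syn.post[sl], syn.weight[sl])
        return spikes

    def simulate_frame(
        self,
        frame: np.ndarray,
        projection: InputProjection,
        duration: int = 30,
    ) -> SpikeRecord:
        """Inject one frame and advance ``duration`` 1-ms steps.

        Returns the spike fragment for the frame (times relative to frame
        start).  This is the plain-Python path used for small simulations
        and testing; the pipeline uses the compiled kernel, which this must
        agree with.
        """
        if duration < 1:
            raise ValueError("duration must be >= 1 ms")
        self.inject_frame(frame, projection)
        ns, ts = [], []
        for t in range(duration):
            flags = self.step_membrane()
            for k in np.flatnonzero(flags):
                ns.append(int(k))
                ts.append(t)
        return SpikeRecord(
            neurons=np.array(ns, dtype=int),
            times=np.array(ts, dtype=int),
            n_neurons=self.n_neurons,
            duration=duration,
        )

    # -- kernel plumbing ----------------------------------------------------

    def kernel_arrays(self) -> dict:
        """Arrays shared with the compiled simulation kernel (views, not copies)."""
        syn = self.synapses
        return dict(
            v=self.v, u=self.u, a_arr=self.a, b_arr=self.b,
            c_arr=self.c, d_arr=self.d,
            i_inj=self.i_inj, i_rec=self.i_rec,
            pre=syn.pre, post=syn.post, w=syn.weight,
            w_lo=self._syn_lo, w_hi=self._syn_hi,
            out_off=self._out_off, out_syn=self._out_syn,
        )


def build_network(
    n_neurons: int, connectivity: float = 0.1, seed: int = 0
) -> Network:
    """Build a random reservoir with ``floor(N^2 * C)`` synapses.

    Neuron types are assigned 4:1 excitatory:inhibitory (round(0.8*N)
    excitatory); synapse endpoints are uniform random (self-connections and
    duplicates permitted); weights are N(6, 0.5) for excitatory and
    N(-5, 0.5) for inhibitory presynaptic neurons.
    """
    if n_neurons < 2:
        raise ValueError("n_neurons must be >= 2")
    if not 0 < connectivity <= 1:
        raise ValueError("connectivity must be in (0, 1]")
    rng = np.random.default_rng(seed)

    n_exc = round(0.8 * n_neurons)
    types = np.array([True] * n_exc + [False] * (n_neurons - n_exc))
    rng.shuffle(types)
    params = [EXCITATORY if t else INHIBITORY for t in types]

    n_syn = int(np.floor(n_neurons**2 * connectivity))
    pre = rng.integers(0, n_neurons, size=n_syn).astype(np.int64)
    post = rng.integers(0, n_neurons, size=n_syn).astype(np.int64)
    exc_syn = types[pre]
    weight = np.where(
        exc_syn,
        rng.normal(6.0, 0.5, size=n_syn),
        rng.normal(-5.0, 0.5, size=n_syn),
    )
    table = SynapseTable(
        pre=pre, post=post, weight=weight, is_excitatory=exc_syn
    )
    return Network(params=params, synapses=table)


def build_input_projection(
    n_attributes: int,
    n_neurons: int,
    seed: int = 0,
    scale: float = 20.0,
    dense: bool = True,
) -> InputProjection:
    """Randomly wire input attributes to reservoir neurons.

    Dense tasks get ``round(0.2 * n_neurons)`` connections per attribute
    with U[0, 1] weights; the sparse (high-dimensional, e.g. pixel) variant
    gets one connection per attribute with weights scaled by 0.25.
    """
    rng = np.random.default_rng(seed)
    if dense:
        per_attr = max(1, round(0.2 * n_neurons))
        attribute = np.repeat(np.arange(n_attributes), per_attr)
        target = rng.integers(0, n_neurons, size=n_attributes * per_attr)
        weight = rng.uniform(0.0, 1.0, size=n_attributes * per_attr)
    else:
        attribute = np.arange(n_attributes)
        target = rng.integers(0, n_neurons, size=n_attributes)
        weight = rng.uniform(0.0, 1.0, size=n_attributes) * 0.25
    return InputProjection(
        attribute=attribute.astype(np.int64),
        target=target.astype(np.int64),
        weight=weight,
        scale=scale,
    )


def isi_histogram(
    record: SpikeRecord, bin_width: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of inter-spike intervals pooled over neurons.

    Neurons with fewer than two spikes contribute nothing.  Returns
    ``(counts, bin_edges)`` with bins of ``bin_width`` ms.
    """
    isis = []
    for times in record.per_neuron():
        if len(times) >= 2:
            isis.append(np.diff(times))
    if not isis:
        return np.array([]), np.array([0.0])
    pooled = np.concatenate(isis).astype(float)
    top = np.ceil(pooled.max() / bin_width) * bin_width + bin_width
    edges = np.arange(0.0, top + bin_width / 2, bin_width)
    counts, edges = np.histogram(pooled, bins=edges)
    return counts, edges
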