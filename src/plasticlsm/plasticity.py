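"""Synaptic plasticity rules: BCM, bi-phasic STDP and tri-phasic STDP.

The three rules share one application contract: after each 30-ms input frame
is simulated, every recurrent synapse receives a weight update computed from
that frame's activity, and weights are clamped to their sign-preserving
bounds ([0, 10] excitatory, [-10, 0] inhibitory).

* **BCM** is rate-based: ``dw = y (y - theta) x - eps_w`` with *y* the
  postsynaptic and *x* the presynaptic activity (both normalized to [0, 1])
  and *theta* a sliding threshold — an exponential moving average of the
  normalized postsynaptic membrane potential (decay coefficient 0.935).
  The uniform decay ``eps_w`` slowly weakens all synapses.
* **Bi-phasic STDP** potentiates pre-before-post spike pairs and depresses
  the reverse, each with an exponentially decaying window:
  ``A+ exp(-dt/tau+)`` for dt > 0, ``-A- exp(dt/tau-)`` for dt <= 0
  (dt = t_post - t_pre).
* **Tri-phasic STDP** has a narrow Gaussian potentiation peak at dt = 15 ms
  flanked by a broad Gaussian depression:
  ``A+ exp(-(dt-15)^2/200) - A- exp(-(dt-15)^2/2000)``.

Spike pairs are formed within a frame by greedy nearest-neighbour matching
(closest opposite-side spike first, each spike used once); pairs never span
frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from . import _kernels
from .network import Network, SpikeRecord

__all__ = [
    "Rule",
    "PlasticityConfig",
    "BCMState",
    "bcm_delta",
    "update_bcm_threshold",
    "stdp_biphasic_delta",
    "stdp_triphasic_delta",
    "apply_plasticity",
    "window_table",
]


class Rule(Enum):
    NONE = "none"
    BCM = "bcm"
    STDP = "stdp"
    TP_STDP = "tp_stdp"

    @property
    def code(self) -> int:
        return {
            Rule.NONE: _kernels.RULE_NONE,
            Rule.BCM: _kernels.RULE_BCM,
            Rule.STDP: _kernels.RULE_STDP,
            Rule.TP_STDP: _kernels.RULE_TP_STDP,
        }[self]


@dataclass
class PlasticityConfig:
    """Rule selection and parameters.

    Defaults follow the standard parameterization of each rule: bi-phasic
    STDP uses a symmetric window A± = 0.15, tau± = 20 ms; tri-phasic STDP
    uses A+ = 0.25, A- = 0.1; BCM uses uniform decay eps_w = 1e-4 and
    threshold EMA coefficient 0.935.  Weight bounds are ±10 (further
    restricted per synapse to preserve sign).
    """

    rule: Rule = Rule.NONE
    A_plus: float = 0.15
    A_minus: float = 0.15
    tau_plus: float = 20.0
    tau_minus: float = 20.0
    eps_w: float = 1e-4
    theta_decay: float = 0.935
    w_max: float = 10.0
    w_min: float = -10.0

    @classmethod
    def for_rule(cls, rule: Rule | str) -> "PlasticityConfig":
        rule = Rule(rule) if not isinstance(rule, Rule) else rule
        if rule is Rule.TP_STDP:
            return cls(rule=rule, A_plus=0.25, A_minus=0.1)
        return cls(rule=rule)


@dataclass
class BCMState:
    """Running BCM quantities, persistent across frames and samples.

    ``theta`` is the per-neuron sliding threshold; ``vmin``/``vmax`` are the
    running membrane bounds used to normalize the potential into [0, 1]
    (a degenerate min = max normalizes to 0); ``xmax`` is the running
    maximum per-frame spike count used to normalize presynaptic activity.
    """

    theta: np.ndarray
    vmin: np.ndarray
    vmax: np.ndarray
    xmax: np.ndarray

    @classmethod
    def zeros(cls, n_neurons: int) -> "BCMState":
        return cls(
            theta=np.zeros(n_neurons),
            vmin=np.full(n_neurons, np.inf),
            vmax=np.full(n_neurons, -np.inf),
            xmax=np.zeros(n_neurons),
        )


def bcm_delta(x: float, y: float, theta: float, eps_w: float = 1e-4) -> float:
    """BCM weight change: ``y (y - theta) x - eps_w``."""
    return y * (y - theta) * x - eps_w


def update_bcm_threshold(
    state: BCMState, v_post: np.ndarray
) -> np.ndarray:
    """One EMA step of the sliding threshold from raw membrane potentials.

    ``v_post`` is the per-neuron membrane potential (mV); it is normalized
    to [0, 1] against the running min/max before entering
    ``theta <- 0.935 theta + 0.065 y``.  Returns the normalized activities.
    """
    v_post = np.asarray(v_post, dtype=float)
    state.vmin = np.minimum(state.vmin, v_post)
    state.vmax = np.maximum(state.vmax, v_post)
    span = state.vmax - state.vmin
    y = np.where(span > 0, (v_post - state.vmin) / np.where(span > 0, span, 1.0), 0.0)
    state.theta = 0.935 * state.theta + (1.0 - 0.935) * y
    return y


def stdp_biphasic_delta(
    delta_t: float,
    A_plus: float = 0.15,
    A_minus: float = 0.15,
    tau_plus: float = 20.0,
    tau_minus: float = 20.0,
) -> float:
    """Bi-phasic STDP window at pre-post delay ``delta_t`` (ms)."""
    if delta_t > 0:
        return A_plus * np.exp(-delta_t / tau_plus)
    return -A_minus * np.exp(delta_t / tau_minus)


def stdp_triphasic_delta(
    delta_t: float, A_plus: float = 0.25, A_minus: float = 0.1
) -> float:
    """Tri-phasic STDP window at pre-post delay ``delta_t`` (ms)."""
    q = (delta_t - 15.0) ** 2
    return A_plus * np.exp(-q / 200.0) - A_minus * np.exp(-q / 2000.0)


def _frame_spike_arrays(
    record: SpikeRecord, n_neurons: int, frame_duration: int
) -> tuple[np.ndarray, np.ndarray]:
    fc = np.zeros(n_neurons, dtype=np.int64)
    ft = np.zeros((n_neurons, frame_duration), dtype=np.float64)
    for k, t in zip(record.neurons, record.times):
        ft[k, fc[k]] = float(t)
        fc[k] += 1
    return fc, ft


def apply_plasticity(
    network: Network,
    frame_spikes: SpikeRecord,
    config: PlasticityConfig,
    state: BCMState | None = None,
    y_bar: np.ndarray | None = None,
) -> np.ndarray:
    """Apply one between-frame plasticity update; return the applied deltas.

    For the STDP rules the update is computed from the spike pairings in
    ``frame_spikes``; for BCM it uses the frame-averaged normalized
    postsynaptic activity ``y_bar`` (with ``state`` supplying the sliding
    threshold and presynaptic normalization).  Weights are modified in place
    and clamped; the returned vector is the post-clamp change per synapse.
    """
    syn = network.synapses
    n_syn = len(syn)
    delta = np.zeros(n_syn)
    if config.rule is Rule.NONE:
        return delta
    if config.rule not in (Rule.BCM, Rule.STDP, Rule.TP_STDP):
        raise ValueError(f"unknown plasticity rule: {config.rule!r}")

    frame_duration = max(int(frame_spikes.duration), 1)
    fc, ft = _frame_spike_arrays(frame_spikes, network.n_neurons, frame_duration)

    if config.rule is Rule.BCM:
        if state is None:
            state = BCMState.zeros(network.n_neurons)
        if y_bar is None:
            y_bar = np.zeros(network.n_neurons)
        state.xmax = np.maximum(state.xmax, fc)
        x_bar = np.where(state.xmax > 0, fc / np.where(state.xmax > 0, state.xmax, 1.0), 0.0)
        theta = state.theta
    else:
        x_bar = np.zeros(network.n_neurons)
        y_bar = np.zeros(network.n_neurons)
        theta = np.zeros(network.n_neurons)

    used_a = np.zeros(frame_duration, dtype=np.bool_)
    used_b = np.zeros(frame_duration, dtype=np.bool_)
    _kernels.apply_plasticity_frame(
        syn.weight, syn.pre, syn.post,
        network._syn_lo, network._syn_hi,
        config.rule.code,
        config.A_plus, config.A_minus, config.tau_plus, config.tau_minus,
        config.eps_w,
        fc, ft, theta, np.asarray(y_bar, dtype=float), x_bar,
        used_a, used_b, delta,
    )
    return delta


def window_table(
    rule: Rule | str,
    delta_t: np.ndarray | None = None,
    config: PlasticityConfig | None = None,
):
    """(delta_t, delta_w) table of an STDP learning window, for plotting."""
    import pandas as pd

    rule = Rule(rule) if not isinstance(rule, Rule) else rule
    if config is None:
        config = PlasticityConfig.for_rule(rule)
    if delta_t is None:
        delta_t = np.linspace(-100.0, 100.0, 401)
    if rule is Rule.STDP:
        dw = [
            stdp_biphasic_delta(t, config.A_plus, config.A_minus,
                                config.tau_plus, config.tau_minus)
            for t in delta_t
        ]
    elif rule is Rule.TP_STDP:
        dw = [stdp_triphasic_delta(t, config.A_plus, config.A_minus)
              for t in delta_t]
    else:
        raise ValueError("window tables exist for the STDP rules only")
    return pd.DataFrame({"delta_t_ms": delta_t, "delta_w": dw})
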