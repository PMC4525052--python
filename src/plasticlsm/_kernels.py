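"""Compiled inner loops for membrane simulation, plasticity and LMS.

Everything here operates on plain numpy arrays so numba can compile it; the
object-level API lives in :mod:`plasticlsm.network`, :mod:`.plasticity` and
:mod:`.readout`, which share these kernels so the fast pipeline path and the
unit-testable Python surface cannot drift apart.

Rule codes: 0 = none, 1 = BCM, 2 = bi-phasic STDP, 3 = tri-phasic STDP.
"""

from __future__ import annotations

import numpy as np
from numba import njit

RULE_NONE = 0
RULE_BCM = 1
RULE_STDP = 2
RULE_TP_STDP = 3

# tri-phasic window constants: peak centre (ms) and Gaussian denominators
TP_CENTER = 15.0
TP_DENOM_P = 200.0
TP_DENOM_D = 2000.0


@njit(cache=True)
def _window_delta(rule, dt, A_plus, A_minus, tau_plus, tau_minus):
    if rule == RULE_STDP:
        if dt > 0.0:
            return A_plus * np.exp(-dt / tau_plus)
        return -A_minus * np.exp(dt / tau_minus)
    # tri-phasic
    q = (dt - TP_CENTER) ** 2
    return A_plus * np.exp(-q / TP_DENOM_P) - A_minus * np.exp(-q / TP_DENOM_D)


@njit(cache=True)
def _pair_delta(ta, na, tb, nb, used_a, used_b, rule,
                A_plus, A_minus, tau_plus, tau_minus):
    """Sum of window deltas over greedy nearest-neighbour spike pairs.

    Each spike is used at most once; pairs are accepted in order of
    increasing |t_post - t_pre| (ties: earliest pre, then post spike).
    """
    for i in range(na):
        used_a[i] = False
    for j in range(nb):
        used_b[j] = False
    total = 0.0
    n_pairs = min(na, nb)
    for _ in range(n_pairs):
        best = 1.0e18
        bi = -1
        bj = -1
        for i in range(na):
            if used_a[i]:
                continue
            for j in range(nb):
                if used_b[j]:
                    continue
                d = abs(tb[j] - ta[i])
                if d < best:
                    best = d
                    bi = i
                    bj = j
        used_a[bi] = True
        used_b[bj] = True
        dt = tb[bj] - ta[bi]
        total += _window_delta(rule, dt, A_plus, A_minus, tau_plus, tau_minus)
    return total


@njit(cache=True)
def apply_plasticity_frame(w, pre, post, w_lo, w_hi, rule,
                           A_plus, A_minus, tau_plus, tau_minus, eps_w,
                           fc, ft, theta, y_bar, x_bar,
                           used_a, used_b, delta_out):
    """Apply one between-frame plasticity update to all synapses, in place.

    ``fc``/``ft`` are per-neuron spike counts and spike times (ms) within the
    just-simulated frame; ``theta``/``y_bar``/``x_bar`` are the BCM threshold
    and frame-averaged normalized post/pre activities (ignored for STDP).
    ``delta_out`` receives the applied (post-clamp) change per synapse.
    """
    n_syn = w.shape[0]
    for m in range(n_syn):
        dw = 0.0
        if rule == RULE_BCM:
            y = y_bar[post[m]]
            dw = y * (y - theta[post[m]]) * x_bar[pre[m]] - eps_w
        elif rule == RULE_STDP or rule == RULE_TP_STDP:
            na = fc[pre[m]]
            nb = fc[post[m]]
            if na > 0 and nb > 0:
                dw = _pair_delta(ft[pre[m]], na, ft[post[m]], nb,
                                 used_a, used_b, rule,
                                 A_plus, A_minus, tau_plus, tau_minus)
        old = w[m]
        new = old + dw
        if new > w_hi[m]:
            new = w_hi[m]
        elif new < w_lo[m]:
            new = w_lo[m]
        w[m] = new
        delta_out[m] = new - old


@njit(cache=True)
def simulate_sample(v, u, a_arr, b_arr, c_arr, d_arr,
                    i_inj, i_rec,
                    pre, post, w, w_lo, w_hi, out_off, out_syn,
                    in_attr, in_target, in_weight, input_scale,
                    frames, frame_duration,
                    rule, A_plus, A_minus, tau_plus, tau_minus, eps_w,
                    theta_decay, theta, vmin, vmax, xmax,
                    spike_n, spike_t, t_start,
                    used_a, used_b, delta_scratch, err_info):
    """Present one multi-frame sample: inject, integrate, adapt.

    For each frame the injected current is set to
    ``W_in * attribute * input_scale`` and held for ``frame_duration`` 1-ms
    Euler steps of the quadratic integrate-and-fire membrane (spike at
    v > 30 mV, reset v <- c, u <- u + d); recurrent spikes deliver their
    synaptic weight as current on the following step; the configured
    plasticity rule is applied between frames.  Spikes are appended to
    ``spike_n``/``spike_t`` with absolute times starting at ``t_start``.

    Returns the number of spikes recorded, or -1 on numerical divergence
    (offending neuron index left in ``err_info[0]``).
    """
    n = v.shape[0]
    n_frames = frames.shape[0]
    n_attr = frames.shape[1]
    fc = np.zeros(n, dtype=np.int64)
    ft = np.zeros((n, frame_duration), dtype=np.float64)
    y_sum = np.zeros(n)
    x_bar = np.zeros(n)
    spiked = np.zeros(n, dtype=np.int64)
    n_spikes = 0
    t_global = t_start

    for f in range(n_frames):
        for k in range(n):
            i_inj[k] = 0.0
        for k in range(in_attr.shape[0]):
            i_inj[in_target[k]] += (
                in_weight[k] * frames[f, in_attr[k]] * input_scale
            )
        for k in range(n):
            fc[k] = 0
            y_sum[k] = 0.0

        for t in range(frame_duration):
            n_spiking = 0
            for k in range(n):
                cur = i_inj[k] + i_rec[k]
                vk = v[k]
                v_new = vk + (0.04 * vk * vk + 5.0 * vk + 140.0 - u[k] + cur)
                u_new = u[k] + a_arr[k] * (b_arr[k] * vk - u[k])
                if not np.isfinite(v_new) or abs(v_new) > 1.0e8:
                    err_info[0] = k
                    return -1
                if rule == RULE_BCM:
                    # running membrane normalization feeds the sliding threshold
                    if v_new < vmin[k]:
                        vmin[k] = v_new
                    if v_new > vmax[k]:
                        vmax[k] = v_new
                    span = vmax[k] - vmin[k]
                    y_t = (v_new - vmin[k]) / span if span > 0.0 else 0.0
                    theta[k] = theta_decay * theta[k] + (1.0 - theta_decay) * y_t
                    y_sum[k] += y_t
                if v_new > 30.0:
                    spike_n[n_spikes] = k
                    spike_t[n_spikes] = t_global
                    n_spikes += 1
                    ft[k, fc[k]] = float(t)
                    fc[k] += 1
                    spiked[n_spiking] = k
                    n_spiking += 1
                    v[k] = c_arr[k]
                    u[k] = u_new + d_arr[k]
                else:
                    v[k] = v_new
                    u[k] = u_new
            # recurrent delivery: one-step delay, delta-impulse currents
            for k in range(n):
                i_rec[k] = 0.0
            for s in range(n_spiking):
                src = spiked[s]
                for m in range(out_off[src], out_off[src + 1]):
                    syn = out_syn[m]
                    i_rec[post[syn]] += w[syn]
            t_global += 1

        if rule == RULE_BCM:
            for k in range(n):
                if fc[k] > xmax[k]:
                    xmax[k] = fc[k]
                x_bar[k] = fc[k] / xmax[k] if xmax[k] > 0.0 else 0.0
                y_sum[k] /= frame_duration
            apply_plasticity_frame(w, pre, post, w_lo, w_hi, rule,
                                   A_plus, A_minus, tau_plus, tau_minus,
                                   eps_w, fc, ft, theta, y_sum, x_bar,
                                   used_a, used_b, delta_scratch)
        elif rule == RULE_STDP or rule == RULE_TP_STDP:
            apply_plasticity_frame(w, pre, post, w_lo, w_hi, rule,
                                   A_plus, A_minus, tau_plus, tau_minus,
                                   eps_w, fc, ft, theta, y_sum, x_bar,
                                   used_a, used_b, delta_scratch)
    return n_spikes


@njit(cache=True)
def lms_train(weights, states, labels, draws, mu, cum_error):
    """LMS training of one-vs-all readout rows with running WTA error.

    ``draws`` indexes the training state presented at each iteration.  The
    winner-takes-all prediction is made from the outputs computed with the
    pre-update weights, matching the iterative procedure; ``cum_error[i]``
    receives the cumulative misclassification fraction after iteration i+1.
    """
    n_classes = weights.shape[0]
    n_iter = draws.shape[0]
    outputs = np.zeros(n_classes)
    error_sum = 0.0
    for i in range(n_iter):
        x = states[draws[i]]
        lab = labels[draws[i]]
        best = 0
        for cls in range(n_classes):
            y = 0.0
            wrow = weights[cls]
            for j in range(x.shape[0]):
                y += wrow[j] * x[j]
            outputs[cls] = y
            if y > outputs[best]:
                best = cls
        for cls in range(n_classes):
            target = 1.0 if cls == lab else 0.0
            coef = mu * (target - outputs[cls])
            wrow = weights[cls]
            for j in range(x.shape[0]):
                wrow[j] += coef * x[j]
        if best != lab:
            error_sum += 1.0
        cum_error[i] = error_sum / (i + 1.0)
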