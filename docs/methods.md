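# Methods

This note documents the model, the synthetic data, the numerical choices
and the known limitations of `plasticlsm`.  It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Network model

Neurons follow the two-variable quadratic membrane model
`v' = 0.04v² + 5v + 140 − u + I`, `u' = a(bv − u)`, integrated by plain
Euler at **dt = 1 ms**, with the membrane updated before the spike test; a
neuron crossing 30 mV emits a spike and resets `v ← c`, `u ← u + d`.
Excitatory cells use (a, b, c, d) = (0.2, 0.2, −65, 8) (regular spiking),
inhibitory cells (0.1, 0.2, −65, 2); the population is 4:1
excitatory:inhibitory (`round(0.8 N)` excitatory, assigned by a seeded
shuffle).  1 ms Euler matches the millisecond-denominated constants
elsewhere in the model (τ = 6 ms filter, 30 ms frames) and the canonical
usage of this membrane model.  A membrane magnitude above 10⁸ mV or a
non-finite value raises a divergence error naming the neuron.

Connectivity is `⌊N²C⌋` synapses (C = 0.1) with presynaptic and
postsynaptic endpoints drawn independently and uniformly; self-connections
and duplicates are kept as drawn, since only uniform endpoint drawing is
specified.  Initial weights are 𝒩(6, 0.5) for excitatory and 𝒩(−5, 0.5)
for inhibitory presynaptic neurons.  Synapses are static delta impulses:
a spike at step t delivers its weight as current to the postsynaptic
neuron at step t + 1 (one-step transmission delay) for exactly one step.

Input frames persist for the whole 30 ms frame: the injected current of a
target neuron is `Σ W_in · value · 20` over its input connections, set at
frame onset and held.  Dense tasks wire `round(0.2 N)` connections per
attribute with U[0, 1] weights; very high-dimensional (pixel) inputs get
one connection per attribute with weights scaled by 0.25.  Activity reset
between samples restores `v ← c`, `u ← b·c` (standard initialization for
this membrane model) and clears all pending currents; weights are never
touched by a reset.

## Plasticity

All three rules are applied once per frame, after the frame's 30 membrane
steps, to **every** recurrent synapse, excitatory and inhibitory.  Weights
clamp to [0, 10] (excitatory) and [−10, 0] (inhibitory): the printed ±10
bounds, tightened per synapse so that plasticity can never silently flip a
synapse's sign.

**Bi-phasic STDP** (A± = 0.15, τ± = 20 ms) and **tri-phasic STDP**
(A₊ = 0.25, A₋ = 0.1, Gaussian denominators 200 and 2000 ms² centred at
Δt = 15 ms) act on pre/post spike pairs *within* the just-simulated frame;
pairs never span frames, mirroring the between-frame application order.
Pairing is greedy nearest-neighbour: candidate pairs are accepted in order
of increasing |Δt| (ties to the earlier spike), each spike used at most
once.  This bounds the per-frame update by the smaller spike count and is
the standard scheme for window-based STDP when no pairing rule is stated.

**BCM** is rate-based: `Δw = ȳ(ȳ − θ)x̄ − ε_w` with ε_w = 10⁻⁴.
The sliding threshold θ is an exponential moving average (coefficient
0.935) of the postsynaptic membrane potential normalized to [0, 1] by
per-neuron running min/max of all previously seen values; it is updated at
every membrane step ("continuously"), while the weight update itself is
per frame.  ȳ is the frame average of the normalized potential; x̄ is the
presynaptic frame spike count normalized by the running per-neuron maximum
frame count — a running normalization mirroring the membrane one, chosen
because the rule is only specified to act on temporal averages of pre- and
postsynaptic activity.  A degenerate normalization (min = max, i.e. the
first observation) maps to 0; the effect vanishes after one step.  The BCM
running state persists across samples and phases and is not rolled back
with the weights during collection, since it models the neuron's history
rather than the synapse.

## Readout

The state vector takes, per neuron, the maximum of the decaying trace
`r(t) = r(t−1)e^{−1/6} + s(t)` over the **final 50 steps** of the sample's
concatenated spike record (shorter records are left-padded with silence).
The 50-step window is the stated filter length even though frames last
30 ms; the mismatch is deliberate fidelity to the printed constants, and
its cost is discussed under Limitations.  Readouts are bias-free dot
products, one row per class, trained by LMS (μ = 0.005) on uniformly
random draws from the training states — target 1 for the matching class, 0
otherwise — with the cumulative winner-takes-all error tracked from the
pre-update outputs at every iteration.  Ties in the argmax resolve to the
lowest class index.  Reported errors: cumulative training error, final
training error, and held-out test error; the headline classification
number is the test error, since generalization is what an error rate on a
split data set must mean.

## Synthetic data

**Tri-function signal.**  A Markov switching process: at each step, with
probability 0.05, the active generator switches to one of the other two
with freshly drawn parameters.  Generators: sine with period uniform in
[10, 50] steps; chaotic tent map `x ← 1.8·min(x, 1−x)` from a uniform
start; constant uniform in [0, 1].  The concatenated signal is globally
min-max rescaled to [0, 1].  These internals preserve three qualitatively
distinct regimes (smooth oscillation, broadband chaos, flat) without
importing the external benchmark definition.  The signal is cut into
non-overlapping 10-frame samples (one attribute per frame), labelled by
the majority step label (ties to the earliest label in the window);
10 frames is about half the mean segment length (1/0.05 = 20 steps), so
most windows are pure-class.  The default series length is 50,000 steps
(5,000 samples), split 50/50 per class into train/test.

**Vowel-like sequences.**  Each class owns a smooth per-feature temporal
template (shared base curve plus a class offset scaled by `class_sep`,
both low-order random Fourier series); a sample evaluates its template at
n uniformly spaced points (n uniform in [7, 29]) and adds Gaussian noise
(σ = 0.05), clipped to [0, 1].  Defaults (9 classes × 40 samples × 12
features) emulate the shape of the nine-speaker vowel-utterance task;
`class_sep = 0` removes all class signal, giving a chance-level control.

**Motion-like video.**  A bright rectangle moves along a class-dependent
direction (2πc/6) over a noisy background.  The preprocessor block-averages
each spatial axis by `round(1/0.2) = 5`, takes absolute differences of
consecutive downsampled frames, and binarizes at 20% of the stack maximum,
yielding N−1 sparse binary feature columns.

What the generators do **not** emulate: real cepstral statistics and
speaker variability, video camera noise and articulated motion,
non-stationarity across recording conditions.  Passing tests on these
inputs therefore demonstrate the correctness and the qualitative behaviour
of the pipeline, not performance on real speech or video.

## Experiment pipeline

Three phases, seeds derived by name (data, split, topology, projection,
pretrain, readout) from one experiment seed via a seed sequence, so a
report is exactly reproducible from its configuration echo.

1. **Pre-training**: 10,000 iterations; each presents one uniformly random
   *training* sample frame-by-frame with plasticity between frames, then
   resets activity.  Weight/ISI snapshots at presentations 1, 100, 1000.
2. **Collection**: baseline weights stored; every sample (both splits) is
   presented once with plasticity still active; its state vector and
   weight delta (weights − baseline) are recorded and the weights rolled
   back before the next sample.  The network leaves this phase bit-equal
   to how it entered (a tested contract).
3. **Readout training**: 100,000 LMS iterations on the train-split states;
   winner-takes-all evaluation on both splits.

The interference statistic pools all collected samples; the distance
matrix uses the train/test split as its two sets, exactly the printed L1
form `Σ_i |ΔW_i(a, X) − ΔW_i(b, Y)|` (an L2 variant is available via
`metric="l2"` for sensitivity analysis, but the printed sum-of-absolute
form is the default and the one all reported numbers use).  C_n in the
interference magnitude bracket is the total class count, the only reading
that keeps the per-class and total formulas consistent with one symbol.

Default scales: N = 135 for performance runs, N = 35 for weight-matrix
visualization; the test suite and acceptance script run the performance
scale for the headline numbers and the visualization scale for
distribution snapshots.

## Numerical and degenerate-input choices

- Weight updates are accumulated per synapse per frame, then clamped once;
  a weight at a bound with a further same-sign update stays at the bound.
- STDP pairing tie-break: lowest pre-spike index, then post.
- Majority-label ties in segmentation: earliest label in the window.
- Winner-takes-all ties: lowest class index.
- Constant attributes under min-max normalization map to 0.
- Interference requires ≥ 2 classes and ≥ 1 synapse; empty classes in a
  split raise an error naming the class.

## Known limitations

- **Short reservoir memory vs the readout window.**  With delta-impulse
  synapses, reservoir activity decays within roughly one 30 ms frame of
  input removal, and the state vector reads only the final 50 steps
  (~1.7 frames) of a sample.  Class evidence for the tri-function task
  that lives in earlier frames of a 10-frame window is therefore invisible
  to the linear readout: classification error on that task is
  substantially higher than an ideal decoder with full-window access could
  achieve.  This follows from the printed model constants (T = 50, τ = 6,
  30 ms frames, delta synapses) and is reported as measured.
- **Interference is drift-sensitive.**  The sign bracket of the
  interference statistic compares class-mean deltas against the mean of
  the other classes'.  When all classes share one input channel, the
  per-sample weight change is dominated by the deterministic drift of the
  plasticity flow at the frozen baseline, which is common to all classes;
  sign opposition is then rare and I_total small.  The statistic reads
  high only when class-specific deviations dominate that common drift.
- Plasticity models no axonal delays beyond one step, no conductance
  synapses, no short-term or structural plasticity, no reward modulation.
- The vowels ASCII reader is provided for the published frame format but
  is untested against the real distribution files.
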