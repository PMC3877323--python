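# Methods

`stdpnet` simulates the emergence of feedforward structure in a spatial
spiking network trained by asynchronous paired-layer stimulation, and the
recovery of the plasticity rule's time constants from that structure and
from the network's propagation dynamics. This note records the model, the
parameter choices that matter, the numerical scheme, and the design
decisions taken where the problem left the design open.

## Model

**Geometry and connectivity.** N = `n_layers x per_layer` neurons sit at
cell centres of the unit square, arranged in `n_layers` vertical layers
ordered left to right (defaults 50 x 20). Each unordered pair at distance
`d` (in side units) is connected with probability
`p(d) = k exp(-d / lambda_c)`, one Bernoulli draw per pair; a connected
pair carries two directed synapses with independent initial weights drawn
uniformly from [0, 1]. Synapses are classified feedforward / feedback /
recurrent by the layer order of their endpoints.

The connection decay length `lambda_c` defaults to **one inter-layer
spacing** (0.02 at the default geometry). This is the scale at which the
training protocol below is self-consistent: only synapses between adjacent
layers ever experience pre/post pairings (state recovery between trials
removes all cross-trial pairings), so the fraction of feedforward synapses
that training can saturate equals the fraction spanning exactly one layer.
At `lambda_c` = one spacing that fraction is ~0.6, which matches the
saturated fractions the experiments below produce; at several spacings the
trainable fraction collapses to ~0.2 and the saturation experiment loses
its meaning.

**Membrane dynamics.** Leaky integrate-and-fire with conductance-based
alpha synapses:

    tau_m dV_i/dt = (V_rest - V_i) + g * sum_j a_ji W_ji s_j(t) (E_ex - V_i) + I_i(t)

with tau_m = 20 ms, V_rest = -70 mV, threshold V_th = -54 mV, E_ex = 0 mV
(standard V1-cell modelling values). External currents are in
voltage-equivalent units (membrane resistance folded in). A neuron reaching
threshold is reset to rest; there is no refractory period. `s_j` is the
superposition of unit-peak alpha kernels `(s/tau_alpha) exp(1 - s/tau_alpha)`
(tau_alpha = 2 ms) triggered by presynaptic spikes.

**Plasticity.** Nearest-spike pair-based STDP with hard bounds [0, 1]: a
pairing with lag `dt = t_post - t_pre` changes the weight by
`+A+ exp(-dt/tau+)` for dt > 0 and `-A- exp(dt/tau-)` for dt < 0; at dt = 0
(synchronous volleys) both directed synapses of a pair receive the
potentiation amplitude `+A+` — this is what drives recurrent (intra-layer)
weights to the upper bound under synchronous within-layer stimulation.
Every spike pairs only with the partner's most recent spike, appropriate to
the low-rate training regime. Updates apply at the spike step, before
integration continues; weights clip to the bounds after every update.

**Training.** For each adjacent layer pair (l, l+1), left to right: a pulse
of amplitude `i_s` and duration `t_d` = 5 ms into layer l, a gap `delta_t`
(pulse offset to next onset — the inter-stimulus interval), the same pulse
into layer l+1, then a settling window of 10 tau_alpha with plasticity
still on; afterwards the membrane/synaptic state (not the weights) resets
to rest, implementing the long recovery time between trials exactly. One
sweep over all pairs is one trial; defaults use 20 trials. `i_s` is
calibrated per configuration: the smallest amplitude on a 1-mV grid that
fires an isolated neuron within `t_d` (73 mV at the defaults), verified to
cause no off-layer spikes. Because all neurons of a layer see the same
current from rest, layers fire synchronous volleys with latency ~= t_d, so
the realized pairing lag is `t_d + delta_t` for both the potentiated
(feedforward) and depressed (feedback) adjacent synapses.

**Testing.** A steady current `i_t` into one layer (default: layer 3) with
plasticity frozen; the propagation count S is the total number of spikes in
all layers to the right of the driven one during the test window.

## The three observation regimes

A single parameter set cannot serve all of the package's measurements; the
presets in `stdpnet.analysis` pin one regime per question.

**Saturation regime** (`saturation_preset`; A± = 0.1, symmetric tau± = 20 ms,
k = 0.2). Twenty trials at short intervals accumulate ~2.0 of cumulative
potentiation per adjacent pairing — far beyond the weight range — so
essentially every adjacent feedforward weight rails at 1 and every adjacent
feedback weight at 0. The saturated fractions equal the adjacent fraction
of each class (~0.6): this regime reproduces the headline saturated
fractions at `delta_t` = 0. At `delta_t` = 60 ms the cumulative potentiation is
20 x 0.1 x exp(-65/20) ~= 0.08, so only ~8% of adjacent (~5% of all)
feedforward weights can reach the bound. Note the pair of values this
regime produces at intervals 0 and 60 ms decays with the *pairing sum*,
not with any fitted exponential: fractions saturate (head) and floor
(tail), which is why exponent fitting is done in a different regime.

**Unsaturated structure regime** (`structure_preset`; A± = 0.02, scaled
20 x 10 lattice). With cumulative modification <= 0.4 the weights stay off
the bounds and the class-mean modification is, per seed, a deterministic
multiple of the pairing sum `20 A exp(-(t_d + delta_t)/tau)`. A log-linear
fit of dG± over delta_t in {0, 10, ..., 60} ms then recovers tau± to
within a few percent for the shorter time constants and ~12% for tau = 40 ms
(the residual upward bias comes from the small clipping tails, which are
largest where the per-interval modification is largest). The modification is measured against each network's
own realized initial class mean: with O(50) synapses per class the sampled
initial mean is 0.5 ± 0.04, and using the nominal 0.5 injects an additive
baseline that corrupts the exponential tail.

**Propagation regime** (`propagation_preset`; 20 x 40 lattice, k = 0.3,
lambda_c = 0.4 spacings, g = 0.028, i_t = 730 mV, t_test = 600 ms,
saturation-regime amplitudes). The propagation count is made proportional
to the *bound-saturated fraction* of adjacent feedforward synapses, which
for uniform initial weights is exactly `min(1, c)` with
`c = 2 exp(-(t_d + delta_t)/tau+)` — a clean exponential with zero
baseline. Three choices make S track it:

* *Sparse convergence* (adjacent in-degree ~0.13): almost every relay event
  is carried by a single synapse. Posts with two or more inputs respond to
  the *sum* of two partial weights, which is nonlinear in the saturated
  fraction and has a nonzero untrained response; their density scales with
  in-degree squared and is negligible here.
* *Relay threshold at the bound*: with the strong steady probe the driven
  layer fires at a discretization-locked 2.0 spikes/ms, and g = 0.028
  places the single-synapse firing threshold at a weight of ~0.975. Only
  saturated synapses relay; every untrained weight (< 1 a.s.) is silent, so
  the untrained network produces no downstream spikes at all.
* *Probe current 10 x i_s*: at this drive the driven layer's rate is set by
  the current alone (recurrent conductance input shifts the membrane by a
  few percent of the drive), which makes the relay threshold insensitive to
  the recurrent weights — and hence to their ablation — and stable across
  seeds. At the 2 x i_s default the driven rate is slow enough that its
  discretized period, and so the relay threshold, jumps between seeds.

The sweep window is scaled to the probed time constant
(`delta_t` from `0.744 tau - 5` to `2.59 tau - 5`, i.e. c in [0.95, 0.15]):
above the head the saturated fraction clips at one, beyond the tail single
relays produce counting noise. Within the window, fitted
propagation falloff constants track tau+ with ratio ~1.0 and the
lambda_dyn-vs-tau+ slope is ~1 by construction of the readout; the S-vs-dG+
relation is approximately linear with a coefficient kappa that grows with
the probe amplitude. The kappa probe amplitudes (730, 900, 1200 mV) map to
distinct discretized driver periods (0.5, 0.4, 0.3 ms at dt = 0.1 ms);
amplitudes within one period bin produce identical driver rates and hence
identical counts.

## Numerics

* Clock-driven integration, dt = 0.1 ms. The alpha conductance is carried
  by two per-neuron state variables with exact exponential per-step
  updates, so overlapping spikes superpose exactly; the membrane uses
  exponential Euler with conductances frozen over the step (exact for
  constant input, first-order in general; halving dt moves spike times by
  less than dt).
* Spikes are detected at step end; all spikes within a step are
  simultaneous (dt = 0 pairings). Each directed synapse is updated exactly
  once per spike volley.
* Step times are computed from the step index, not accumulated, so
  half-open stimulus windows never gain or lose a step to floating-point
  drift — with a minimally-calibrated pulse a single lost step silences
  the layer.
* Training trials early-exit once no neuron can reach threshold any more
  (a conservative bound on future synaptic drive), which removes most of
  the settling time without changing any spike.
* Exponential fits are least squares on (x, log y); non-positive values are
  dropped with a warning, fewer than three surviving points is an error,
  and a non-decaying trend is flagged (`lam = inf`). A nonlinear
  refinement was considered and rejected: all fitted curves here are
  noiseless-to-a-few-percent exponentials where the log-linear fit is
  already exact in the mean.

## Problem sizes

Full-size saturation runs use the 50 x 20 lattice; exponent-recovery and
propagation experiments use scaled lattices (20 x 10 and 20 x 40) with 3-5
independent networks per condition and 6-7 interval points per sweep, sizes
at which the quantities of interest are already deterministic to within a
few percent (class means are per-seed deterministic; propagation counts are
averaged across seeds before fitting).

## Limitations

* Purely excitatory, no refractory period: outside the presets' sparse
  regimes the network either fails to propagate or reverberates; there is
  no inhibition to stabilize dense connectivity.
* The saturated fractions at long intervals are set by the pairing sum
  `n_trials A exp(-(t_d + delta_t)/tau)`; with the standard amplitudes the
  value at `delta_t` = 60 ms is ~5%, and no parameter choice consistent
  with the short-interval fractions raises it materially.
* Synchronous-volley training makes every adjacent pairing carry the same
  lag; jittered stimuli (not modelled) would dephase volleys and smear the
  falloff constants.
* The propagation readout counts single-synapse relays; it measures the
  saturated fraction, not a deep multi-layer cascade. Activity reaches the
  first one or two layers downstream of the probe, by design.
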