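"""Training and testing protocols for feedforward-structure formation.

Training: for every adjacent layer pair ``(l, l+1)``, left to right, a pulse
current is injected into the left layer for ``t_d`` ms, then — after an
inter-stimulus interval ``delta_t`` measured from pulse offset to the next
onset — into the right layer for ``t_d`` ms, with STDP on.  After each
trial the membrane and synaptic state is reset to rest (the "long recovery
time" between trials, implemented exactly), while the weights persist.  One
sweep over all pairs constitutes one trial per pair.

The pulse amplitude is calibrated once per configuration: the smallest
amplitude on a 1-mV grid that makes an isolated neuron fire within the
pulse, verified to cause no spikes outside the stimulated layer at initial
weights.  Because all neurons of a stimulated layer see the same current
from rest, a layer fires as a synchronous volley near the end of its pulse.

Testing: a steady current into one layer with plasticity frozen; the
propagation count ``S`` is the total number of spikes in all layers to the
right of the stimulated one during the test window.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .lif_dynamics import (
    NeuronParams,
    SimulationState,
    SpikeRaster,
    StimulusProgram,
    SynapseParams,
    run,
)
from .network_model import (
    FEEDBACK,
    RECURRENT,
    Network,
    class_mask,
)
from .stdp import StdpParams

__all__ = [
    "TrainingProtocol",
    "TestProtocol",
    "CalibrationError",
    "calibrate_pulse_amplitude",
    "resolve_training",
    "resolve_test",
    "train_pair",
    "train_network",
    "test_propagation",
    "PropagationResult",
    "ablate",
]


class CalibrationError(RuntimeError):
    """Stimulus calibration failed (layer silent, or off-layer spikes)."""


@dataclass(frozen=True)
class TrainingProtocol:
    """Alternating paired-layer pulse stimulation.

    ``i_s = None`` requests auto-calibration (minimal amplitude driving every
    stimulated neuron to fire within ``t_d``).  ``delta_t`` is the gap from
    left-pulse offset to right-pulse onset.  ``settle`` is the plasticity
    window simulated after the second pulse (default ``10 * tau_alpha``);
    recovery between trials is an exact state reset.
    """

    i_s: float | None = None  # pulse amplitude, voltage-equivalent mV
    t_d: float = 5.0  # pulse duration, ms
    delta_t: float = 0.0  # inter-stimulus interval, ms
    n_trials: int = 20  # trials per layer pair
    settle: float | None = None  # post-pulse window, ms

    def __post_init__(self) -> None:
        if self.i_s is not None and self.i_s <= 0:
            raise ValueError("i_s must be positive")
        if self.t_d <= 0:
            raise ValueError("t_d must be positive")
        if self.delta_t < 0:
            raise ValueError("delta_t must be non-negative")
        if self.n_trials < 0:
            raise ValueError("n_trials must be non-negative")


@dataclass(frozen=True)
class TestProtocol:
    """Steady-current stimulation of one layer with plasticity frozen.

    ``i_t = None`` requests the default of twice the calibrated training
    pulse amplitude.
    """

    i_t: float | None = None  # steady current amplitude, mV
    target_layer: int = 3
    t_test: float = 200.0  # test duration, ms

    def __post_init__(self) -> None:
        if self.i_t is not None and self.i_t <= 0:
            raise ValueError("i_t must be positive")
        if self.target_layer < 1:
            raise ValueError("target_layer must be >= 1")
        if self.t_test <= 0:
            raise ValueError("t_test must be positive")


def calibrate_pulse_amplitude(
    neuron: NeuronParams,
    syn: SynapseParams,
    t_d: float,
    dt: float = 0.1,
    grid_step: float = 1.0,
    grid_max: float = 1000.0,
) -> float:
    """Smallest grid amplitude that makes an isolated neuron fire within ``t_d``.

    Simulates a single synapse-free neuron under a constant current for each
    candidate amplitude (bisection over the grid; firing is monotone in the
    amplitude).
    """
    from .network_model import GeometryConfig

    geometry = GeometryConfig(n_layers=2, per_layer=1)
    from .network_model import build_lattice

    positions, layer_of = build_lattice(geometry)
    net = Network(
        geometry=geometry,
        positions=positions,
        layer_of=layer_of,
        pre=np.empty(0, int),
        post=np.empty(0, int),
        weights=np.empty(0),
    )

    def fires(amp: float) -> bool:
        stim = StimulusProgram.pulse([0], 0.0, t_d, amp)
        res = run(net, neuron, syn, stim, duration=t_d, dt=dt)
        return bool(np.any(res.raster.neurons == 0))

    lo, hi = 1, int(round(grid_max / grid_step))
    if not fires(hi * grid_step):
        raise CalibrationError(
            f"no amplitude on the grid up to {grid_max} mV fires within t_d={t_d} ms"
        )
    while lo < hi:
        mid = (lo + hi) // 2
        if fires(mid * grid_step):
            hi = mid
        else:
            lo = mid + 1
    return lo * grid_step


def _settle(training: TrainingProtocol, syn: SynapseParams) -> float:
    return training.settle if training.settle is not None else 10.0 * syn.tau_alpha


def resolve_training(
    training: TrainingProtocol,
    network: Network,
    neuron: NeuronParams,
    syn: SynapseParams,
    dt: float = 0.1,
    verify_layer: int | None = None,
) -> TrainingProtocol:
    """Fill in ``i_s`` by calibration and verify no off-layer spikes.

    The verification stimulates one layer (a middle layer by default) of the
    network at its current weights with a single pulse and requires that all
    resulting spikes stay inside that layer.
    """
    if training.i_s is None:
        i_s = calibrate_pulse_amplitude(neuron, syn, training.t_d, dt=dt)
        training = replace(training, i_s=i_s)
    if verify_layer is None:
        verify_layer = network.geometry.n_layers // 2
    stim = StimulusProgram.for_layer(
        network.layer_of, verify_layer, 0.0, training.t_d, training.i_s
    )
    res = run(
        network.copy(),
        neuron,
        syn,
        stim,
        duration=training.t_d + _settle(training, syn),
        dt=dt,
    )
    layers_hit = set(network.layer_of[res.raster.neurons].tolist())
    if not layers_hit:
        raise CalibrationError(
            f"calibrated amplitude i_s={training.i_s} fails to fire layer {verify_layer}"
        )
    if layers_hit - {verify_layer}:
        raise CalibrationError(
            f"i_s={training.i_s} causes off-layer spikes in layers "
            f"{sorted(layers_hit - {verify_layer})} at current weights"
        )
    return training


def train_pair(
    network: Network,
    pair_index: int,
    training: TrainingProtocol,
    neuron: NeuronParams,
    syn: SynapseParams,
    stdp_params: StdpParams,
    dt: float = 0.1,
) -> SpikeRaster:
    """One training trial of layer pair ``(l, l+1)``; weights update in place.

    Simulates left pulse, inter-stimulus gap, right pulse and a settling
    window with plasticity on, then discards the membrane/synaptic state
    (exact recovery to rest).  Raises :class:`CalibrationError` if either
    stimulated layer fails to spike.
    """
    l = pair_index
    n_layers = network.geometry.n_layers
    if not 1 <= l <= n_layers - 1:
        raise ValueError(f"pair index {l} outside 1..{n_layers - 1}")
    if training.i_s is None:
        raise ValueError("training.i_s is unset; call resolve_training first")
    t_d, gap = training.t_d, training.delta_t
    stim = StimulusProgram.for_layer(network.layer_of, l, 0.0, t_d, training.i_s) + (
        StimulusProgram.for_layer(network.layer_of, l + 1, t_d + gap, t_d, training.i_s)
    )
    duration = 2 * t_d + gap + _settle(training, syn)
    res = run(
        network,
        neuron,
        syn,
        stim,
        duration=duration,
        dt=dt,
        plasticity=stdp_params,
        quiescent_exit_after=2 * t_d + gap,
    )
    fired_layers = set(network.layer_of[res.raster.neurons].tolist())
    for layer in (l, l + 1):
        if layer not in fired_layers:
            raise CalibrationError(
                f"stimulated layer {layer} produced no spikes "
                f"(i_s={training.i_s}, t_d={t_d}); recalibrate the pulse amplitude"
            )
    return res.raster


def train_network(
    network: Network,
    training: TrainingProtocol,
    neuron: NeuronParams,
    syn: SynapseParams,
    stdp_params: StdpParams,
    dt: float = 0.1,
) -> pd.DataFrame:
    """Train every adjacent pair, left to right, for ``n_trials`` sweeps.

    Weights of ``network`` are modified in place.  Returns the per-sweep
    trajectory of mean weights per connection class (row 0 = initial state).
    """
    training = resolve_training(training, network, neuron, syn, dt=dt)
    masks = {cls: class_mask(network, cls) for cls in ("feedforward", "feedback", "recurrent")}

    def _row(trial: int) -> dict:
        w = network.weights
        return {
            "trial": trial,
            **{
                f"{cls}_mean": (float(w[m].mean()) if m.any() else np.nan)
                for cls, m in masks.items()
            },
        }

    rows = [_row(0)]
    for trial in range(1, training.n_trials + 1):
        for l in range(1, network.geometry.n_layers):
            train_pair(network, l, training, neuron, syn, stdp_params, dt=dt)
        rows.append(_row(trial))
    return pd.DataFrame(rows)


@dataclass
class PropagationResult:
    """Outcome of a propagation test."""

    raster: SpikeRaster
    total_spikes: int  # S: spikes of all layers right of the target
    per_layer: np.ndarray  # spike count per layer (index 0 = layer 1)
    i_t: float
    target_layer: int


def resolve_test(
    test: TestProtocol,
    neuron: NeuronParams,
    syn: SynapseParams,
    training: TrainingProtocol | None = None,
    dt: float = 0.1,
) -> TestProtocol:
    """Fill in ``i_t`` (default: twice the calibrated training pulse amplitude)."""
    if test.i_t is not None:
        return test
    if training is not None and training.i_s is not None:
        i_s = training.i_s
    else:
        t_d = training.t_d if training is not None else TrainingProtocol().t_d
        i_s = calibrate_pulse_amplitude(neuron, syn, t_d, dt=dt)
    return replace(test, i_t=2.0 * i_s)


def test_propagation(
    network: Network,
    test: TestProtocol,
    neuron: NeuronParams,
    syn: SynapseParams,
    dt: float = 0.1,
) -> PropagationResult:
    """Steady current into the target layer with plasticity frozen.

    Returns the spike raster, the propagation count ``S`` (total spikes of
    all layers strictly right of the target during the test window) and the
    per-layer spike counts.  The network is not modified.
    """
    n_layers = network.geometry.n_layers
    if test.target_layer > n_layers:
        raise ValueError(f"target layer {test.target_layer} outside 1..{n_layers}")
    test = resolve_test(test, neuron, syn, dt=dt)
    stim = StimulusProgram.steady(
        np.flatnonzero(network.layer_of == test.target_layer), test.i_t, test.t_test
    )
    res = run(network, neuron, syn, stim, duration=test.t_test, dt=dt)
    per_layer = res.raster.layer_counts(network.layer_of, n_layers)
    total = int(per_layer[test.target_layer :].sum())
    return PropagationResult(
        raster=res.raster,
        total_spikes=total,
        per_layer=per_layer,
        i_t=float(test.i_t),
        target_layer=test.target_layer,
    )


def ablate(network: Network, drop: str) -> Network:
    """Copy of the network with a connection class removed from the support.

    ``drop`` is ``"feedback"``, ``"recurrent"`` or ``"both"`` (= feedback and
    recurrent).  Idempotent.
    """
    if drop == "both":
        mask = class_mask(network, FEEDBACK) | class_mask(network, RECURRENT)
    elif drop in (FEEDBACK, RECURRENT):
        mask = class_mask(network, drop)
    else:
        raise ValueError(f"unknown ablation class {drop!r}; expected feedback|recurrent|both")
    return network.subset(~mask)
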