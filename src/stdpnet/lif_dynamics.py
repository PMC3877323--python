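"""Clock-driven integrate-and-fire dynamics with alpha-conductance synapses.

The membrane potential of neuron ``i`` obeys

    tau_m dV_i/dt = (V_rest - V_i) + g * sum_j a_ji W_ji s_j(t) * (E_ex - V_i) + I_i(t)

where ``s_j`` is the superposition of alpha kernels triggered by the spikes
of presynaptic neuron ``j`` and ``I_i`` is an external current in
voltage-equivalent units (membrane resistance folded in).  When ``V_i``
reaches threshold the neuron emits a spike and is reset to rest; there is no
refractory period.

The alpha conductance is maintained by two per-neuron linear state
variables with exact exponential per-step updates, so overlapping spikes
superpose correctly.  The membrane equation is advanced by exponential
Euler with conductances frozen over the step, which is exact for constant
input and first-order accurate in general.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network_model import Network

__all__ = [
    "NeuronParams",
    "SynapseParams",
    "StimulusProgram",
    "SimulationState",
    "SpikeRaster",
    "RunResult",
    "SimulationError",
    "alpha_kernel",
    "step",
    "run",
]

NEVER = -np.inf  # sentinel for "has not spiked yet"


class SimulationError(RuntimeError):
    """Raised when the integration produces a non-finite state."""


@dataclass(frozen=True)
class NeuronParams:
    """Membrane parameters (V1-cell modelling conventions)."""

    tau_m: float = 20.0  # membrane time constant, ms
    v_rest: float = -70.0  # resting potential, mV
    v_th: float = -54.0  # firing threshold, mV
    e_ex: float = 0.0  # excitatory reversal potential, mV

    def __post_init__(self) -> None:
        if self.tau_m <= 0:
            raise ValueError("tau_m must be positive")
        if not self.v_rest < self.v_th < self.e_ex:
            raise ValueError("need v_rest < v_th < e_ex")


@dataclass(frozen=True)
class SynapseParams:
    g: float = 0.06  # constant synaptic conductance scale, dimensionless
    tau_alpha: float = 2.0  # alpha-function time constant, ms

    def __post_init__(self) -> None:
        if self.g < 0:
            raise ValueError("g must be non-negative")
        if self.tau_alpha <= 0:
            raise ValueError("tau_alpha must be positive")


def alpha_kernel(s: float | np.ndarray, tau_alpha: float) -> float | np.ndarray:
    """Unit-peak alpha function: ``(s/tau) * exp(1 - s/tau)`` for ``s >= 0``, else 0."""
    s = np.asarray(s, dtype=float)
    u = s / tau_alpha
    out = np.where(s >= 0, u * np.exp(1.0 - u), 0.0)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class StimulusInterval:
    """Constant current ``amplitude`` into ``neurons`` during ``[t_start, t_end)``."""

    neurons: np.ndarray
    t_start: float
    t_end: float
    amplitude: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "neurons", np.atleast_1d(np.asarray(self.neurons, int)))
        if not self.t_start < self.t_end:
            raise ValueError("need t_start < t_end")
        if not np.isfinite(self.amplitude):
            raise ValueError("amplitude must be finite")


@dataclass
class StimulusProgram:
    """Piecewise-constant per-neuron current program."""

    intervals: list[StimulusInterval] = field(default_factory=list)

    @classmethod
    def pulse(cls, neurons, t_start: float, duration: float, amplitude: float) -> "StimulusProgram":
        return cls([StimulusInterval(neurons, t_start, t_start + duration, amplitude)])

    @classmethod
    def steady(cls, neurons, amplitude: float, t_end: float, t_start: float = 0.0) -> "StimulusProgram":
        return cls([StimulusInterval(neurons, t_start, t_end, amplitude)])

    @classmethod
    def for_layer(
        cls, layer_of: np.ndarray, layer: int, t_start: float, duration: float, amplitude: float
    ) -> "StimulusProgram":
        neurons = np.flatnonzero(np.asarray(layer_of) == layer)
        if neurons.size == 0:
            raise ValueError(f"no neurons in layer {layer}")
        return cls.pulse(neurons, t_start, duration, amplitude)

    def __add__(self, other: "StimulusProgram") -> "StimulusProgram":
        return StimulusProgram(self.intervals + other.intervals)

    @property
    def t_last(self) -> float:
        """End time of the last interval (0 for the empty program)."""
        return max((iv.t_end for iv in self.intervals), default=0.0)

    def current(self, t: float, n: int, out: np.ndarray | None = None) -> np.ndarray:
        """Per-neuron current at time ``t`` (intervals are half-open ``[start, end)``)."""
        if out is None:
            out = np.zeros(n)
        else:
            out.fill(0.0)
        for iv in self.intervals:
            if iv.t_start <= t < iv.t_end:
                out[iv.neurons] += iv.amplitude
        return out


@dataclass
class SimulationState:
    """Mutable per-neuron state: potential, alpha-kernel variables, spike memory."""

    v: np.ndarray
    syn_x: np.ndarray  # impulse-fed auxiliary variable of the alpha kernel
    syn_s: np.ndarray  # conductance factor seen by postsynaptic neurons
    last_spike: np.ndarray  # most recent spike time, -inf if never
    t: float = 0.0

    @classmethod
    def at_rest(cls, n: int, neuron: NeuronParams) -> "SimulationState":
        return cls(
            v=np.full(n, neuron.v_rest, dtype=float),
            syn_x=np.zeros(n),
            syn_s=np.zeros(n),
            last_spike=np.full(n, NEVER),
            t=0.0,
        )

    def copy(self) -> "SimulationState":
        return SimulationState(
            self.v.copy(), self.syn_x.copy(), self.syn_s.copy(), self.last_spike.copy(), self.t
        )


@dataclass
class SpikeRaster:
    """Ordered spike events ``(neuron index, spike time in ms)``."""

    neurons: np.ndarray
    times: np.ndarray

    def __post_init__(self) -> None:
        self.neurons = np.asarray(self.neurons, dtype=int)
        self.times = np.asarray(self.times, dtype=float)
        if len(self.neurons) != len(self.times):
            raise ValueError("neurons and times must have equal length")
        if np.any(np.diff(self.times) < 0):
            raise ValueError("spike times must be non-decreasing")

    def __len__(self) -> int:
        return len(self.times)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"neuron_id": self.neurons + 1, "time_ms": self.times})

    def to_tsv(self, path) -> None:
        df = self.to_frame()
        df["time_ms"] = df["time_ms"].map(lambda t: f"{t:.4f}")
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "SpikeRaster":
        df = pd.read_csv(path, sep="\t")
        return cls(df["neuron_id"].to_numpy() - 1, df["time_ms"].to_numpy(float))

    def layer_counts(self, layer_of: np.ndarray, n_layers: int) -> np.ndarray:
        """Spike count per layer (index 0 = layer 1)."""
        if len(self) == 0:
            return np.zeros(n_layers, dtype=int)
        return np.bincount(
            np.asarray(layer_of)[self.neurons] - 1, minlength=n_layers
        ).astype(int)


@dataclass
class RunResult:
    raster: SpikeRaster
    state: SimulationState
    network: Network


def _advance(
    state: SimulationState,
    w_csr,
    neuron: NeuronParams,
    syn: SynapseParams,
    i_ext: np.ndarray,
    dt: float,
    decay: float,
    t_next: float,
) -> np.ndarray:
    """One integration step in place; returns indices of neurons spiking at step end.

    ``t_next`` is the step-end time, supplied by the caller rather than
    accumulated here so that long runs do not drift off the time grid
    (stimulus windows are half-open and grid alignment must be exact).
    """
    # exact update of the alpha-kernel pair over [t, t+dt]
    x_old = state.syn_x
    state.syn_s = decay * (state.syn_s + dt * x_old / syn.tau_alpha * np.e)
    state.syn_x = decay * x_old
    # conductance-weighted input, frozen over the step (exponential Euler)
    cond = syn.g * (w_csr @ state.syn_s)
    denom = 1.0 + cond
    v_inf = (neuron.v_rest + cond * neuron.e_ex + i_ext) / denom
    state.v = v_inf + (state.v - v_inf) * np.exp(-denom * dt / neuron.tau_m)
    if not np.all(np.isfinite(state.v)):
        bad = int(np.flatnonzero(~np.isfinite(state.v))[0])
        raise SimulationError(
            f"non-finite membrane potential for neuron {bad} at t={t_next:.4f} ms"
        )
    state.t = t_next
    fired = np.flatnonzero(state.v >= neuron.v_th)
    if fired.size:
        state.v[fired] = neuron.v_rest
        state.syn_x[fired] += 1.0  # scaled by e/tau_alpha in the s-update above
        state.last_spike[fired] = state.t
    return fired


def step(
    state: SimulationState,
    network: Network,
    neuron: NeuronParams,
    syn: SynapseParams,
    stimulus: StimulusProgram | None,
    dt: float = 0.1,
) -> tuple[SimulationState, np.ndarray]:
    """Advance the network one time step; returns ``(state, spiking neuron indices)``.

    Spikes are detected at step end: any neuron at or above threshold is
    recorded as spiking at ``t + dt`` and reset to rest.  For repeated
    stepping prefer :func:`run`, which hoists the per-call setup.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    w = network.csr_view()
    i_ext = (
        stimulus.current(state.t, network.n_neurons)
        if stimulus is not None
        else np.zeros(network.n_neurons)
    )
    decay = float(np.exp(-dt / syn.tau_alpha))
    fired = _advance(state, w, neuron, syn, i_ext, dt, decay, state.t + dt)
    return state, fired


def run(
    network: Network,
    neuron: NeuronParams,
    syn: SynapseParams,
    stimulus: StimulusProgram | None,
    duration: float,
    dt: float = 0.1,
    plasticity=None,
    state: SimulationState | None = None,
    quiescent_exit_after: float | None = None,
) -> RunResult:
    """Simulate for ``duration`` ms; optionally apply STDP at every spike.

    ``plasticity`` is an :class:`stdpnet.stdp.StdpParams`; when given, every
    spike triggers nearest-spike STDP updates of the spiking neuron's
    incoming and outgoing synapses (weights of ``network`` are modified in
    place) before integration continues.

    ``quiescent_exit_after``: once ``t`` exceeds this time *and* no neuron
    can possibly reach threshold any more (a conservative bound on the
    future synaptic drive), the run returns early.  The returned state is
    then the quiescent state at the exit time.  Used by the training
    protocol to avoid integrating dead settling time.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if dt <= 0:
        raise ValueError("dt must be positive")
    from . import stdp as _stdp  # local import to avoid a cycle

    if state is None:
        state = SimulationState.at_rest(network.n_neurons, neuron)
    w = network.csr_view()
    decay = float(np.exp(-dt / syn.tau_alpha))
    n = network.n_neurons
    i_ext = np.zeros(n)
    n_steps = int(round(duration / dt))
    ev_neurons: list[np.ndarray] = []
    ev_times: list[np.ndarray] = []
    check_every = max(1, int(round(1.0 / dt)))  # quiescence test every ~1 ms
    t_base = state.t
    for k in range(n_steps):
        # time computed from the step index: accumulation must not drift off
        # the grid, or half-open stimulus windows lose/gain whole steps
        t_now = t_base + k * dt
        if stimulus is not None:
            stimulus.current(t_now, n, out=i_ext)
        fired = _advance(state, w, neuron, syn, i_ext, dt, decay, t_base + (k + 1) * dt)
        if fired.size:
            ev_neurons.append(fired)
            ev_times.append(np.full(fired.size, state.t))
            if plasticity is not None:
                for i in fired:
                    _stdp.apply_on_spike(int(i), state.t, state.last_spike, network, plasticity)
        elif (
            quiescent_exit_after is not None
            and state.t >= quiescent_exit_after
            and k % check_every == 0
            and _quiescent(state, w, neuron, syn)
        ):
            break
    if ev_neurons:
        raster = SpikeRaster(np.concatenate(ev_neurons), np.concatenate(ev_times))
    else:
        raster = SpikeRaster(np.empty(0, int), np.empty(0))
    return RunResult(raster=raster, state=state, network=network)


def _quiescent(state: SimulationState, w_csr, neuron: NeuronParams, syn: SynapseParams) -> bool:
    """True if no neuron can reach threshold without further external input.

    Uses the bound ``max_t e^(-t/tau) (s + x e t / tau) <= s + x`` on the
    future alpha conductance of every presynaptic neuron, evaluated at the
    excitatory reversal potential; with all steady-state potentials below
    threshold and all current potentials below threshold, no spike can occur.
    """
    if np.any(state.v >= neuron.v_th):
        return False
    s_bound = state.syn_s + state.syn_x
    cond = syn.g * (w_csr @ s_bound)
    v_inf_bound = (neuron.v_rest + cond * neuron.e_ex) / (1.0 + cond)
    return bool(np.all(v_inf_bound < neuron.v_th))
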