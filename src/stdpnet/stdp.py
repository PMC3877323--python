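"""Nearest-spike pair-based STDP with hard weight bounds.

The weight change for a pre/post spike pair with lag ``dt = t_post - t_pre``
is an exponential function of the lag:

    dW = +A_plus  * exp(-dt / tau_plus)   for dt > 0   (pre before post)
    dW = -A_minus * exp(+dt / tau_minus)  for dt < 0   (post before pre)
    dW = +A_plus                          for dt = 0   (synchronous spikes)

Only the most recent spike of the partner neuron contributes (nearest-spike
rule, appropriate for the low-frequency stimulation regime), and every
updated weight is clipped into the hard bounds ``[w_min, w_max]``.

The rule is *temporally symmetric* when ``A_plus == A_minus`` and
``tau_plus == tau_minus``, and asymmetric otherwise.  Synchronous spikes
potentiate both directed synapses of a reciprocal pair, which is what
drives the strong growth of recurrent (intra-layer) weights under
synchronous within-layer stimulation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .network_model import Network

__all__ = ["StdpParams", "stdp_kernel", "apply_on_spike", "clip_weight"]


@dataclass(frozen=True)
class StdpParams:
    a_plus: float = 0.1  # potentiation amplitude per pairing, weight units
    a_minus: float = 0.1  # depression amplitude per pairing
    tau_plus: float = 20.0  # potentiation time constant, ms
    tau_minus: float = 20.0  # depression time constant, ms
    w_max: float = 1.0  # hard upper bound
    w_min: float = 0.0  # hard lower bound

    def __post_init__(self) -> None:
        if self.a_plus < 0 or self.a_minus < 0:
            raise ValueError("amplitudes must be non-negative")
        if self.tau_plus <= 0 or self.tau_minus <= 0:
            raise ValueError("time constants must be positive")
        if not self.w_min < self.w_max:
            raise ValueError("need w_min < w_max")

    @property
    def is_symmetric(self) -> bool:
        return self.a_plus == self.a_minus and self.tau_plus == self.tau_minus

    def asymmetric(self) -> "StdpParams":
        """Default temporally asymmetric variant: A-/A+ = 1.05, tau- = 2 tau+."""
        return replace(self, a_minus=1.05 * self.a_plus, tau_minus=2.0 * self.tau_plus)


def stdp_kernel(delta_t: float | np.ndarray, params: StdpParams) -> float | np.ndarray:
    """Weight change for a single pairing with lag ``delta_t = t_post - t_pre`` (ms)."""
    delta_t = np.asarray(delta_t, dtype=float)
    if not np.all(np.isfinite(delta_t)):
        raise ValueError("delta_t must be finite")
    causal = delta_t >= 0
    # single always-negative exponent avoids overflow for large |delta_t|
    exponent = np.where(causal, -delta_t / params.tau_plus, delta_t / params.tau_minus)
    out = np.where(causal, params.a_plus, -params.a_minus) * np.exp(exponent)
    return float(out) if out.ndim == 0 else out


def clip_weight(w: float | np.ndarray, params: StdpParams) -> float | np.ndarray:
    """Clip a weight into the hard bounds ``[w_min, w_max]``."""
    out = np.clip(w, params.w_min, params.w_max)
    return float(out) if np.ndim(out) == 0 else out


def apply_on_spike(
    i: int,
    t: float,
    last_spike: np.ndarray,
    network: Network,
    params: StdpParams,
) -> None:
    """Apply nearest-spike STDP for a spike of neuron ``i`` at time ``t`` in place.

    Caller contract: ``last_spike[i]`` has already been set to ``t`` (as have
    the entries of any neurons spiking simultaneously), and ``t`` is not
    earlier than any recorded spike time.

    * Incoming synapses ``j -> i`` with a recorded presynaptic spike
      ``t_j <= t`` are updated by ``kernel(t - t_j)`` — the potentiation
      path, including the synchronous case ``t_j == t``.
    * Outgoing synapses ``i -> j`` with a recorded postsynaptic spike
      strictly before ``t`` are updated by ``kernel(t_j - t)`` — the
      depression path.  Simultaneous partners are excluded: their own
      incoming pass applies the synchronous potentiation, so each directed
      synapse is touched exactly once per spike volley.

    Every touched weight is clipped into the hard bounds.
    """
    w = network.weights
    in_ids, pres = network.incoming(i)
    if in_ids.size:
        tj = last_spike[pres]
        has = tj > -np.inf
        if np.any(has):
            ids = in_ids[has]
            w[ids] = np.clip(
                w[ids] + stdp_kernel(t - tj[has], params), params.w_min, params.w_max
            )
    out_ids, posts = network.outgoing(i)
    if out_ids.size:
        tj = last_spike[posts]
        has = (tj > -np.inf) & (tj < t)
        if np.any(has):
            ids = out_ids[has]
            w[ids] = np.clip(
                w[ids] + stdp_kernel(tj[has] - t, params), params.w_min, params.w_max
            )
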