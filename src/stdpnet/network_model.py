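"""Spatial layered network: lattice geometry and distance-dependent connectivity.

Neurons sit on a regular lattice inside the unit square, organised into
vertical layers ordered left to right.  Each unordered pair of neurons is
connected with a probability that decays exponentially with their Euclidean
distance; a connected pair carries *two* directed synapses (one per
direction) with independent random initial weights.  The directed weights
are the quantity that spike-timing-dependent plasticity later evolves.

Synapses are classified relative to the layer order: *feedforward* (pre in a
layer left of post), *feedback* (pre right of post) and *recurrent*
(same layer).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.spatial.distance import pdist

__all__ = [
    "GeometryConfig",
    "ConnectivityConfig",
    "Network",
    "FEEDFORWARD",
    "FEEDBACK",
    "RECURRENT",
    "SYNAPSE_CLASSES",
    "build_lattice",
    "connection_probability",
    "generate_network",
    "classify_synapse",
    "classify_synapses",
]

FEEDFORWARD = "feedforward"
FEEDBACK = "feedback"
RECURRENT = "recurrent"
SYNAPSE_CLASSES = (FEEDFORWARD, FEEDBACK, RECURRENT)


@dataclass(frozen=True)
class GeometryConfig:
    """Lattice geometry: ``n_layers`` columns of ``per_layer`` neurons in a unit square.

    The side length of the square is the distance unit; layer ``l`` occupies
    the column centred at ``x = (l - 0.5) / n_layers``.
    """

    n_layers: int = 50
    per_layer: int = 20
    side: float = 1.0

    def __post_init__(self) -> None:
        if self.n_layers < 2:
            raise ValueError("n_layers must be >= 2 (training needs a layer pair)")
        if self.per_layer < 1:
            raise ValueError("per_layer must be >= 1")
        if self.side != 1.0:
            raise ValueError("side is fixed at 1.0 (distances are in side units)")

    @property
    def n_neurons(self) -> int:
        return self.n_layers * self.per_layer

    @property
    def layer_spacing(self) -> float:
        """Horizontal distance between adjacent layers, in side units."""
        return self.side / self.n_layers


@dataclass(frozen=True)
class ConnectivityConfig:
    """Distance-dependent connection rule ``p(d) = k * exp(-d / lambda_c)``.

    ``lambda_c`` defaults to one inter-layer spacing of the default geometry
    (0.02 side units at 50 layers) so that adjacent-layer pairs dominate the
    connectivity; see docs/methods.md for the rationale.  Initial directed
    weights are drawn uniformly from ``[w_init_low, w_init_high]``.
    """

    k: float = 0.2
    lambda_c: float = 0.02
    w_init_low: float = 0.0
    w_init_high: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.k <= 1.0:
            raise ValueError("k must lie in [0, 1]")
        if self.lambda_c <= 0:
            raise ValueError("lambda_c must be positive")
        if not 0.0 <= self.w_init_low < self.w_init_high:
            raise ValueError("need 0 <= w_init_low < w_init_high")


def build_lattice(geometry: GeometryConfig) -> tuple[np.ndarray, np.ndarray]:
    """Place neurons at cell centres of the unit square, indexed left to right.

    Returns ``(positions, layer_of)`` where ``positions`` is an ``(N, 2)``
    array of ``(x, y)`` coordinates and ``layer_of`` maps each neuron to its
    1-based layer.  Neuron ``m`` (0-based) lives in layer ``m // per_layer + 1``,
    so layer ``l`` spans 0-based indices ``(l-1)*per_layer .. l*per_layer - 1``.
    """
    n_layers, per_layer = geometry.n_layers, geometry.per_layer
    m = np.arange(geometry.n_neurons)
    layer_of = m // per_layer + 1
    row = m % per_layer + 1
    x = (layer_of - 0.5) / n_layers
    y = (row - 0.5) / per_layer
    return np.column_stack([x, y]), layer_of


def connection_probability(
    d: float | np.ndarray, cfg: ConnectivityConfig
) -> float | np.ndarray:
    """Connection probability at distance ``d``: ``min(k * exp(-d/lambda_c), 1)``."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    p = np.minimum(cfg.k * np.exp(-d / cfg.lambda_c), 1.0)
    return float(p) if p.ndim == 0 else p


@dataclass
class Network:
    """A directed weighted network on the lattice.

    Synapse arrays (``pre``, ``post``, ``weights``) are kept in canonical
    order, sorted by ``(post, pre)``, which is exactly CSR order for the
    weight matrix ``W[post, pre]``.  ``csr_view`` therefore returns a sparse
    matrix whose ``data`` aliases ``weights``: in-place weight updates are
    immediately visible to the simulator's matrix-vector products.

    The adjacency support is symmetric as an undirected relation (``j -> i``
    exists iff ``i -> j`` exists); the two directed weights are independent.
    """

    geometry: GeometryConfig
    positions: np.ndarray
    layer_of: np.ndarray
    pre: np.ndarray
    post: np.ndarray
    weights: np.ndarray
    _in_indptr: np.ndarray | None = field(default=None, repr=False, compare=False)
    _out_order: np.ndarray | None = field(default=None, repr=False, compare=False)
    _out_indptr: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        n = self.geometry.n_neurons
        if len(self.positions) != n or len(self.layer_of) != n:
            raise ValueError("positions/layer_of length does not match geometry")
        if not (len(self.pre) == len(self.post) == len(self.weights)):
            raise ValueError("synapse arrays must have equal length")
        if np.any(self.pre == self.post):
            raise ValueError("self-loops are not allowed")
        order = np.lexsort((self.pre, self.post))
        if not np.array_equal(order, np.arange(len(order))):
            self.pre = self.pre[order]
            self.post = self.post[order]
            self.weights = np.asarray(self.weights, dtype=float)[order]
        self.weights = np.asarray(self.weights, dtype=float)

    @property
    def n_neurons(self) -> int:
        return self.geometry.n_neurons

    @property
    def n_synapses(self) -> int:
        return len(self.weights)

    def _build_index(self) -> None:
        n = self.n_neurons
        self._in_indptr = np.searchsorted(self.post, np.arange(n + 1))
        self._out_order = np.argsort(self.pre, kind="stable")
        self._out_indptr = np.searchsorted(self.pre[self._out_order], np.arange(n + 1))

    def incoming(self, i: int) -> tuple[np.ndarray, np.ndarray]:
        """Synapse ids and presynaptic neuron ids of all synapses ``j -> i``."""
        if self._in_indptr is None:
            self._build_index()
        ids = np.arange(self._in_indptr[i], self._in_indptr[i + 1])
        return ids, self.pre[ids]

    def outgoing(self, i: int) -> tuple[np.ndarray, np.ndarray]:
        """Synapse ids and postsynaptic neuron ids of all synapses ``i -> j``."""
        if self._out_indptr is None:
            self._build_index()
        ids = self._out_order[self._out_indptr[i] : self._out_indptr[i + 1]]
        return ids, self.post[ids]

    def csr_view(self) -> sparse.csr_matrix:
        """CSR matrix ``W[post, pre]`` whose data aliases ``self.weights``."""
        if self._in_indptr is None:
            self._build_index()
        n = self.n_neurons
        return sparse.csr_matrix(
            (self.weights, self.pre, self._in_indptr), shape=(n, n), copy=False
        )

    def weight_matrix(self) -> sparse.csr_matrix:
        """Independent copy of the weight matrix ``W[post, pre]``."""
        m = self.csr_view().copy()
        return m

    def copy(self) -> "Network":
        return Network(
            geometry=self.geometry,
            positions=self.positions,
            layer_of=self.layer_of,
            pre=self.pre.copy(),
            post=self.post.copy(),
            weights=self.weights.copy(),
        )

    def subset(self, keep: np.ndarray) -> "Network":
        """Copy with only the synapses selected by boolean mask ``keep``."""
        keep = np.asarray(keep, dtype=bool)
        return Network(
            geometry=self.geometry,
            positions=self.positions,
            layer_of=self.layer_of,
            pre=self.pre[keep],
            post=self.post[keep],
            weights=self.weights[keep].copy(),
        )


def generate_network(
    geometry: GeometryConfig,
    connectivity: ConnectivityConfig,
    seed: int | np.random.Generator,
) -> Network:
    """Draw a network: one Bernoulli trial per unordered pair, reciprocal synapses.

    For each unordered pair at distance ``d`` a single Bernoulli draw with
    ``p = connection_probability(d)`` decides whether the pair is connected;
    on success both directed synapses are created with independent uniform
    initial weights.  Deterministic given the seed.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    positions, layer_of = build_lattice(geometry)
    n = geometry.n_neurons
    d = pdist(positions)
    p = connection_probability(d, connectivity)
    hit = rng.random(p.shape) < p
    iu, ju = np.triu_indices(n, k=1)
    i_sel, j_sel = iu[hit], ju[hit]
    pre = np.concatenate([i_sel, j_sel])
    post = np.concatenate([j_sel, i_sel])
    weights = rng.uniform(connectivity.w_init_low, connectivity.w_init_high, size=len(pre))
    return Network(
        geometry=geometry,
        positions=positions,
        layer_of=layer_of,
        pre=pre,
        post=post,
        weights=weights,
    )


def classify_synapse(pre_neuron: int, post_neuron: int, geometry_or_layers) -> str:
    """Class of the directed synapse ``pre -> post``.

    ``geometry_or_layers`` is either a :class:`GeometryConfig` (layers derived
    from index arithmetic) or a per-neuron layer array.
    """
    if isinstance(geometry_or_layers, GeometryConfig):
        _, layer_of = build_lattice(geometry_or_layers)
    else:
        layer_of = np.asarray(geometry_or_layers)
    n = len(layer_of)
    for idx in (pre_neuron, post_neuron):
        if not 0 <= idx < n:
            raise IndexError(f"neuron index {idx} outside network of size {n}")
    lp, lq = layer_of[pre_neuron], layer_of[post_neuron]
    if lp < lq:
        return FEEDFORWARD
    if lp > lq:
        return FEEDBACK
    return RECURRENT


def classify_synapses(network: Network) -> np.ndarray:
    """Vectorised synapse classification; returns an array of class labels."""
    lp = network.layer_of[network.pre]
    lq = network.layer_of[network.post]
    out = np.full(network.n_synapses, RECURRENT, dtype=object)
    out[lp < lq] = FEEDFORWARD
    out[lp > lq] = FEEDBACK
    return out


def class_mask(network: Network, cls: str) -> np.ndarray:
    """Boolean mask over synapses belonging to connection class ``cls``."""
    if cls not in SYNAPSE_CLASSES:
        raise ValueError(f"unknown synapse class {cls!r}; expected one of {SYNAPSE_CLASSES}")
    lp = network.layer_of[network.pre]
    lq = network.layer_of[network.post]
    if cls == FEEDFORWARD:
        return lp < lq
    if cls == FEEDBACK:
        return lp > lq
    return lp == lq
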