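"""Network architecture: clustered RNN plus read-out layer.

Two subnetworks: a recurrent network of ``N_E`` excitatory neurons (divided
uniformly into ``N_C`` clusters) and ``N_I`` inhibitory neurons, randomly
connected with per-class probability; and a read-out layer of ``N_R``
read-out neurons (R), each with exactly one supervisor (S) and one
interneuron (H) afferent, receiving all-to-all plastic connections from the
excitatory RNN neurons (RE).

Connection classes are named ``target<-source``: EE, IE (E->I), EI (I->E),
II, RE (E->R), SR (S->R), HR (H->R).  Autapses and multapses are excluded;
there are no R->R connections.  The edge set is immutable after
construction -- plasticity changes magnitudes only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import ConfigError, SimulationConfig

__all__ = [
    "NetworkTopology",
    "SynapseState",
    "assign_clusters",
    "build_connectivity",
    "init_weights",
]

RNN_CLASSES = ("EE", "EI", "IE", "II")
ALL_CLASSES = RNN_CLASSES + ("RE", "SR", "HR")


@dataclass
class NetworkTopology:
    """Populations, cluster labels, and per-class adjacency masks.

    ``adjacency[cls]`` is a boolean matrix of shape (n_target, n_source);
    entry (i, j) is True iff an edge j -> i exists.  ``delay_ms`` is the
    synaptic delay shared by the recurrent classes.
    """

    N_E: int
    N_I: int
    N_C: int
    N_R: int
    cluster_label: np.ndarray  # (N_E,) int
    adjacency: dict[str, np.ndarray] = field(default_factory=dict)
    delay_ms: float = 1.0

    @property
    def cluster_size(self) -> int:
        return self.N_E // self.N_C

    def neurons_of_cluster(self, c: int) -> np.ndarray:
        return np.nonzero(self.cluster_label == c)[0]


@dataclass
class SynapseState:
    """Per-class weight matrices with bounds, plastic flags and the
    normalization targets K (fixed at initialization, never mutated)."""

    W: dict[str, np.ndarray]
    W_min: dict[str, float]
    W_max: dict[str, float]
    plastic: dict[str, bool]
    K: np.ndarray  # (N_E,) initial incoming EE sum per E neuron
    frozen: bool = False

    def copy(self) -> "SynapseState":
        return SynapseState(
            W={k: v.copy() for k, v in self.W.items()},
            W_min=dict(self.W_min),
            W_max=dict(self.W_max),
            plastic=dict(self.plastic),
            K=self.K.copy(),
            frozen=self.frozen,
        )


def assign_clusters(N_E: int, N_C: int) -> np.ndarray:
    """Divide N_E excitatory neurons uniformly into N_C contiguous clusters.

    Labels ascend with neuron index in blocks of N_E/N_C so the learned block
    structure is visible in raw matrix order.  Raises ConfigError if N_E is
    not divisible by N_C (never truncates).
    """
    if N_E <= 0 or N_C <= 0:
        raise ConfigError(f"assign_clusters: N_E={N_E} and N_C={N_C} must be > 0")
    if N_E % N_C != 0:
        raise ConfigError(
            f"assign_clusters: N_E={N_E} is not divisible by N_C={N_C}; "
            "clusters must be of equal size"
        )
    return np.repeat(np.arange(N_C, dtype=np.int64), N_E // N_C)


def _random_adjacency(
    n_tgt: int, n_src: int, p: float, rng: np.random.Generator, same_population: bool
) -> np.ndarray:
    adj = rng.random((n_tgt, n_src)) < p
    if same_population:
        np.fill_diagonal(adj, False)  # no autapses
    return adj


def build_connectivity(cfg: SimulationConfig, rng: np.random.Generator | int) -> NetworkTopology:
    """Build the random RNN connectivity and the deterministic read-out wiring.

    Each ordered pair of distinct RNN neurons carries an edge independently
    with its class probability.  RE is complete bipartite (all E -> all R);
    read-out neuron k receives exactly supervisor k and interneuron k.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    net = cfg.network
    labels = assign_clusters(net.N_E, net.N_C)
    adj = {
        "EE": _random_adjacency(net.N_E, net.N_E, net.p_EE, rng, True),
        "EI": _random_adjacency(net.N_E, net.N_I, net.p_EI, rng, False),
        "IE": _random_adjacency(net.N_I, net.N_E, net.p_IE, rng, False),
        "II": _random_adjacency(net.N_I, net.N_I, net.p_II, rng, True),
        "RE": np.ones((net.N_R, net.N_E), dtype=bool),
        "SR": np.eye(net.N_R, dtype=bool),
        "HR": np.eye(net.N_R, dtype=bool),
    }
    return NetworkTopology(
        N_E=net.N_E,
        N_I=net.N_I,
        N_C=net.N_C,
        N_R=net.N_R,
        cluster_label=labels,
        adjacency=adj,
        delay_ms=cfg.weights.delay,
    )


def init_weights(topology: NetworkTopology, cfg: SimulationConfig) -> SynapseState:
    """Initialize every edge of a class to one scalar weight and fix K.

    K_i is the realized incoming EE weight sum of neuron i at initialization;
    it is computed once here and never mutated afterwards.  Initial weights of
    plastic classes must lie within their bounds (ConfigError otherwise; this
    is also enforced by config validation).
    """
    w = cfg.weights
    init = {
        "EE": w.w_EE, "EI": w.w_EI, "IE": w.w_IE, "II": w.w_II,
        "RE": w.w_RE, "SR": w.w_SR, "HR": w.w_HR,
    }
    lo = {"EE": w.w_EE_min, "EI": w.w_EI_min, "RE": w.w_RE_min}
    hi = {"EE": w.w_EE_max, "EI": w.w_EI_max, "RE": w.w_RE_max}
    plastic = {c: c in ("EE", "EI", "RE") for c in ALL_CLASSES}
    for c in ("EE", "EI", "RE"):
        if not lo[c] <= init[c] <= hi[c]:
            raise ConfigError(
                f"init_weights: class {c} initial weight {init[c]} outside "
                f"plastic bounds [{lo[c]}, {hi[c]}]"
            )
    W = {
        c: np.where(topology.adjacency[c], init[c], 0.0).astype(np.float64)
        for c in ALL_CLASSES
    }
    K = W["EE"].sum(axis=1)
    return SynapseState(
        W=W,
        W_min={c: lo.get(c, 0.0) for c in ALL_CLASSES},
        W_max={c: hi.get(c, np.inf) for c in ALL_CLASSES},
        plastic=plastic,
        K=K,
        frozen=False,
    )
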