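"""Deterministic synthetic inputs for tests and demos.

Everything here is reproducible from (parameters, seed) alone and generated
at run time -- idealized ring weight matrices with known spectra, ground-truth
sequential rasters for the clock metrics, and scripted voltage/spike
scenarios that serve as oracle inputs for the plasticity rules.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .engine import SpikeRecord

__all__ = [
    "make_ring_matrix",
    "make_sequential_raster",
    "PlasticityScenario",
    "make_plasticity_scenario",
]


def make_ring_matrix(N_C: int, m: int, w_intra: float, w_ff: float) -> np.ndarray:
    """Idealized block-cyclic weight matrix of N_C clusters of size m.

    Diagonal blocks carry ``w_intra``; superdiagonal blocks (cluster i ->
    i+1, wrap-around) carry ``w_ff``; everything else is zero.  Its nonzero
    eigenvalues are m*w_ff*(N_C-th roots of unity) shifted by m*w_intra
    (block-circulant closed form), which makes it the reference object for
    the leading-ring spectrum.
    """
    if N_C <= 0 or m <= 0:
        raise ValueError("N_C and m must be positive")
    ones = np.ones((m, m))
    W = np.zeros((N_C * m, N_C * m))
    for c in range(N_C):
        sl = slice(c * m, (c + 1) * m)
        tgt = slice(((c + 1) % N_C) * m, ((c + 1) % N_C + 1) * m)
        W[sl, sl] = w_intra * ones
        W[tgt, sl] = w_ff * ones
    return W


def make_sequential_raster(
    N_C: int,
    per_cluster_ms: float,
    n_cycles: int,
    jitter_ms: float = 0.0,
    rng: np.random.Generator | int = 0,
    *,
    neurons_per_cluster: int = 5,
    spikes_per_window: int = 8,
) -> tuple[SpikeRecord, np.ndarray]:
    """Ground-truth raster: cluster c's neurons fire in window c of each cycle.

    Returns (record, cluster labels).  With zero jitter the clock metrics
    recover the period N_C*per_cluster_ms exactly.
    """
    if per_cluster_ms <= 0:
        raise ValueError("per_cluster_ms must be positive")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    n_e = N_C * neurons_per_cluster
    labels = np.repeat(np.arange(N_C), neurons_per_cluster)
    ids, times = [], []
    period = N_C * per_cluster_ms
    for k in range(n_cycles):
        for c in range(N_C):
            w0 = k * period + c * per_cluster_ms
            for j in range(neurons_per_cluster):
                tt = w0 + (np.arange(spikes_per_window) + 0.5) * (
                    per_cluster_ms / spikes_per_window)
                if jitter_ms > 0:
                    tt = tt + rng.normal(0.0, jitter_ms, size=len(tt))
                for t in tt:
                    if 0.0 <= t:
                        ids.append(c * neurons_per_cluster + j)
                        times.append(t)
    order = np.argsort(times, kind="stable")
    rec = SpikeRecord(
        np.asarray(times, dtype=float)[order],
        np.asarray(ids, dtype=np.int32)[order],
        {"E": (0, n_e)},
    )
    return rec, labels


@dataclass
class PlasticityScenario:
    """Scripted postsynaptic voltages and spike trains on a coarse grid.

    ``V`` is piecewise-constant per coarse step (shape (n_steps, n_post));
    ``pre``/``post`` mark spikes delivered at coarse step starts / detected
    at coarse step ends.  ``refine(k)`` returns the same scenario on a k-fold
    finer grid (voltages repeated, spikes at the same absolute times), which
    is what dense-grid reference integrators consume.
    """

    dt: float
    V: np.ndarray
    pre: np.ndarray  # (n_steps, n_pre) spike counts at step starts
    post: np.ndarray  # (n_steps, n_post) spike counts at step ends

    @property
    def n_steps(self) -> int:
        return self.V.shape[0]

    def refine(self, k: int) -> "PlasticityScenario":
        V = np.repeat(self.V, k, axis=0)
        pre = np.zeros((self.n_steps * k, self.pre.shape[1]), dtype=self.pre.dtype)
        pre[::k] = self.pre
        post = np.zeros((self.n_steps * k, self.post.shape[1]), dtype=self.post.dtype)
        post[k - 1::k] = self.post
        return PlasticityScenario(self.dt / k, V, pre, post)


def make_plasticity_scenario(
    rng: np.random.Generator | int,
    *,
    T_ms: float = 200.0,
    dt: float = 0.1,
    n_post: int = 1,
    n_pre: int = 1,
    segment_ms: float = 5.0,
    v_range: tuple[float, float] = (-80.0, -40.0),
    pre_rate_hz: float = 25.0,
    post_rate_hz: float = 12.0,
) -> PlasticityScenario:
    """Random scenario: voltage steps every ``segment_ms``, Poisson spikes.

    Voltage levels straddle the plasticity thresholds so depression,
    potentiation and both rectifier branches are all exercised.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    n_steps = int(round(T_ms / dt))
    seg_steps = int(round(segment_ms / dt))
    n_seg = -(-n_steps // seg_steps)
    levels = rng.uniform(v_range[0], v_range[1], size=(n_seg, n_post))
    V = np.repeat(levels, seg_steps, axis=0)[:n_steps]
    pre = rng.poisson(pre_rate_hz * dt * 1e-3, size=(n_steps, n_pre))
    post = rng.poisson(post_rate_hz * dt * 1e-3, size=(n_steps, n_post))
    return PlasticityScenario(dt, V, pre, post)
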