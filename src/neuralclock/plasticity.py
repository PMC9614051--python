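"""Learning rules: voltage-based STDP, inhibitory plasticity, normalization.

Three rules act on the plastic connection classes:

* **Voltage-based STDP** (EE and RE).  Depression is a jump per presynaptic
  spike (delivered with delay d), gated by the slow low-pass ``u`` of the
  postsynaptic voltage above ``theta_LTD``.  Potentiation is continuous,
  proportional to the presynaptic spike trace ``x`` and active only while the
  instantaneous postsynaptic voltage exceeds ``theta_LTP`` and its fast
  low-pass ``v`` exceeds ``theta_LTD``.
* **Inhibitory plasticity** (EI, i.e. I -> E).  Symmetric spike-triggered
  rule: each presynaptic (I) spike changes the weight by
  ``A_inh * (y_i^E - 2 alpha r0 tau_y)`` and each postsynaptic (E) spike by
  ``A_inh * y_j^I``, pushing excitatory firing toward the target rate r0.
* **Synaptic normalization** (EE).  At regular intervals every neuron's
  incoming EE weights are shifted subtractively so their sum returns exactly
  to its initial value K.

Spike-train terms are integrated as per-spike jumps (Dirac impulses), never
as rate*dt products, so the accumulated spike-triggered change is invariant
under refinement of the simulation step.  The continuous potentiation term
is integrated in closed form over each step under the convention that the
postsynaptic voltage V is constant within a step (its value at the step
start) while the traces x and v relax exponentially; per-step updates are
therefore exact for piecewise-constant voltage scenarios.

Step conventions (shared with the engine, time t = step start):
1. delivered presynaptic spikes act first: depression jumps read u(t), the
   inhibitory presynaptic term reads y^E(t), and the presynaptic traces x
   jump by alpha;
2. potentiation is integrated over [t, t+dt) from the post-jump x;
3. all traces then relax/decay to t+dt;
4. postsynaptic spikes detected in this step (nominal time t+dt) trigger the
   inhibitory postsynaptic term reading y^I(t+dt) (after decay and after
   coincident inhibitory jumps), and increment their own y traces.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .config import InhibPlasticityParams, VoltageSTDPParams

__all__ = [
    "TraceState",
    "update_voltage_traces",
    "update_spike_traces",
    "voltage_stdp_step",
    "inhibitory_plasticity_step",
    "normalize_incoming",
    "ltd_jump",
    "ltp_row_factor",
    "inhib_offset",
    "normalize_rows",
]


# ---------------------------------------------------------------------------
# jitted primitives (the engine calls exactly these)
# ---------------------------------------------------------------------------

@njit(cache=True, inline="always")
def ltd_jump(u: float, theta_LTD: float, A_LTD: float) -> float:
    """Depression jump per delivered presynaptic spike: -A_LTD R(u - theta)."""
    r = u - theta_LTD
    return -A_LTD * r if r > 0.0 else 0.0


@njit(cache=True, inline="always")
def _pos_part_integral(A: float, B: float, s0: float, s1: float,
                       tau_x: float, tau_p: float) -> float:
    # integral over [s0, s1] of e^{-s/tau_x} * (A + B e^{-s/tau_v})
    # with 1/tau_p = 1/tau_x + 1/tau_v
    return A * tau_x * (np.exp(-s0 / tau_x) - np.exp(-s1 / tau_x)) + \
        B * tau_p * (np.exp(-s0 / tau_p) - np.exp(-s1 / tau_p))


@njit(cache=True)
def ltp_row_factor(V: float, v0: float, dt: float,
                   tau_x: float, tau_v: float,
                   theta_LTP: float, theta_LTD: float, A_LTP: float) -> float:
    """Closed-form potentiation increment per unit of presynaptic trace.

    Returns F such that the weight gains F * x_j(t) over one step, where
    x_j(t) is the presynaptic trace at the step start (after spike jumps).
    V is held at its step-start value; v relaxes toward V from v0; x decays.
    The rectifier on v changes sign at most once per step (v is monotonic),
    and the crossing is handled exactly.
    """
    c1 = V - theta_LTP
    if c1 <= 0.0:
        return 0.0
    A = V - theta_LTD
    B = v0 - V
    tau_p = 1.0 / (1.0 / tau_x + 1.0 / tau_v)
    g0 = A + B                          # v(0) - theta_LTD
    g1 = A + B * np.exp(-dt / tau_v)    # v(dt) - theta_LTD
    if g0 <= 0.0 and g1 <= 0.0:
        return 0.0
    if g0 > 0.0 and g1 > 0.0:
        integral = _pos_part_integral(A, B, 0.0, dt, tau_x, tau_p)
    else:
        s_star = -tau_v * np.log(-A / B)  # sign change of A + B e^{-s/tau_v}
        if g0 > 0.0:
            integral = _pos_part_integral(A, B, 0.0, s_star, tau_x, tau_p)
        else:
            integral = _pos_part_integral(A, B, s_star, dt, tau_x, tau_p)
    return A_LTP * c1 * integral


@njit(cache=True, inline="always")
def inhib_presyn_jump(yE: float, A_inh: float, offset: float) -> float:
    return A_inh * (yE - offset)


@njit(cache=True, inline="always")
def inhib_postsyn_jump(yI: float, A_inh: float) -> float:
    return A_inh * yI


def inhib_offset(p: InhibPlasticityParams) -> float:
    """Depression offset 2 alpha r0 tau_y of the target-rate rule."""
    return 2.0 * p.alpha * p.r0 * p.tau_y


@njit(cache=True)
def normalize_rows(W: np.ndarray, mask: np.ndarray, K: np.ndarray,
                   w_min: float, w_max: float) -> int:
    """Subtractive row normalization followed by bound clipping.

    For each target neuron i with l_i > 0 incoming edges, subtracts
    ((sum_k W_ik) - K_i) / l_i from every existing incoming weight; the row
    sum then equals K_i to machine precision before clipping.  Returns the
    number of clipped entries (clipping is applied after the subtraction and
    may re-introduce a small sum deviation, which is reported, not fixed).
    """
    n_post, n_pre = W.shape
    clipped = 0
    for i in range(n_post):
        s = 0.0
        l = 0
        for j in range(n_pre):
            if mask[i, j]:
                s += W[i, j]
                l += 1
        if l == 0:
            continue
        corr = (s - K[i]) / l
        if corr != 0.0:
            for j in range(n_pre):
                if mask[i, j]:
                    W[i, j] -= corr
        for j in range(n_pre):
            if mask[i, j]:
                if W[i, j] < w_min:
                    W[i, j] = w_min
                    clipped += 1
                elif W[i, j] > w_max:
                    W[i, j] = w_max
                    clipped += 1
    return clipped


# ---------------------------------------------------------------------------
# array-level operations (unit-test / scenario API; engine mirrors these)
# ---------------------------------------------------------------------------

@dataclass
class TraceState:
    """Low-pass traces for a set of postsynaptic and presynaptic neurons.

    u, v: filtered membrane potentials (mV) per postsynaptic neuron;
    x: presynaptic spike trace per presynaptic neuron (driven by delayed
    spikes); y_E, y_I: spike-rate traces used by the inhibitory rule.
    """

    u: np.ndarray
    v: np.ndarray
    x: np.ndarray
    y_E: np.ndarray = field(default_factory=lambda: np.zeros(0))
    y_I: np.ndarray = field(default_factory=lambda: np.zeros(0))

    @classmethod
    def zeros(cls, n_post: int, n_pre: int, V_rest: float = -70.0) -> "TraceState":
        return cls(
            u=np.full(n_post, V_rest), v=np.full(n_post, V_rest),
            x=np.zeros(n_pre), y_E=np.zeros(n_post), y_I=np.zeros(n_pre),
        )


def update_voltage_traces(traces: TraceState, V: np.ndarray, dt: float,
                          p: VoltageSTDPParams) -> TraceState:
    """Relax u and v toward the current membrane potential (exact update)."""
    if dt <= 0:
        raise ValueError("dt must be > 0")
    ku = np.exp(-dt / p.tau_u)
    kv = np.exp(-dt / p.tau_v)
    traces.u = V + (traces.u - V) * ku
    traces.v = V + (traces.v - V) * kv
    return traces


def update_spike_traces(traces: TraceState, spikes: np.ndarray, dt: float,
                        tau_x: float, alpha: float = 1.0) -> TraceState:
    """Jump x by alpha per spike (impulse semantics), then decay by dt."""
    traces.x = (traces.x + alpha * spikes) * np.exp(-dt / tau_x)
    return traces


def voltage_stdp_step(
    W: np.ndarray,
    mask: np.ndarray | None,
    traces: TraceState,
    V: np.ndarray,
    pre_spikes_delayed: np.ndarray,
    dt: float,
    p: VoltageSTDPParams,
    *,
    tau_x: float | None = None,
    w_min: float = -np.inf,
    w_max: float = np.inf,
) -> tuple[np.ndarray, int]:
    """One plasticity step of the voltage-based STDP rule.

    Applies the depression jumps for the delivered presynaptic spikes, jumps
    the presynaptic traces, integrates the potentiation term in closed form
    over the step, updates u/v/x to the end of the step, and clips to bounds.
    Returns (weight increment actually applied, number of clipped entries).
    ``W`` is updated in place; ``mask`` restricts updates to existing edges
    (None means all-to-all, as for the RE class).
    """
    if tau_x is None:
        tau_x = p.tau_x_EE
    n_post, n_pre = W.shape
    m = np.ones_like(W, dtype=bool) if mask is None else mask
    W_before = W.copy()

    # 1) depression jumps + presynaptic trace jumps at the step start
    pre = np.asarray(pre_spikes_delayed, dtype=float)
    if pre.any():
        ltd = -p.A_LTD * np.maximum(traces.u - p.theta_LTD, 0.0)  # per post
        W += m * np.outer(ltd, pre)
        traces.x = traces.x + p.alpha * pre

    # 2) closed-form potentiation over [t, t+dt)
    F = np.array([
        ltp_row_factor(V[i], traces.v[i], dt, tau_x, p.tau_v,
                       p.theta_LTP, p.theta_LTD, p.A_LTP)
        for i in range(n_post)
    ])
    if F.any():
        W += m * np.outer(F, traces.x)

    # 3) traces to end of step
    ku = np.exp(-dt / p.tau_u)
    kv = np.exp(-dt / p.tau_v)
    traces.u = V + (traces.u - V) * ku
    traces.v = V + (traces.v - V) * kv
    traces.x = traces.x * np.exp(-dt / tau_x)

    # 4) clip (silent but counted)
    lo = np.clip(W, w_min, w_max)
    n_clip = int(np.sum((lo != W) & m))
    W[...] = np.where(m, lo, 0.0)
    return W - W_before, n_clip


def inhibitory_plasticity_step(
    W_EI: np.ndarray,
    mask: np.ndarray | None,
    traces: TraceState,
    pre_spikes_delayed: np.ndarray,
    post_spikes: np.ndarray,
    dt: float,
    p: InhibPlasticityParams,
    *,
    w_min: float = -np.inf,
    w_max: float = np.inf,
) -> tuple[np.ndarray, int]:
    """One step of the target-rate inhibitory rule (all terms spike jumps).

    Presynaptic (I) spikes delivered this step add A_inh (y^E - 2 alpha r0
    tau_y) reading y^E at the step start; the y traces then decay; I spikes
    increment y^I; postsynaptic (E) spikes (nominal time t+dt) add
    A_inh y^I reading the post-decay, post-jump trace, then increment y^E.
    Returns (applied increment, clip count); ``W_EI`` updated in place.
    """
    m = np.ones_like(W_EI, dtype=bool) if mask is None else mask
    W_before = W_EI.copy()
    offset = inhib_offset(p)

    pre = np.asarray(pre_spikes_delayed, dtype=float)
    if pre.any():
        W_EI += m * np.outer(p.A_inh * (traces.y_E - offset), pre)

    ky = np.exp(-dt / p.tau_y)
    traces.y_E = traces.y_E * ky
    traces.y_I = (traces.y_I + p.alpha * pre) * ky

    post = np.asarray(post_spikes, dtype=float)
    if post.any():
        W_EI += m * np.outer(post, p.A_inh * traces.y_I)
        traces.y_E = traces.y_E + p.alpha * post

    lo = np.clip(W_EI, w_min, w_max)
    n_clip = int(np.sum((lo != W_EI) & m))
    W_EI[...] = np.where(m, lo, 0.0)
    return W_EI - W_before, n_clip


def normalize_incoming(
    W_EE: np.ndarray,
    K: np.ndarray,
    mask: np.ndarray,
    *,
    w_min: float = -np.inf,
    w_max: float = np.inf,
) -> tuple[np.ndarray, int]:
    """Return each neuron's incoming EE sum to K by subtractive correction.

    Neurons without incoming edges are skipped.  After the subtraction and
    before clipping, every row sum equals K exactly (machine precision).
    ``W_EE`` is updated in place; returns (W_EE, clip count).
    """
    if W_EE.shape != mask.shape:
        raise ValueError("weight matrix and adjacency mask shapes differ")
    clipped = normalize_rows(
        W_EE, np.ascontiguousarray(mask, dtype=np.bool_), np.asarray(K, dtype=np.float64),
        float(w_min), float(w_max),
    )
    return W_EE, clipped
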