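"""Membrane dynamics for the five neuron roles and the synaptic kernel.

E, R and S neurons are adaptive exponential integrate-and-fire (AdEx); R and
S disable the adaptation current (gamma = 0).  I and H neurons are leaky
integrate-and-fire.  Synaptic input is conductance based: each neuron carries
strictly segregated excitatory and inhibitory channels, each implemented as a
pair of exponential states (rise, decay) whose difference reproduces the
double-exponential kernel exactly (superposition of analytic kernel copies,
one per delivered spike).

Integration scheme: the membrane leak is advanced by its exact exponential
over one step; the AdEx spike-initiation term, the synaptic drive and the
adaptation coupling are explicit (first order in dt).  A spike is declared
when V reaches the ceiling ``V_peak``; the membrane is never left above the
ceiling.  The exponential argument is clamped to avoid overflow, and cut off
far below threshold so purely subthreshold relaxation is exactly exponential.

The jitted scalar step functions here are the exact code the simulation
engine executes; tests drive them directly against closed-form oracles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .config import AdExParams, LIFParams, SynapticKernelParams

__all__ = [
    "kernel_value",
    "conductance",
    "ChannelState",
    "NeuronStateE",
    "NeuronStateI",
    "adex_step",
    "lif_step",
    "step_excitatory",
    "step_inhibitory",
    "update_conductances",
    "NumericsError",
]

_EXP_ARG_MAX = 20.0  # clamp of (V - V_T)/Delta_T before exponentiation
_EXP_ARG_MIN = -8.0  # below this the spike-initiation term is exactly 0


class NumericsError(RuntimeError):
    """Membrane potential became non-finite (integration blow-up)."""


def kernel_value(t, tau_rise: float, tau_decay: float, c_K: float = 1.0):
    """Analytic double-exponential kernel K(t), unitless via c_K [ms].

    K(t) = c_K * (exp(-t/tau_decay) - exp(-t/tau_rise)) / (tau_decay - tau_rise)
    for t >= 0, and 0 for t < 0.  Non-negative, -> 0 as t -> inf.
    """
    t = np.asarray(t, dtype=float)
    out = np.where(
        t >= 0.0,
        c_K * (np.exp(-t / tau_decay) - np.exp(-t / tau_rise)) / (tau_decay - tau_rise),
        0.0,
    )
    return out if out.ndim else float(out)


@njit(cache=True, inline="always")
def conductance(x_rise: float, x_decay: float, c_K: float, tau_rise: float, tau_decay: float) -> float:
    return c_K * (x_decay - x_rise) / (tau_decay - tau_rise)


@njit(cache=True, inline="always")
def adex_step(
    V: float, VT: float, a: float, ref: int,
    g_e: float, g_i: float, dt: float,
    tau_m: float, E_L: float, Delta_T: float,
    VT_rest: float, A_T: float, V_reset: float, V_peak: float,
    ref_steps: int, C: float, b: float, a_sub: float, gamma: float,
    E_exc: float, E_inh: float,
    k_leak: float, k_T: float, k_a: float,
):
    """Advance one AdEx neuron by dt.  Returns (V, VT, a, ref, spiked).

    ``k_leak``, ``k_T``, ``k_a`` are the precomputed per-step decay factors
    exp(-dt/tau) of the membrane leak, adaptive threshold and adaptation
    current.  Conductances are read at the step start and held constant.
    """
    spiked = False
    if ref > 0:
        ref -= 1
        V = V_reset
    else:
        arg = (V - VT) / Delta_T
        if arg > _EXP_ARG_MAX:
            arg = _EXP_ARG_MAX
        exp_term = (Delta_T / tau_m) * np.exp(arg) if arg > _EXP_ARG_MIN else 0.0
        Q = (g_e * (E_exc - V) + g_i * (E_inh - V)) / C
        V_new = E_L + (V - E_L) * k_leak + dt * (exp_term + Q - gamma * a / C)
        if V_new >= V_peak:
            spiked = True
            V = V_reset
            VT = VT + A_T
            a = a + b
            ref = ref_steps
        else:
            V = V_new
    # threshold and adaptation relax regardless of refractoriness
    VT = VT_rest + (VT - VT_rest) * k_T
    a = a * k_a + a_sub * (V - E_L) * (1.0 - k_a)
    return V, VT, a, ref, spiked


@njit(cache=True, inline="always")
def lif_step(
    V: float, ref: int, g_e: float, g_i: float, dt: float,
    E_L: float, V_th: float, V_reset: float,
    ref_steps: int, C: float, E_exc: float, E_inh: float, k_leak: float,
):
    """Advance one LIF neuron by dt.  Returns (V, ref, spiked)."""
    spiked = False
    if ref > 0:
        ref -= 1
        V = V_reset
    else:
        Q = (g_e * (E_exc - V) + g_i * (E_inh - V)) / C
        V_new = E_L + (V - E_L) * k_leak + dt * Q
        if V_new >= V_th:
            spiked = True
            V = V_reset
            ref = ref_steps
        else:
            V = V_new
    return V, ref, spiked


# ---------------------------------------------------------------------------
# Convenience state containers + step wrappers (unit-test / small-scale API).
# The engine operates on flat arrays with the jitted primitives above.
# ---------------------------------------------------------------------------

@dataclass
class ChannelState:
    """One conductance channel: rise/decay exponential states."""

    x_rise: float = 0.0
    x_decay: float = 0.0

    def g(self, kern: SynapticKernelParams, inhibitory: bool = False) -> float:
        tr = kern.tau_rise_inh if inhibitory else kern.tau_rise_exc
        td = kern.tau_decay_inh if inhibitory else kern.tau_decay_exc
        return conductance(self.x_rise, self.x_decay, kern.c_K, tr, td)


@dataclass
class NeuronStateE:
    """State of one AdEx neuron (E/R/S role)."""

    V: float
    V_T: float
    a: float = 0.0
    ref: int = 0
    exc: ChannelState = field(default_factory=ChannelState)
    inh: ChannelState = field(default_factory=ChannelState)


@dataclass
class NeuronStateI:
    """State of one LIF neuron (I/H role)."""

    V: float
    ref: int = 0
    exc: ChannelState = field(default_factory=ChannelState)
    inh: ChannelState = field(default_factory=ChannelState)


def step_excitatory(
    state: NeuronStateE, p: AdExParams, kern: SynapticKernelParams, dt: float,
    *, t: float = 0.0, index: int = -1,
) -> bool:
    """Advance one AdEx neuron by dt using its current conductances.

    Returns the spike flag; on spike the membrane is reset, the adaptive
    threshold and adaptation current jump, and a refractory period starts.
    Raises NumericsError (naming neuron and time) if V leaves the finite
    range, which the ceiling-based spike detection is designed to prevent.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    g_e = state.exc.g(kern)
    g_i = state.inh.g(kern, inhibitory=True)
    V, VT, a, ref, spiked = adex_step(
        state.V, state.V_T, state.a, state.ref, g_e, g_i, dt,
        p.tau_m, p.E_L, p.Delta_T, p.V_T_rest, p.A_T, p.V_reset, p.V_peak,
        int(round(p.t_ref / dt)), p.C, p.b, p.a_sub, p.gamma,
        kern.E_exc, kern.E_inh,
        np.exp(-dt / p.tau_m), np.exp(-dt / p.tau_T), np.exp(-dt / p.tau_a),
    )
    if not np.isfinite(V):
        raise NumericsError(f"non-finite membrane potential (neuron {index}, t={t} ms)")
    state.V, state.V_T, state.a, state.ref = V, VT, a, ref
    return bool(spiked)


def step_inhibitory(
    state: NeuronStateI, p: LIFParams, kern: SynapticKernelParams, dt: float,
    *, t: float = 0.0, index: int = -1,
) -> bool:
    """Advance one LIF neuron by dt.  Returns the spike flag."""
    if dt <= 0:
        raise ValueError("dt must be > 0")
    g_e = state.exc.g(kern)
    g_i = state.inh.g(kern, inhibitory=True)
    V, ref, spiked = lif_step(
        state.V, state.ref, g_e, g_i, dt,
        p.E_L, p.V_th, p.V_reset, int(round(p.t_ref / dt)),
        p.C, kern.E_exc, kern.E_inh, np.exp(-dt / p.tau_m),
    )
    if not np.isfinite(V):
        raise NumericsError(f"non-finite membrane potential (neuron {index}, t={t} ms)")
    state.V, state.ref = V, ref
    return bool(spiked)


def update_conductances(
    state: NeuronStateE | NeuronStateI,
    kern: SynapticKernelParams,
    dt: float,
    exc_weight_in: float = 0.0,
    inh_weight_in: float = 0.0,
) -> None:
    """Advance both conductance channels by dt and add delivered spike weight.

    The weighted spike input jumps both exponential states of its channel, so
    the resulting conductance trace equals the sum of analytic kernel copies
    (exact superposition / linearity of the convolution).  Channels are
    strictly segregated; inhibitory input can never enter the excitatory
    accumulator.  Raises on negative resulting conductance (which only a
    negative weight could produce).
    """
    if exc_weight_in < 0 or inh_weight_in < 0:
        raise ValueError("delivered spike weight must be non-negative")
    state.exc.x_rise = state.exc.x_rise * np.exp(-dt / kern.tau_rise_exc) + exc_weight_in
    state.exc.x_decay = state.exc.x_decay * np.exp(-dt / kern.tau_decay_exc) + exc_weight_in
    state.inh.x_rise = state.inh.x_rise * np.exp(-dt / kern.tau_rise_inh) + inh_weight_in
    state.inh.x_decay = state.inh.x_decay * np.exp(-dt / kern.tau_decay_inh) + inh_weight_in
    if state.exc.g(kern) < -1e-12 or state.inh.g(kern, inhibitory=True) < -1e-12:
        raise NumericsError("negative synaptic conductance")
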