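"""Independent brute-force reference integrators for the plasticity rules.

These integrate the literal differential form of the learning rules on a
dense fine grid (trapezoid quadrature for the continuous potentiation term,
per-spike jumps for the Dirac terms, exact exponential trace relaxation) and
are deliberately written without reference to the package's step functions.
"""

from __future__ import annotations

import numpy as np


def r(x: np.ndarray | float) -> np.ndarray | float:
    return np.maximum(x, 0.0)


def voltage_stdp_reference(
    V: np.ndarray,  # (n_steps, n_post) piecewise-constant voltage per step
    pre: np.ndarray,  # (n_steps, n_pre) presyn spike counts at step starts
    dt: float,
    *,
    A_LTD: float, A_LTP: float, theta_LTD: float, theta_LTP: float,
    tau_u: float, tau_v: float, tau_x: float, alpha: float,
    u0: float, v0: float,
) -> np.ndarray:
    """Final weight change of the voltage-based STDP rule, dense integration.

    dW/dt = -A_LTD s_pre(t) R(u - th_LTD) + A_LTP x R(V - th_LTP) R(v - th_LTD)

    Spike terms are impulses (jumps at the spike time, reading the traces at
    that time); the continuous term is integrated with the trapezoid rule on
    the given grid; u, v relax exactly toward the (constant-per-step) V and
    x decays exactly.
    """
    n_steps, n_post = V.shape
    n_pre = pre.shape[1]
    ku, kv, kx = np.exp(-dt / tau_u), np.exp(-dt / tau_v), np.exp(-dt / tau_x)
    u = np.full(n_post, u0)
    v = np.full(n_post, v0)
    x = np.zeros(n_pre)
    dW = np.zeros((n_post, n_pre))
    for n in range(n_steps):
        Vn = V[n]
        s = pre[n]
        if s.any():
            dW += np.outer(-A_LTD * r(u - theta_LTD), s)
            x = x + alpha * s
        # trapezoid over [t, t+dt): integrand at both ends, traces exact
        f0 = np.outer(r(Vn - theta_LTP) * r(v - theta_LTD), x)
        u_end = Vn + (u - Vn) * ku
        v_end = Vn + (v - Vn) * kv
        x_end = x * kx
        f1 = np.outer(r(Vn - theta_LTP) * r(v_end - theta_LTD), x_end)
        dW += A_LTP * 0.5 * dt * (f0 + f1)
        u, v, x = u_end, v_end, x_end
    return dW


def inhib_reference(
    pre: np.ndarray,  # (n_steps, n_pre) I spike counts at step starts
    post: np.ndarray,  # (n_steps, n_post) E spike counts at step ends
    dt: float,
    *,
    A_inh: float, r0: float, tau_y: float, alpha: float,
) -> np.ndarray:
    """Final weight change of the target-rate inhibitory rule.

    dW/dt = A_inh (y_post - 2 alpha r0 tau_y) s_pre(t) + A_inh y_pre s_post(t)

    All terms are impulses.  y traces jump by alpha per spike of their
    neuron and decay exactly; presynaptic spikes are nominally at step
    starts, postsynaptic at step ends (reading the post-decay traces).
    """
    n_steps, n_pre = pre.shape
    n_post = post.shape[1]
    ky = np.exp(-dt / tau_y)
    offset = 2.0 * alpha * r0 * tau_y
    yE = np.zeros(n_post)
    yI = np.zeros(n_pre)
    dW = np.zeros((n_post, n_pre))
    for n in range(n_steps):
        s_pre = pre[n]
        if s_pre.any():
            dW += np.outer(A_inh * (yE - offset), s_pre)
        yE = yE * ky
        yI = (yI + alpha * s_pre) * ky
        s_post = post[n]
        if s_post.any():
            dW += np.outer(s_post, A_inh * yI)
            yE = yE + alpha * s_post
    return dW
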