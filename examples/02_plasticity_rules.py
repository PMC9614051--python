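"""The three learning rules on scripted inputs.

Shows the impulse semantics of the voltage-based STDP rule (a depression
jump that does not depend on the integration step), a potentiating
pre-before-depolarization pairing, the balance point of the inhibitory
rule, and the exactness of subtractive synaptic normalization.
"""

import numpy as np

import neuralclock as nc
from neuralclock.plasticity import (
    TraceState,
    inhib_offset,
    inhibitory_plasticity_step,
    normalize_incoming,
    voltage_stdp_step,
)

p = nc.desk_config().stdp
pi = nc.desk_config().inhib

# 1) depression is a per-spike jump: same total change at dt=0.1 and 0.01
for dt in (0.1, 0.01):
    W = np.zeros((1, 1))
    tr = TraceState(u=np.array([p.theta_LTD + 5.0]), v=np.array([-75.0]),
                    x=np.zeros(1))
    voltage_stdp_step(W, None, tr, np.array([-75.0]), np.array([1.0]), dt, p)
    print(f"LTD jump for one presynaptic spike (u 5 mV above threshold), "
          f"dt={dt}: {W[0,0]:+.3e} nS")
print("-> identical: the spike term integrates the Dirac impulse, not rate*dt\n")

# 2) pre spike followed by postsynaptic depolarization potentiates
W = np.zeros((1, 1))
tr = TraceState(u=np.full(1, -70.0), v=np.full(1, -70.0), x=np.zeros(1))
for n in range(300):
    pre = np.array([1.0]) if n == 10 else np.zeros(1)
    V = np.full(1, -40.0) if 15 <= n < 55 else np.full(1, -70.0)
    voltage_stdp_step(W, None, tr, V, pre, 0.1, p)
print(f"pre spike followed 0.5 ms later by 4 ms of depolarization to -40 mV: "
      f"dW = {W[0,0]:+.3e} nS (potentiation)\n")

# 3) the inhibitory rule's balance point
tr = TraceState(u=np.zeros(1), v=np.zeros(1), x=np.zeros(1),
                y_E=np.array([inhib_offset(pi)]), y_I=np.zeros(1))
W = np.zeros((1, 1))
inhibitory_plasticity_step(W, None, tr, np.array([1.0]), np.zeros(1), 0.1, pi)
print(f"I spike with postsynaptic rate trace exactly at 2*alpha*r0*tau_y "
      f"({inhib_offset(pi):.2f}): dW = {W[0,0]:+.1e} (the target-rate fixed point)\n")

# 4) normalization restores each neuron's incoming sum exactly
rng = np.random.default_rng(0)
mask = rng.random((6, 6)) < 0.8
np.fill_diagonal(mask, False)
W = np.where(mask, rng.uniform(1.0, 4.0, (6, 6)), 0.0)
K = np.where(mask.any(1), 10.0, 0.0)
normalize_incoming(W, K, mask)
print("row sums after normalization (target K=10):",
      np.round(W.sum(axis=1), 12))
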