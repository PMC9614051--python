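"""Full-scale validation workflow (long-running; hours of wall time).

Runs the complete protocol at the full network size — 2400 E neurons in 30
clusters, 600 I neurons, 1 h + 1 h of clock learning, 12 s of read-out
training on ABCBA, replay — and checks the full-scale targets:

* clock period about 470 ms (within 10%),
* per-cluster activation about 15 ms,
* about one read-out spike per element during replay.

The full-scale parameter set is a provisional extrapolation of the
calibrated desk preset (weights scaled inversely with in-degree, learning
rates scaled with training duration); these targets are asserted only here,
never in the default test suite.  Expect several hours on one core.
"""

import numpy as np

import neuralclock as nc
from neuralclock.analysis import (
    cluster_block_means,
    clock_metrics,
    decode_replay,
    trigger_cycle_bounds,
)
from neuralclock.engine import replay, train_clock, train_readout
from neuralclock.stimulation import SequenceSpec, phase1_period

cfg = nc.full_scale_config()
print("training full-scale clock (1 h + 1 h biological)...")
clock = train_clock(cfg)
state = clock.state
topo = state.topology

bm = cluster_block_means(state.synapses.W["EE"], topo.cluster_label,
                         topo.adjacency["EE"])
print(f"blocks: intra {bm.diagonal_mean():.2f}, ff {bm.superdiagonal_mean():.2f}, "
      f"back {bm.subdiagonal_mean():.2f}, far {bm.distant_mean():.2f}")

rep0 = replay(state, 10_000.0, cfg)
cm = clock_metrics(rep0.spikes, topo.cluster_label)
print(f"clock period {cm.period_mean_ms:.0f} ms, activation "
      f"{cm.activation_mean_ms:.1f} ms, sequentiality {cm.sequentiality:.2f}")
assert cm.ok, "no sequential dynamics at full scale"
assert abs(cm.period_mean_ms - 470.0) / 470.0 < 0.10, cm.period_mean_ms
assert 5.0 < cm.activation_mean_ms < 30.0, cm.activation_mean_ms

seq = SequenceSpec.from_string("ABCBA", cfg.stim.t_element, cfg.stim.lead)
train_readout(state, seq, cfg)
rep = replay(state, 5_000.0, cfg)
p_nom = phase1_period(topo.N_C, cfg.stim.t_stim, cfg.stim.t_gap)
bounds = trigger_cycle_bounds(rep.spikes, topo.cluster_label, dt=cfg.dt,
                              tau_ms=cfg.trigger.tau_ms,
                              threshold=cfg.trigger.threshold,
                              lockout_ms=cfg.trigger.lockout_frac * p_nom)
dec = decode_replay(rep.spikes, seq.alphabet, bounds, merge_ms=40.0)
counts = [c for _, cnts in dec.cycles for c in cnts]
print(f"decoded cycles: {['.'.join(c[0]) for c in dec.cycles[:5]]}")
print(f"read-out spikes per element: {np.mean(counts):.2f}")
assert dec.max_consecutive(tuple("ABCBA")) >= 3
assert np.mean(counts) < 3.0  # about one spike per element
print("full-scale validation passed")
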