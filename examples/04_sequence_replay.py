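"""Teach the read-out layer a higher-order sequence and replay it.

Loads the trained clock from ``out/clock/`` (run 03_train_clock.py first),
trains the read-out connections on ABCB — B recurs with different
successors, so the next element is not determined by the current one —
and then replays the sequence from spontaneous input alone.
"""

import numpy as np

import neuralclock as nc
from neuralclock.analysis import decode_replay, trigger_cycle_bounds
from neuralclock.artifacts import read_weights
from neuralclock.engine import SimState, replay, train_readout
from neuralclock.stimulation import SequenceSpec, phase1_period

cfg = nc.desk_config()
topo, syn = read_weights("out/clock")
syn.frozen = True
state = SimState.init(cfg, topo, syn)

seq = SequenceSpec.from_string("ABCB", cfg.stim.t_element, cfg.stim.lead)
print(f"sequence {''.join(seq.elements)}: {seq.n_readout} elements, "
      f"presentation {seq.presentation_ms:.0f} ms per clock cycle")
res = train_readout(state, seq, cfg)
print(f"read-out trained: {len(res.trigger_times_ms)} presentations locked "
      f"to detected cycle starts over {cfg.protocol.readout_ms/1000:.0f} s")

W_RE = state.synapses.W["RE"]
lab = topo.cluster_label
band = np.array([[W_RE[r, lab == c].mean() for c in range(topo.N_C)]
                 for r in range(topo.N_R)])
print("\nmean RE weight from each cluster to each read-out neuron (nS):")
for r, name in enumerate(seq.alphabet):
    print(f"  {name}: " + " ".join(f"{v:4.1f}" for v in band[r]))
print("-> each read-out neuron selects the clusters active during its "
      "element's time slots (B has two bands: it occurs twice)")

rep = replay(state, 4000.0, cfg)
p_nom = phase1_period(topo.N_C, cfg.stim.t_stim, cfg.stim.t_gap)
bounds = trigger_cycle_bounds(rep.spikes, lab, dt=cfg.dt,
                              tau_ms=cfg.trigger.tau_ms,
                              threshold=cfg.trigger.threshold,
                              lockout_ms=cfg.trigger.lockout_frac * p_nom)
dec = decode_replay(rep.spikes, seq.alphabet, bounds, merge_ms=20.0)
print(f"\nreplay of {len(dec.cycles)} clock cycles, decoded element order:")
for k, (elements, counts) in enumerate(dec.cycles[:8]):
    print(f"  cycle {k}: {''.join(elements)}  (spikes per element {counts})")
print(f"longest run of consecutive correct cycles: "
      f"{dec.max_consecutive(tuple('ABCB'))}")
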