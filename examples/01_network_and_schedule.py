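"""Build the clustered network and inspect the stimulation protocol.

Constructs the desk-scale topology (10 clusters x 20 excitatory neurons,
100 inhibitory neurons), initializes the uniform weights, and prints the
timing arithmetic of the sequential training schedule.
"""

import numpy as np

import neuralclock as nc
from neuralclock.stimulation import phase1_period, rounds_in, schedule_for_phase
from neuralclock.topology import build_connectivity, init_weights

cfg = nc.desk_config()
topo = build_connectivity(cfg, cfg.seeds.topology)
syn = init_weights(topo, cfg)

print(f"network: {topo.N_E} E in {topo.N_C} clusters of {topo.cluster_size}, "
      f"{topo.N_I} I, {topo.N_R} read-out units")
for cls in ("EE", "EI", "IE", "II"):
    m = topo.adjacency[cls]
    print(f"  {cls}: {m.sum()} edges, mean in-degree {m.sum(1).mean():.1f}")
print(f"  K (incoming EE sum per neuron): mean {syn.K.mean():.0f} nS")

period = phase1_period(topo.N_C, cfg.stim.t_stim, cfg.stim.t_gap)
print(f"\nphase-1 schedule: {cfg.stim.t_stim:.0f} ms excitation + "
      f"{cfg.stim.t_gap:.0f} ms gap per cluster -> period {period:.0f} ms")
print(f"rounds in 5 min of training: {rounds_in(cfg.protocol.phase1_ms, period)}")
print(f"(full scale: 30 clusters -> period {phase1_period(30, 9.0, 6.0):.0f} ms, "
      f"{rounds_in(3_600_000.0, 450.0)} rounds per hour)")

sched = schedule_for_phase(cfg, "phase1", T_ms=period)
print("\ncluster 0 external drive (exc_Hz, inh_Hz):")
for t in (0.0, 5.0, 10.0, 15.0):
    print(f"  t={t:5.1f} ms: {sched.cluster_rates(0, t)}")
print("during its 9 ms window a cluster is excited at 22.5k spk/s; at every "
      "other time it receives inhibitory drive instead — never both.")
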