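# neuralclock

A spiking recurrent network that learns to tell time, and a read-out layer
that uses that clock to learn and replay spatiotemporal sequences.

## The model

Cortical computations such as motor production and language need sequences
whose elements have specific order *and* timing, bridging the millisecond
timescale of neurons to behavioral timescales of hundreds of milliseconds.
`neuralclock` implements a two-component solution:

**1. A neural clock.** A recurrent network of `N_E` adaptive exponential
integrate-and-fire (AdEx) excitatory neurons, divided uniformly into `N_C`
clusters, plus `N_I` leaky integrate-and-fire inhibitory neurons, randomly
connected with probability `p` (no autapses, no multapses). Excitatory
membranes follow

    dV/dt = (E_L - V + Δ_T exp((V - V_T)/Δ_T))/τ_E - a/C + Q,

with an adaptive threshold `V_T`, a spike-triggered adaptation current `a`,
and conductance-based synaptic drive `Q` through double-exponential kernels
(strictly segregated excitatory and inhibitory channels). Three plasticity
mechanisms act during learning:

* **voltage-based STDP** on E→E (and later E→R) synapses — depression as a
  per-presynaptic-spike jump gated by a slow low-pass `u` of the
  postsynaptic voltage, potentiation continuous in time, gated by the
  instantaneous voltage and a fast low-pass `v`, scaled by a presynaptic
  spike trace `x`:

      dW/dt = -A_LTD s_pre(t-d) R(u - θ_LTD)
              + A_LTP x(t-d) R(V - θ_LTP) R(v - θ_LTD)

* **inhibitory plasticity with a target rate** on I→E synapses,
  `dW/dt = A_inh (y^E - 2αr₀τ_y) s^I(t-d) + A_inh y^I s^E(t)`, which pushes
  excitatory firing toward `r₀`;
* **synaptic normalization** — every `τ_norm` the incoming E→E weights of
  each neuron are shifted subtractively so their sum returns exactly to its
  initial value `K`.

Training drives the clusters one by one (9 ms of 22.5k spk/s Poisson
excitation per cluster, 6 ms gaps, inhibitory drive otherwise) for the
first phase, then switches to unstructured spontaneous drive. The network
self-organizes into a ring: strong within-cluster weights, strong
cluster *i* → *i+1* weights, weak *i* → *i−1*, nothing elsewhere. Under
spontaneous input the clusters then activate cyclically, ~15 ms each — a
clock whose period matches the training period. The signature of the
learned ring is a circle of leading eigenvalues in the spectrum of the full
signed weight matrix, next to a circular-law bulk and a large-negative
E/I-balance pair.

**2. A read-out layer.** One read-out neuron (R) per sequence element, each
with a private supervisor (S) and interneuron (H), receives plastic
all-to-all connections from the clock (RE). During 12 s of training, each
element's supervisor is driven during its time slot of every clock cycle
(presentations locked to the detected activation of cluster 0); the
voltage-STDP rule binds each read-out neuron to the clusters active during
its slots. Because time, not the previous element, selects the next
element, higher-order (non-Markovian) sequences like ABCB or ABCBA — where
B's successor is ambiguous — are learned without difficulty. After
training, spontaneous drive to the recurrent network alone replays the
sequence, cycle after cycle.

## A worked example

The desk-scale preset (10 clusters × 20 E neurons, 100 I neurons, 5 min of
biological time per clock phase) trains in a few minutes on one core:

```
python examples/03_train_clock.py
python examples/04_sequence_replay.py
```

Output of the clock training (default seeds):

```
block means (nS): intra-cluster 44.2, feedforward i->i+1 27.3,
                  backward i->i-1 0.60, distant 0.20
spontaneous dynamics: period 142 ms (stimulus period was 150 ms),
                      sequentiality 0.99, cluster activation 14.4 ms
```

The intra-cluster and feedforward blocks dominate (the ring), the backward
block is weak but present, everything else is vanishingly small; under
spontaneous drive the clusters activate in order (sequentiality 0.99:
nearly every activation transition goes *i* → *i+1*), ~15 ms each, with a
cycle period close to the 150 ms training period. The replay example then
teaches the read-out layer ABCB and decodes the replayed spikes:

```
replay of 27 clock cycles, decoded element order:
  cycle 0: ABCB  (spikes per element (6, 7, 6, 6))
  cycle 1: ABCB  (spikes per element (7, 7, 7, 6))
  ...
longest run of consecutive correct cycles: 14
```

The other examples show the stimulation-protocol arithmetic (`01`), the
plasticity rules on scripted inputs (`02`), and the closed-form eigenvalue
ring of an idealized feedforward matrix (`05`).
`examples/full_scale_validation.py` runs the complete full-size protocol
(2400 E / 600 I / 30 clusters, 1 h + 1 h + 12 s) and checks the ~470 ms
clock period and per-element read-out spiking; it needs several hours.

There is also a thin CLI over the same workflows:

```
neuralclock build --preset desk --out net/
neuralclock train-clock --preset desk --out trained/
neuralclock train-readout --preset desk --weights trained/ --sequence ABCB --out readout/
neuralclock replay --preset desk --weights readout/ --out spikes.tsv
neuralclock analyze --preset desk --weights readout/ --spikes spikes.tsv --out metrics.json
```

## Layout

| where | what |
| --- | --- |
| `src/neuralclock/topology.py` | clustered architecture, random connectivity, weight init |
| `src/neuralclock/neurons.py` | AdEx/LIF membranes, conductance kernels |
| `src/neuralclock/plasticity.py` | the three learning rules, normalization |
| `src/neuralclock/stimulation.py` | Poisson drive schedules, sequence specs |
| `src/neuralclock/engine.py` + `_kernel.py` | time-stepped simulation (numba), learning workflow |
| `src/neuralclock/analysis.py` | block means, spectra, clock metrics, replay decoding |
| `src/neuralclock/fixtures.py` | deterministic synthetic inputs for tests/demos |
| `src/neuralclock/config.py`, `artifacts.py` | parameter table with provenance, TSV/MTX/JSON I/O |
| `docs/methods.md` | model, conventions, numerical choices, calibration rationale |
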