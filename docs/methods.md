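# Methods

This note documents the model equations as implemented, the conventions the
implementation fixes where the underlying description leaves choices open,
the numerical scheme, and the calibration of the scaled-down preset. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Model summary

Two subnetworks. The recurrent network (RNN) holds `N_E` excitatory (E)
neurons in `N_C` equal, contiguous clusters and `N_I` inhibitory (I)
neurons; every ordered pair of distinct RNN neurons is connected
independently with its class probability (autapses and multapses excluded).
The read-out layer holds `N_R` read-out neurons (R), each wired to exactly
one supervisor (S) and one interneuron (H); the E population projects
all-to-all onto R. Connection classes are named **target←source** (`EI`
means I→E). E→E and I→E are plastic during clock learning; E→R is plastic
during read-out learning; everything else is static. There are no R→R
connections.

### Membranes

E, R and S neurons are adaptive exponential integrate-and-fire:

    dV/dt = (E_L - V + Δ_T exp((V - V_T)/Δ_T)) / τ_m  - γ a/C + Q

with spike detection at a ceiling `V_peak`, reset to `V_reset`, absolute
refractory period `t_ref`, an adaptive threshold (`V_T += A_T` per spike,
relaxing to `V_T_rest` with `τ_T`) and a spike-triggered adaptation current
(`a += b` per spike, decaying with `τ_a`; subthreshold coupling `a_sub` is
available but 0 by default). γ is 1 for E and 0 for R and S — only E
neurons adapt via `a`; R neurons instead carry a stronger threshold
adaptation (`A_T` = 6 mV, `τ_T` = 15 ms) that keeps read-out responses
sparse while recovering fast enough to respond to a repeated element two
slots later. I and H neurons are leaky integrate-and-fire with a fixed
threshold.

Synaptic drive is conductance-based, `Q = (g_e(E_exc - V) + g_i(E_inh -
V))/C`, with strictly segregated excitatory and inhibitory channels. Each
channel implements the double-exponential kernel

    K(t) = c_K (e^{-t/τ_decay} - e^{-t/τ_rise}) / (τ_decay - τ_rise)

exactly, as a pair of exponential states jumped by the synaptic weight at
delivery; `c_K = 1 ms` makes the kernel unitless (its time integral is
`c_K`, so a Poisson drive of rate `r` through weight `w` contributes a mean
conductance `r·w·c_K`).

### Plasticity

Voltage-based STDP (EE and RE classes):

    dW/dt = -A_LTD s_pre(t-d) R(u - θ_LTD)
            + A_LTP x_pre(t-d) R(V - θ_LTP) R(v - θ_LTD)

`u`, `v` are slow/fast exponential low-passes of the postsynaptic voltage,
`x` the presynaptic spike trace (`dx/dt = α s - x/τ_x`; jump `α` per
spike, `α = 1 ms⁻¹` fixes units), `R(x) = max(x, 0)`. The RE class has its
own learning-rate pair and trace constant `τ_x_RE`, and no weight-dependent
potentiation anywhere. Inhibitory plasticity (EI):

    dW/dt = A_inh (y^E - 2 α r₀ τ_y) s^I(t-d) + A_inh y^I s^E(t)

Normalization: every `τ_norm`, for each E neuron `i` with `l` incoming EE
edges, `W_ij ← W_ij - (Σ_k W_ik - K_i)/l` — the only reading of the
update that conserves the sum, which afterwards equals `K_i` (the incoming
sum realized at initialization) to machine precision; bound clipping is
applied after the subtraction and its effect is counted, not re-corrected.

## Discrete-time semantics (the load-bearing conventions)

All spike-train terms are **Dirac impulses integrated as per-spike jumps**,
never `rate·dt` products; the accumulated spike-triggered change is
therefore invariant under refinement of the step (halving `dt` changes it
only at float precision). The continuous potentiation term is integrated
in closed form over each step, treating the postsynaptic `V` as constant
within the step while `x` decays and `v` relaxes exponentially; the
rectifier crossing of `v - θ_LTD` (monotonic within a step) is handled
exactly. Per-step updates are thus exact for piecewise-constant-voltage
inputs, and the test suite verifies them against an independently coded
dense integration at `dt/100` (trapezoid quadrature, exact traces) to
1e-4 relative.

Within one engine step at nominal time `t`:

1. recurrent spikes emitted `d` earlier are delivered; conductance jumps
   read the pre-step weights (single-buffer read-before-write — never a
   partially updated value);
2. spike-triggered plasticity fires: depression reads `u(t)`, the
   inhibitory presynaptic term reads `y^E(t)`; presynaptic traces `x` jump;
3. potentiation integrates over `[t, t+dt)` from the post-jump `x`;
4. external Poisson input is sampled (full Poisson counts per bin — at
   22.5k spk/s and `dt` = 0.1 ms the expectation is 2.25 per bin, so
   Bernoulli thinning would undershoot) and delivered without delay (the
   synaptic delay applies to recurrent spikes only; an external "spike" is
   already the arrival at the synapse);
5. `u`, `v` relax toward `V(t)`;
6. membranes integrate and spikes are detected, with nominal spike time
   `t+dt` (always a multiple of `dt`);
7. conductance states and spike traces decay;
8. postsynaptic spike terms of the inhibitory rule fire, reading the
   post-decay `y^I`; the spikes' own `y` jumps follow;
9. emitted spikes enter the delay ring (a spike at `t` affects no other
   neuron before exactly `t + d`); normalization runs at `τ_norm`
   boundaries.

Presynaptic traces (`x`, and `y^I` for the delayed term) are driven by
*delivered* (delayed) spikes; a trace driven by spikes delayed by `d` and
read at `t` equals the undelayed trace at `t-d` identically, so the
`x(t-d)` semantics is exact without storing trace history.

Integration is exponential-Euler on the membrane leak with the
spike-initiation exponential, synaptic drive and adaptation explicit. The
exponential's argument is clamped above (no overflow) and cut off below
`-8` (where the term is < 1e-4 mV/ms), so subthreshold relaxation is
exactly exponential. The detection ceiling guarantees the membrane is
never left above `V_peak`; a non-finite membrane aborts the run naming the
neuron and time. Spike *times* carry an O(dt) discretization bias (~0.3 ms
per spike at `dt` = 0.1 ms, dominated by the escape phase); the test suite
pins it below 2% of the inter-spike interval at moderate rates.

State persists across protocol phases — no periodic or per-phase resets —
with one documented exception: spikes still inside the delay line at a
phase boundary (a 1 ms window against multi-minute phases) are dropped.
Initial conditions: membranes and voltage traces at the resting potential,
spike traces and conductances at zero. Each phase derives its RNG streams
from the configured seeds; identical configuration and seeds give
bit-identical results on one platform.

## Clock-phase locking and replay decoding

Read-out training must present the sequence at the same time of every
clock cycle. The engine detects cycle starts online: the reference
cluster's (cluster 0) spike count per step is smoothed with an exponential
filter (`τ` = 3 ms); an upward crossing of a population-rate threshold
(1 spk/ms), after a lockout of 0.6 nominal periods, triggers one
presentation (lead time, then one supervisor window per element). The
same detector, run offline on the replay raster with the same parameters,
provides the cycle boundaries for decoding — training and decoding share a
phase reference, which avoids boundary rotation between two different
period estimators.

`decode_replay` groups each read-out neuron's spikes into *element events*
(a gap above `merge_ms` opens a new event, so an element occurring twice
per cycle yields two events), assigns each event to the cycle containing
its median spike time (an event straddling a boundary is not split), and
reports the per-cycle event order and spike counts. `clock_metrics`
estimates the period from activation onsets of cluster 0, cluster
activations as threshold-crossing arg-max runs of Gaussian-smoothed
(σ = 2 ms) per-cluster population rates, and a sequentiality score = the
fraction of activation transitions going i → i+1 (mod N_C); these
estimator choices (smoothing width, thresholds, reference cluster) are
analysis parameters, documented as this package's conventions.

In the full signed weight matrix (E columns positive, I columns negative),
the leading eigenvalues are selected as the `N_C` of largest **modulus**:
selecting by real part alone cannot recover the left half of the ring even
for the idealized block-circulant matrix whose nonzero spectrum is exactly
`m·w` times the `N_C`-th roots of unity.

## Parameters and the scaled-down preset

Times are ms, voltages mV, conductances nS, external rates spk/s, the
target rate spk/ms. Every parameter carries a provenance tag
(`figure-caption` for values printed in the protocol description —
stimulation rates 22.5k/4.5k/10k/1k spk/s, windows 9/6/75/25 ms, sizes
2400/600/30, normalization every 450 ms; `replication-choice` for the rest)
and the simulation refuses unresolved entries. The `replication-choice`
values are drawn from the standard AdEx / voltage-STDP / target-rate
literature lineage and calibrated once; they are provisional in the sense
that the printed description defers them to supplementary material not
available here.

The **desk preset** (`desk_config()`) is the package's study condition for
end-to-end verification: 10 clusters × 20 E, 100 I, p = 0.5 (keeps
in-degrees near full scale), 5 biological minutes per clock phase. Its
calibration, fixed once:

* weights scale inversely with in-degree (EE init 7 nS, bounds [0, 60];
  I→E init 30, bounds [1, 90]; E→I 6; I→I 38) so total synaptic drive per
  neuron matches the full-scale budget;
* the I→E upper bound matters qualitatively: left unbounded, the
  target-rate rule converges toward per-neuron detailed balance, which at
  this scale (binomial in-degree spread of ~19-synapse clusters) cancels
  exactly the recurrent advantage that lets a cluster reverberate — the
  clock degenerates into 5 ms fluctuation blips. Bounding the weights
  keeps inhibition global-and-blunt, and sustained ~15 ms activations with
  clean i → i+1 handoffs appear;
* strong spike-triggered adaptation (b = 350 pA, τ_a = 100 ms) terminates
  each activation and biases the next ignition to the feedforward
  successor;
* `τ_x_EE` = 9 ms sets the learned intra:feedforward block ratio (the
  trace must survive the 6 ms gap to potentiate i → i+1, but not two
  windows);
* the target rate r₀ = 22 Hz is the full-scale 5 Hz scaled by duty cycle:
  one active cluster out of 10 instead of one out of 30;
* the read-out stage uses 30 ms element windows with a 10 ms lead (ABCB
  fits one 150 ms cycle), supervisor→R 300 nS, interneuron→R 900 nS (the
  strong interneuron brake confines learning to the supervised windows),
  RE bounds [0, 6] and learning rates 2e-3.

The sequential-stimulation generator emulates the structured training
input exactly as specified (per-cluster windows, complementary inhibition,
Poisson statistics). What it does not emulate: any feature of real neural
data — trial-to-trial nonstationarity, correlated input noise, cell-type
diversity, conduction-delay distributions. Passing the scaled-down
end-to-end checks therefore demonstrates that the learning dynamics
self-organize as described under the model's own assumptions, not that the
parameters are biologically fitted.

The **full-scale defaults** (`full_scale_config()`) extrapolate the desk
calibration back to 2400/600/30 (weights re-scaled by in-degree, EE
learning rates reduced ~4× for the 12× longer training, r₀ = 5 Hz,
element windows 75 ms with 25 ms lead as in the full protocol). They are
exercised by `examples/full_scale_validation.py` (hours of runtime, checks
the ~470 ms period, ~15 ms activations and per-element read-out spiking)
and are provisional until that workflow is run routinely.

## Known limitations

* Spike times are quantized to `dt` with an O(dt) escape-phase bias; exact
  spike-time correspondence with other integrators is not a goal.
* A single synaptic delay `d` is shared by all recurrent classes.
* The desk-scale read-out occasionally emits an extra element event at
  band edges (decoded cycles like ABCCB between correct ones); the
  consecutive-correct-cycles measure in the acceptance script reflects
  this honestly.
* Parallel learning of several sequences with selective read-out
  inhibition, and non-symbolic (e.g. spectral) sequence elements, are out
  of scope.
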