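"""Model configuration, parameter table with provenance, and validation.

All times are in milliseconds, voltages in millivolts, conductances (synaptic
weights) in nanosiemens, external drive rates in spikes per second (Hz), and
the inhibitory-plasticity target rate in spikes per millisecond.

Connection classes are named ``target<-source``: ``EI`` is the class of
synapses from inhibitory onto excitatory neurons, ``RE`` from excitatory RNN
neurons onto read-out neurons, ``SR``/``HR`` from supervisor/interneuron onto
read-out neurons.

Every parameter carries a provenance tag so the full table is auditable:

* ``figure-caption`` -- printed in the source figures/protocol text
  (stimulation rates and timings, population sizes).
* ``replication-choice`` -- chosen for this implementation from the standard
  AdEx / voltage-STDP / inhibitory-plasticity literature and calibrated once;
  the printed description defers these values to supplementary material that
  is not machine-readable here, so they are provisional.
* ``derived`` -- computed from other entries (e.g. the phase-1 period).
"""

from __future__ import annotations

import copy
import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Any

import yaml

__all__ = [
    "AdExParams",
    "LIFParams",
    "SynapticKernelParams",
    "WeightParams",
    "VoltageSTDPParams",
    "InhibPlasticityParams",
    "NormalizationParams",
    "StimulationParams",
    "ProtocolParams",
    "NetworkParams",
    "TriggerParams",
    "Seeds",
    "SimulationConfig",
    "ConfigError",
    "full_scale_config",
    "desk_config",
    "load_config",
    "save_config",
    "validate_config",
    "parameter_table",
    "config_hash",
]


class ConfigError(ValueError):
    """A configuration violated a structural or dimensional constraint."""


@dataclass
class AdExParams:
    """Adaptive exponential integrate-and-fire neuron (E, R and S roles).

    The membrane evolves as

        dV/dt = (E_L - V + Delta_T * exp((V - V_T)/Delta_T)) / tau_m
                - gamma * a / C + Q

    with Q the conductance-based synaptic drive.  A spike is declared when V
    reaches the numerical ceiling ``V_peak``; V is then reset, the adaptive
    threshold V_T jumps by ``A_T`` (decaying back to ``V_T_rest`` with
    ``tau_T``), the adaptation current jumps by ``b`` (decaying with
    ``tau_a``), and the neuron is refractory for ``t_ref``.  ``gamma`` is 1
    for E neurons and 0 for R and S neurons (no adaptation).
    """

    tau_m: float = 20.0  # ms
    E_L: float = -70.0  # mV
    Delta_T: float = 2.0  # mV
    V_T_rest: float = -52.0  # mV
    A_T: float = 2.0  # mV, threshold jump per spike
    tau_T: float = 10.0  # ms
    V_reset: float = -60.0  # mV
    V_peak: float = 20.0  # mV, spike-detection ceiling
    t_ref: float = 1.0  # ms
    C: float = 300.0  # pF, capacitance-normalizing constant for a/C
    tau_a: float = 100.0  # ms, adaptation-current time constant
    b: float = 350.0  # pA, adaptation jump per spike
    a_sub: float = 0.0  # nS, subthreshold adaptation coupling (off by default)
    gamma: float = 1.0  # adaptation switch


@dataclass
class LIFParams:
    """Leaky integrate-and-fire neuron (I and H roles)."""

    tau_m: float = 20.0  # ms
    E_L: float = -62.0  # mV
    V_th: float = -52.0  # mV
    V_reset: float = -60.0  # mV
    t_ref: float = 1.0  # ms
    C: float = 300.0  # pF, conductance-to-voltage-rate normalizer in Q


@dataclass
class SynapticKernelParams:
    """Double-exponential conductance kernel, made unitless by c_K = 1 ms.

    A spike of weight w at time t_s contributes
        g(t) = w * c_K * (exp(-(t-t_s)/tau_decay) - exp(-(t-t_s)/tau_rise))
                   / (tau_decay - tau_rise)
    to the conductance of its channel.  Excitatory and inhibitory channels are
    strictly segregated.
    """

    tau_rise_exc: float = 1.0  # ms
    tau_decay_exc: float = 6.0  # ms
    tau_rise_inh: float = 0.5  # ms
    tau_decay_inh: float = 2.0  # ms
    E_exc: float = 0.0  # mV, excitatory reversal potential
    E_inh: float = -75.0  # mV, inhibitory reversal potential
    c_K: float = 1.0  # ms, unit-fixing constant of the kernel


@dataclass
class WeightParams:
    """Initial values, bounds, plastic flags and delays per connection class.

    Weights in nS; a single scalar initial weight per class (every edge of a
    class starts identical).  ``w_ext_*`` are the conductance jumps per
    external Poisson spike for each population's external channel.
    """

    w_EE: float = 1.5
    w_EE_min: float = 0.0
    w_EE_max: float = 12.5
    w_EI: float = 12.5
    w_EI_min: float = 1.0
    w_EI_max: float = 37.5
    w_IE: float = 1.25
    w_II: float = 16.0
    w_RE: float = 0.1
    w_RE_min: float = 0.0
    w_RE_max: float = 1.5
    w_SR: float = 300.0
    w_HR: float = 900.0
    w_ext_exc_E: float = 12.0
    w_ext_inh_E: float = 12.0
    w_ext_I: float = 1.6
    w_ext_S: float = 12.0
    w_ext_H: float = 12.0
    delay: float = 1.0  # ms, synaptic delay d (all recurrent classes)


@dataclass
class VoltageSTDPParams:
    """Voltage-based STDP (EE and RE classes).

    Depression is a per-presynaptic-spike jump gated by the slow voltage trace
    u; potentiation is a continuous term gated by the instantaneous voltage V
    and the fast trace v, scaled by the presynaptic spike trace x.  ``alpha``
    (1/ms) fixes the units of the spike-trace jumps.
    """

    A_LTD: float = 1.25e-4  # nS / mV per presynaptic spike (EE)
    A_LTP: float = 3.25e-5  # nS / (mV^2 ms) (EE)
    A_LTD_RE: float = 2.0e-3  # RE depression rate (the RE class has its own rates)
    A_LTP_RE: float = 2.0e-3  # RE potentiation rate
    theta_LTD: float = -70.0  # mV
    theta_LTP: float = -49.0  # mV
    tau_u: float = 10.0  # ms
    tau_v: float = 7.0  # ms
    tau_x_EE: float = 9.0  # ms
    tau_x_RE: float = 5.0  # ms
    alpha: float = 1.0  # 1/ms


@dataclass
class InhibPlasticityParams:
    """Inhibitory plasticity with a target rate (EI class)."""

    A_inh: float = 0.3  # nS per trace unit
    r0: float = 0.005  # spk/ms target rate (5 Hz at the full-scale duty cycle)
    tau_y: float = 20.0  # ms
    alpha: float = 1.0  # 1/ms


@dataclass
class NormalizationParams:
    """Periodic subtractive normalization of incoming EE weights."""

    interval_ms: float = 450.0  # tau_norm
    enabled: bool = True


@dataclass
class StimulationParams:
    """External Poisson drive rates (Hz) and protocol timings (ms)."""

    rexc1E: float = 22500.0  # phase-1 cluster excitation
    rinhE: float = 4500.0  # phase-1 inhibition of inactive clusters
    rexcI: float = 2250.0  # constant drive to I neurons
    rexc2E: float = 1200.0  # phase-2 / replay spontaneous drive to E
    rexcS: float = 10000.0  # supervisor drive during its element
    rbaseS: float = 1000.0  # supervisor baseline
    rexcH: float = 1000.0  # interneuron drive during read-out training
    t_stim: float = 9.0  # per-cluster excitation window
    t_gap: float = 6.0  # gap between cluster windows
    lead: float = 25.0  # lead time before the first element
    t_element: float = 75.0  # per-element presentation window


@dataclass
class ProtocolParams:
    """Durations of the learning workflow stages (ms of biological time)."""

    phase1_ms: float = 3_600_000.0
    phase2_ms: float = 3_600_000.0
    readout_ms: float = 12_000.0
    warmup_ms: float = 50.0
    replay_ms: float = 2_000.0


@dataclass
class NetworkParams:
    N_E: int = 2400
    N_I: int = 600
    N_C: int = 30
    N_R: int = 3
    p_EE: float = 0.2
    p_EI: float = 0.2
    p_IE: float = 0.2
    p_II: float = 0.2


@dataclass
class TriggerParams:
    """Clock-phase trigger used to lock read-out presentations to the cycle.

    Presentations start when the smoothed population rate of the reference
    cluster (cluster 0) crosses ``threshold`` from below, at least
    ``lockout_frac`` of the nominal period after the previous trigger.
    """

    tau_ms: float = 3.0  # exponential smoothing constant of the rate
    threshold: float = 1.0  # spk/ms (population rate of the reference cluster)
    lockout_frac: float = 0.6


@dataclass
class Seeds:
    topology: int = 1
    stimulus: int = 2
    dynamics: int = 3


@dataclass
class SimulationConfig:
    dt: float = 0.1  # ms
    network: NetworkParams = field(default_factory=NetworkParams)
    neuron_E: AdExParams = field(default_factory=AdExParams)
    neuron_R: AdExParams = field(
        default_factory=lambda: AdExParams(gamma=0.0, A_T=6.0, tau_T=15.0))
    neuron_S: AdExParams = field(
        default_factory=lambda: AdExParams(gamma=0.0, A_T=10.0, tau_T=30.0))
    neuron_I: LIFParams = field(default_factory=LIFParams)
    neuron_H: LIFParams = field(default_factory=LIFParams)
    kernel: SynapticKernelParams = field(default_factory=SynapticKernelParams)
    weights: WeightParams = field(default_factory=WeightParams)
    stdp: VoltageSTDPParams = field(default_factory=VoltageSTDPParams)
    inhib: InhibPlasticityParams = field(default_factory=InhibPlasticityParams)
    norm: NormalizationParams = field(default_factory=NormalizationParams)
    stim: StimulationParams = field(default_factory=StimulationParams)
    protocol: ProtocolParams = field(default_factory=ProtocolParams)
    trigger: TriggerParams = field(default_factory=TriggerParams)
    seeds: Seeds = field(default_factory=Seeds)

    def copy(self) -> "SimulationConfig":
        return copy.deepcopy(self)


def full_scale_config() -> SimulationConfig:
    """The full-size configuration: 2400 E / 600 I / 30 clusters, 1 h + 1 h."""
    return SimulationConfig()


def desk_config() -> SimulationConfig:
    """Scaled-down preset that trains in minutes on one core.

    10 clusters x 20 E neurons, 100 I neurons, 5 min per clock-learning phase.
    Connection probability and weights are rescaled so per-neuron in-degrees
    and total synaptic drive stay comparable to the full-scale network, and
    learning rates are raised so structure emerges within the shorter phases.
    Quantitative full-scale targets (470 ms period etc.) are not asserted at
    this scale.
    """
    cfg = SimulationConfig()
    cfg.network = NetworkParams(
        N_E=200, N_I=100, N_C=10, N_R=3,
        p_EE=0.5, p_EI=0.5, p_IE=0.5, p_II=0.5,
    )
    w = cfg.weights
    w.w_EE = 7.0; w.w_EE_min = 0.0; w.w_EE_max = 60.0
    w.w_EI = 30.0; w.w_EI_min = 1.0; w.w_EI_max = 90.0
    w.w_IE = 6.0
    w.w_II = 38.0
    w.w_RE = 0.3; w.w_RE_min = 0.0; w.w_RE_max = 6.0
    cfg.stdp.A_LTD = 5.0e-4
    cfg.stdp.A_LTP = 1.3e-4
    # target rate scaled to the shorter cycle: one cluster of 10 active at a
    # time -> 10% duty instead of 3.3% at 30 clusters
    cfg.inhib.r0 = 0.022
    cfg.protocol.phase1_ms = 300_000.0
    cfg.protocol.phase2_ms = 300_000.0
    cfg.protocol.readout_ms = 12_000.0
    cfg.protocol.replay_ms = 2_000.0
    # Presentation scaled to the desk clock (period 150 ms): 10 ms lead +
    # 4 x 30 ms elements (ABCB) = 130 ms < period.
    cfg.stim.lead = 10.0
    cfg.stim.t_element = 30.0
    return cfg


# ---------------------------------------------------------------------------
# dict <-> dataclass conversion (strict: unknown keys are rejected)
# ---------------------------------------------------------------------------

def _from_dict(cls: type, data: dict[str, Any], path: str = "") -> Any:
    if not isinstance(data, dict):
        raise ConfigError(f"{path or cls.__name__}: expected a mapping, got {type(data).__name__}")
    names = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(names)
    if unknown:
        raise ConfigError(f"{path or cls.__name__}: unknown keys {sorted(unknown)}")
    kwargs: dict[str, Any] = {}
    for key, value in data.items():
        ftype = _FIELD_TYPES.get((cls, key))
        if ftype is not None:
            kwargs[key] = _from_dict(ftype, value, f"{path}{key}.")
        else:
            kwargs[key] = value
    return cls(**kwargs)


_FIELD_TYPES: dict[tuple[type, str], type] = {
    (SimulationConfig, "network"): NetworkParams,
    (SimulationConfig, "neuron_E"): AdExParams,
    (SimulationConfig, "neuron_R"): AdExParams,
    (SimulationConfig, "neuron_S"): AdExParams,
    (SimulationConfig, "neuron_I"): LIFParams,
    (SimulationConfig, "neuron_H"): LIFParams,
    (SimulationConfig, "kernel"): SynapticKernelParams,
    (SimulationConfig, "weights"): WeightParams,
    (SimulationConfig, "stdp"): VoltageSTDPParams,
    (SimulationConfig, "inhib"): InhibPlasticityParams,
    (SimulationConfig, "norm"): NormalizationParams,
    (SimulationConfig, "stim"): StimulationParams,
    (SimulationConfig, "protocol"): ProtocolParams,
    (SimulationConfig, "trigger"): TriggerParams,
    (SimulationConfig, "seeds"): Seeds,
}


def config_to_dict(cfg: SimulationConfig) -> dict[str, Any]:
    return dataclasses.asdict(cfg)


def load_config(path: str) -> SimulationConfig:
    """Load and validate a YAML or JSON configuration file."""
    with open(path) as fh:
        text = fh.read()
    if path.endswith(".json"):
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    cfg = _from_dict(SimulationConfig, data or {})
    validate_config(cfg)
    return cfg


def save_config(cfg: SimulationConfig, path: str) -> None:
    data = config_to_dict(cfg)
    with open(path, "w") as fh:
        if path.endswith(".json"):
            json.dump(data, fh, indent=2)
        else:
            yaml.safe_dump(data, fh, sort_keys=False)


def config_hash(cfg: SimulationConfig) -> str:
    """Stable short hash identifying a configuration (for file headers)."""
    blob = json.dumps(config_to_dict(cfg), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def _is_multiple(x: float, dt: float) -> bool:
    n = round(x / dt)
    return abs(x - n * dt) < 1e-9 * max(1.0, abs(x))


def validate_config(cfg: SimulationConfig) -> None:
    """Check cross-field invariants; raise ConfigError listing all violations."""
    errs: list[str] = []

    if cfg.dt <= 0:
        errs.append("dt: must be > 0")
    net = cfg.network
    for name in ("N_E", "N_I", "N_C", "N_R"):
        if getattr(net, name) <= 0:
            errs.append(f"network.{name}: must be > 0")
    if net.N_C > 0 and net.N_E % net.N_C != 0:
        errs.append(
            f"network.N_E: {net.N_E} not divisible by N_C={net.N_C} "
            "(clusters must be of equal size; refusing to truncate)"
        )
    for name in ("p_EE", "p_EI", "p_IE", "p_II"):
        p = getattr(net, name)
        if not 0.0 <= p <= 1.0:
            errs.append(f"network.{name}: probability {p} outside [0, 1]")

    st = cfg.stdp
    if st.theta_LTP <= st.theta_LTD:
        errs.append(
            f"stdp.theta_LTP: {st.theta_LTP} mV must exceed theta_LTD="
            f"{st.theta_LTD} mV (potentiation requires higher depolarization)"
        )
    for name in ("tau_u", "tau_v", "tau_x_EE", "tau_x_RE"):
        if getattr(st, name) <= 0:
            errs.append(f"stdp.{name}: time constant must be > 0")
    ih = cfg.inhib
    if ih.r0 <= 0:
        errs.append("inhib.r0: target rate must be > 0")
    if ih.tau_y <= 0:
        errs.append("inhib.tau_y: time constant must be > 0")

    w = cfg.weights
    for cls, lo, hi in (
        ("EE", w.w_EE_min, w.w_EE_max),
        ("EI", w.w_EI_min, w.w_EI_max),
        ("RE", w.w_RE_min, w.w_RE_max),
    ):
        init = getattr(w, f"w_{cls}")
        if not lo <= init <= hi:
            errs.append(
                f"weights.w_{cls}: initial weight {init} outside plastic "
                f"bounds [{lo}, {hi}]"
            )
    if w.delay <= 0 or not _is_multiple(w.delay, cfg.dt):
        errs.append(f"weights.delay: {w.delay} ms must be a positive multiple of dt={cfg.dt} ms")

    k = cfg.kernel
    for name in ("tau_rise_exc", "tau_decay_exc", "tau_rise_inh", "tau_decay_inh"):
        if getattr(k, name) <= 0:
            errs.append(f"kernel.{name}: must be > 0")
    if k.tau_decay_exc <= k.tau_rise_exc or k.tau_decay_inh <= k.tau_rise_inh:
        errs.append("kernel: decay time constants must exceed rise time constants")
    if k.c_K <= 0:
        errs.append("kernel.c_K: unit-fixing constant must be > 0")

    s = cfg.stim
    for name in ("rexc1E", "rinhE", "rexcI", "rexc2E", "rexcS", "rbaseS", "rexcH"):
        if getattr(s, name) < 0:
            errs.append(f"stim.{name}: rate must be >= 0")
    for name in ("t_stim", "t_gap", "lead", "t_element"):
        val = getattr(s, name)
        if val < 0 or not _is_multiple(val, cfg.dt):
            errs.append(f"stim.{name}: {val} ms must be a non-negative multiple of dt")

    pr = cfg.protocol
    for name in ("phase1_ms", "phase2_ms", "readout_ms", "warmup_ms", "replay_ms"):
        val = getattr(pr, name)
        if val < 0 or not _is_multiple(val, cfg.dt):
            errs.append(f"protocol.{name}: {val} ms must be a non-negative multiple of dt")
    if cfg.norm.interval_ms <= 0 or not _is_multiple(cfg.norm.interval_ms, cfg.dt):
        errs.append(f"norm.interval_ms: {cfg.norm.interval_ms} ms must be a positive multiple of dt")

    # presentation must fit within one clock cycle (nominal period)
    period = net.N_C * (s.t_stim + s.t_gap)
    # number of elements is sequence-dependent; checked again when a sequence
    # is scheduled.  Here only the degenerate case is rejected.
    if s.lead > period:
        errs.append(f"stim.lead: {s.lead} ms exceeds the nominal clock period {period} ms")

    for role in ("neuron_E", "neuron_R", "neuron_S"):
        n = getattr(cfg, role)
        if n.tau_m <= 0 or n.tau_T <= 0 or n.tau_a <= 0 or n.C <= 0:
            errs.append(f"{role}: time constants and C must be > 0")
        if n.V_peak <= n.V_T_rest:
            errs.append(f"{role}.V_peak: spike ceiling must exceed V_T_rest")
    for role in ("neuron_I", "neuron_H"):
        n = getattr(cfg, role)
        if n.tau_m <= 0:
            errs.append(f"{role}.tau_m: must be > 0")
        if n.V_th <= n.V_reset:
            errs.append(f"{role}.V_th: threshold must exceed V_reset")

    if errs:
        raise ConfigError("invalid configuration:\n  - " + "\n  - ".join(errs))


# ---------------------------------------------------------------------------
# parameter table with provenance
# ---------------------------------------------------------------------------

@dataclass
class ParamEntry:
    name: str
    value: float
    unit: str
    provenance: str


_FIG = "figure-caption"
_RC = "replication-choice"

# unit and provenance per (section, field); anything not listed is a
# replication choice.
_UNITS: dict[str, str] = {
    "dt": "ms",
    "network.N_E": "1", "network.N_I": "1", "network.N_C": "1", "network.N_R": "1",
    "network.p_EE": "1", "network.p_EI": "1", "network.p_IE": "1", "network.p_II": "1",
    "stim.rexc1E": "spk/s", "stim.rinhE": "spk/s", "stim.rexcI": "spk/s",
    "stim.rexc2E": "spk/s", "stim.rexcS": "spk/s", "stim.rbaseS": "spk/s",
    "stim.rexcH": "spk/s",
    "stim.t_stim": "ms", "stim.t_gap": "ms", "stim.lead": "ms", "stim.t_element": "ms",
    "norm.interval_ms": "ms",
    "stdp.A_LTD": "nS/mV", "stdp.A_LTP": "nS/(mV^2 ms)",
    "stdp.theta_LTD": "mV", "stdp.theta_LTP": "mV",
    "stdp.tau_u": "ms", "stdp.tau_v": "ms", "stdp.tau_x_EE": "ms",
    "stdp.tau_x_RE": "ms", "stdp.alpha": "1/ms",
    "inhib.A_inh": "nS", "inhib.r0": "spk/ms", "inhib.tau_y": "ms",
    "inhib.alpha": "1/ms",
    "kernel.c_K": "ms",
    "kernel.E_exc": "mV", "kernel.E_inh": "mV",
    "weights.delay": "ms",
}

_PROVENANCE: dict[str, str] = {
    "network.N_E": _FIG, "network.N_I": _FIG, "network.N_C": _FIG,
    "stim.rexc1E": _FIG, "stim.rinhE": _FIG, "stim.rexcS": _FIG,
    "stim.rbaseS": _FIG,
    "stim.t_stim": _FIG, "stim.t_gap": _FIG, "stim.lead": _FIG,
    "stim.t_element": _FIG,
    "norm.interval_ms": _FIG,  # 450 ms normalization interval
    "kernel.c_K": _RC,  # unit-fixing constant, value 1 ms by construction
}


def parameter_table(cfg: SimulationConfig) -> list[ParamEntry]:
    """Flatten the configuration into an auditable (name, value, unit,
    provenance) table.  Refuses unresolved (None / non-finite) entries."""
    entries: list[ParamEntry] = []

    def visit(prefix: str, obj: Any) -> None:
        for f in dataclasses.fields(obj):
            val = getattr(obj, f.name)
            name = f"{prefix}{f.name}" if not prefix else f"{prefix}.{f.name}"
            if dataclasses.is_dataclass(val):
                visit(name, val)
                continue
            if val is None:
                raise ConfigError(f"{name}: unresolved parameter (None)")
            if isinstance(val, bool):
                val = float(val)
            unit = _UNITS.get(name)
            if unit is None:
                # infer from naming conventions
                if any(tok in f.name for tok in ("tau", "t_ref", "_ms", "delay")):
                    unit = "ms"
                elif f.name.startswith(("E_", "V_", "theta", "Delta", "A_T")):
                    unit = "mV"
                elif f.name.startswith("w_"):
                    unit = "nS"
                elif f.name == "C":
                    unit = "pF"
                elif f.name == "b":
                    unit = "pA"
                elif f.name == "a_sub":
                    unit = "nS"
                else:
                    unit = "1"
            prov = _PROVENANCE.get(name, _RC)
            entries.append(ParamEntry(name, float(val), unit, prov))

    visit("", cfg)
    entries.append(
        ParamEntry(
            "derived.phase1_period",
            cfg.network.N_C * (cfg.stim.t_stim + cfg.stim.t_gap),
            "ms",
            "derived",
        )
    )
    return entries
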