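"""Simulation engine: delayed delivery, phase orchestration, workflows.

The engine advances the whole network in chunks through the jitted kernel
and implements the three-stage learning workflow: ``train_clock`` (sequential
stimulation, then spontaneous drive, both with EE/EI plasticity and periodic
EE normalization), ``train_readout`` (clock frozen, RE plastic, supervisor
presentations locked to the clock cycle by an online trigger on cluster 0's
population rate), and ``replay`` (everything frozen, spontaneous drive to
the RNN only).

State persists across phases (no silent resets); the only exception is that
spikes still in flight within the synaptic delay d at a phase boundary are
not carried over (d is 1 ms against multi-minute phases).  Spike times are
reported in ms relative to the start of each phase and are always multiples
of dt.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernel
from .config import AdExParams, ConfigError, LIFParams, SimulationConfig
from .plasticity import inhib_offset
from .stimulation import (
    SequenceSpec,
    StimulusSchedule,
    phase1_period,
    presentation_rates,
    schedule_for_phase,
)
from .topology import NetworkTopology, SynapseState, build_connectivity, init_weights

__all__ = [
    "SpikeRecord",
    "SimState",
    "PhaseResult",
    "run_phase",
    "train_clock",
    "train_readout",
    "replay",
    "NumericalBlowup",
    "SpikeBufferOverflow",
]

POPULATIONS = ("E", "I", "R", "S", "H")


class NumericalBlowup(RuntimeError):
    """A membrane potential became non-finite during integration."""


class SpikeBufferOverflow(RuntimeError):
    """The spike recording buffer filled up (raise rate_cap_hz)."""


@dataclass
class SpikeRecord:
    """Event log: (global neuron id, spike time in ms), with population
    offsets so ids can be mapped back to per-population indices."""

    times_ms: np.ndarray
    gids: np.ndarray
    offsets: dict[str, tuple[int, int]]  # population -> (gid offset, size)

    @property
    def n_spikes(self) -> int:
        return len(self.times_ms)

    def population(self, pop: str) -> tuple[np.ndarray, np.ndarray]:
        """(local neuron ids, spike times in ms) of one population."""
        off, size = self.offsets[pop]
        m = (self.gids >= off) & (self.gids < off + size)
        return self.gids[m] - off, self.times_ms[m]

    @classmethod
    def empty(cls, offsets: dict[str, tuple[int, int]]) -> "SpikeRecord":
        return cls(np.empty(0), np.empty(0, dtype=np.int32), offsets)


def _pack_adex(p: AdExParams, dt: float) -> np.ndarray:
    return np.array([
        p.tau_m, p.E_L, p.Delta_T, p.V_T_rest, p.A_T, p.tau_T, p.V_reset,
        p.V_peak, round(p.t_ref / dt), p.C, p.tau_a, p.b, p.a_sub, p.gamma,
    ])


def _pack_lif(p: LIFParams, dt: float) -> np.ndarray:
    return np.array([p.tau_m, p.E_L, p.V_th, p.V_reset, round(p.t_ref / dt), p.C])


@dataclass
class SimState:
    """Everything that evolves: topology, synapses and neuron state arrays."""

    cfg: SimulationConfig
    topology: NetworkTopology
    synapses: SynapseState
    # E population
    V_E: np.ndarray; VT_E: np.ndarray; a_E: np.ndarray; ref_E: np.ndarray
    xrEe: np.ndarray; xdEe: np.ndarray; xrEi: np.ndarray; xdEi: np.ndarray
    u_E: np.ndarray; v_E: np.ndarray; xEE: np.ndarray; xRE: np.ndarray
    yE: np.ndarray
    # I population
    V_I: np.ndarray; ref_I: np.ndarray
    xrIe: np.ndarray; xdIe: np.ndarray; xrIi: np.ndarray; xdIi: np.ndarray
    yI: np.ndarray
    # R population
    V_R: np.ndarray; VT_R: np.ndarray; a_R: np.ndarray; ref_R: np.ndarray
    xrRe: np.ndarray; xdRe: np.ndarray; xrRi: np.ndarray; xdRi: np.ndarray
    u_R: np.ndarray; v_R: np.ndarray
    # S population
    V_S: np.ndarray; VT_S: np.ndarray; a_S: np.ndarray; ref_S: np.ndarray
    xrSe: np.ndarray; xdSe: np.ndarray
    # H population
    V_H: np.ndarray; ref_H: np.ndarray
    xrHe: np.ndarray; xdHe: np.ndarray

    @classmethod
    def init(cls, cfg: SimulationConfig, topology: NetworkTopology,
             synapses: SynapseState) -> "SimState":
        """Fresh state: V at the resting potential, voltage traces at the
        resting potential, spike traces and conductances at zero."""
        NE, NI, NR = topology.N_E, topology.N_I, topology.N_R
        z = lambda n: np.zeros(n)
        zi = lambda n: np.zeros(n, dtype=np.int64)
        return cls(
            cfg=cfg, topology=topology, synapses=synapses,
            V_E=np.full(NE, cfg.neuron_E.E_L),
            VT_E=np.full(NE, cfg.neuron_E.V_T_rest),
            a_E=z(NE), ref_E=zi(NE),
            xrEe=z(NE), xdEe=z(NE), xrEi=z(NE), xdEi=z(NE),
            u_E=np.full(NE, cfg.neuron_E.E_L), v_E=np.full(NE, cfg.neuron_E.E_L),
            xEE=z(NE), xRE=z(NE), yE=z(NE),
            V_I=np.full(NI, cfg.neuron_I.E_L), ref_I=zi(NI),
            xrIe=z(NI), xdIe=z(NI), xrIi=z(NI), xdIi=z(NI), yI=z(NI),
            V_R=np.full(NR, cfg.neuron_R.E_L),
            VT_R=np.full(NR, cfg.neuron_R.V_T_rest),
            a_R=z(NR), ref_R=zi(NR),
            xrRe=z(NR), xdRe=z(NR), xrRi=z(NR), xdRi=z(NR),
            u_R=np.full(NR, cfg.neuron_R.E_L), v_R=np.full(NR, cfg.neuron_R.E_L),
            V_S=np.full(NR, cfg.neuron_S.E_L),
            VT_S=np.full(NR, cfg.neuron_S.V_T_rest),
            a_S=z(NR), ref_S=zi(NR), xrSe=z(NR), xdSe=z(NR),
            V_H=np.full(NR, cfg.neuron_H.E_L), ref_H=zi(NR),
            xrHe=z(NR), xdHe=z(NR),
        )

    @property
    def offsets(self) -> dict[str, tuple[int, int]]:
        NE, NI, NR = self.topology.N_E, self.topology.N_I, self.topology.N_R
        return {
            "E": (0, NE), "I": (NE, NI), "R": (NE + NI, NR),
            "S": (NE + NI + NR, NR), "H": (NE + NI + 2 * NR, NR),
        }


@dataclass
class TraceDump:
    """Decimated analog traces of selected E neurons over a phase."""

    neuron_ids: np.ndarray
    time_ms: np.ndarray
    V: np.ndarray  # (n_samples, n_neurons)
    V_T: np.ndarray
    a: np.ndarray
    g_e: np.ndarray
    g_i: np.ndarray


@dataclass
class PhaseResult:
    spikes: SpikeRecord
    counts: np.ndarray  # spikes per global neuron id over the phase
    clips: dict[str, int]
    trigger_times_ms: np.ndarray = field(default_factory=lambda: np.empty(0))
    duration_ms: float = 0.0
    traces: TraceDump | None = None
    clip_log: list[tuple[float, dict[str, int]]] = field(default_factory=list)


def _schedule_arrays(schedule: StimulusSchedule, dt: float):
    period_steps = max(int(round(schedule.period_ms / dt)), 1)
    bounds_steps = np.round(schedule.bounds / dt).astype(np.int64)
    seg_of_step = np.empty(period_steps, dtype=np.int32)
    for s in range(schedule.n_segments):
        seg_of_step[bounds_steps[s]:bounds_steps[s + 1]] = s
    lam_exc = schedule.rate_exc * dt * 1e-3
    lam_inh = schedule.rate_inh * dt * 1e-3
    return period_steps, seg_of_step, np.ascontiguousarray(lam_exc), np.ascontiguousarray(lam_inh)


def run_phase(
    state: SimState,
    schedule: StimulusSchedule,
    *,
    duration_ms: float | None = None,
    plastic: tuple[str, ...] = (),
    record: tuple[str, ...] = (),
    seq: SequenceSpec | None = None,
    trigger: bool = False,
    seed: int = 0,
    chunk_ms: float = 20_000.0,
    rate_cap_hz: float = 400.0,
    record_traces: tuple[int, ...] | None = None,
    trace_every: int = 1,
) -> PhaseResult:
    """Advance the network through one protocol phase.

    ``plastic`` selects the classes updated this phase (intersected with the
    class plastic flags; ignored entirely when the synapse state is frozen).
    ``record`` selects populations whose spikes are logged losslessly.
    With ``trigger=True`` (read-out training) the supervisor drive of ``seq``
    is presented once per detected clock cycle, locked to the activation of
    cluster 0.  ``record_traces`` selects E neurons whose analog state
    (V, V_T, a, conductances) is sampled every ``trace_every`` steps.
    """
    cfg = state.cfg
    dt = cfg.dt
    topo, syn = state.topology, state.synapses
    if duration_ms is None:
        duration_ms = schedule.duration_ms
    if duration_ms > schedule.duration_ms + 1e-9:
        raise ConfigError("schedule does not cover the phase duration")
    n_total = int(round(duration_ms / dt))
    offsets = state.offsets
    if n_total == 0:
        return PhaseResult(SpikeRecord.empty(offsets), np.zeros(0, dtype=np.int64),
                           {"EE": 0, "EI": 0, "RE": 0, "norm": 0})

    if syn.frozen:
        plastic = ()
    ee_p = "EE" in plastic and syn.plastic["EE"]
    ei_p = "EI" in plastic and syn.plastic["EI"]
    re_p = "RE" in plastic and syn.plastic["RE"]

    pE = _pack_adex(cfg.neuron_E, dt)
    pR = _pack_adex(cfg.neuron_R, dt)
    pS = _pack_adex(cfg.neuron_S, dt)
    pI = _pack_lif(cfg.neuron_I, dt)
    pH = _pack_lif(cfg.neuron_H, dt)
    k = cfg.kernel
    kern = np.array([k.tau_rise_exc, k.tau_decay_exc, k.tau_rise_inh,
                     k.tau_decay_inh, k.E_exc, k.E_inh, k.c_K])
    st = cfg.stdp
    stdp = np.array([st.A_LTD, st.A_LTP, st.theta_LTD, st.theta_LTP,
                     st.tau_u, st.tau_v, st.tau_x_EE, st.tau_x_RE, st.alpha,
                     st.A_LTD_RE, st.A_LTP_RE])
    ih = cfg.inhib
    inh = np.array([ih.A_inh, inhib_offset(ih), ih.tau_y, ih.alpha])
    w = cfg.weights
    bounds = np.array([w.w_EE_min, w.w_EE_max, w.w_EI_min, w.w_EI_max,
                       w.w_RE_min, w.w_RE_max])
    w_ext = np.array([w.w_ext_exc_E, w.w_ext_inh_E, w.w_ext_I, w.w_ext_S, w.w_ext_H])

    masks = {c: np.ascontiguousarray(topo.adjacency[c]) for c in ("EE", "EI", "IE", "II")}
    W_SR = syn.W["SR"]
    W_HR = syn.W["HR"]
    w_SR = np.ascontiguousarray(np.diag(W_SR)) if W_SR.ndim == 2 else W_SR
    w_HR = np.ascontiguousarray(np.diag(W_HR)) if W_HR.ndim == 2 else W_HR

    d_steps = int(round(topo.delay_ms / dt))
    if d_steps < 1:
        raise ConfigError("synaptic delay must be at least one step")
    depth = d_steps + 2
    NE, NI, NR = topo.N_E, topo.N_I, topo.N_R
    histE_idx = np.zeros((depth, NE), dtype=np.int32); histE_n = np.zeros(depth, dtype=np.int32)
    histI_idx = np.zeros((depth, NI), dtype=np.int32); histI_n = np.zeros(depth, dtype=np.int32)
    histS_idx = np.zeros((depth, NR), dtype=np.int32); histS_n = np.zeros(depth, dtype=np.int32)
    histH_idx = np.zeros((depth, NR), dtype=np.int32); histH_n = np.zeros(depth, dtype=np.int32)

    period_steps, seg_of_step, lam_exc, lam_inh = _schedule_arrays(schedule, dt)
    grp_E = np.ascontiguousarray(topo.cluster_label, dtype=np.int32)
    lay = schedule.layout
    g_I, g_S0, g_H = lay.i_group, lay.s_group(0), lay.h_group

    trig = cfg.trigger
    if trigger:
        if seq is None:
            raise ConfigError("trigger mode requires a sequence")
        lam_pres = np.ascontiguousarray(
            presentation_rates(seq, cfg.stim.rexcS, cfg.stim.rbaseS, dt) * dt * 1e-3)
        p_nom = phase1_period(topo.N_C, cfg.stim.t_stim, cfg.stim.t_gap)
        lockout_steps = int(round(trig.lockout_frac * p_nom / dt))
        decay = float(np.exp(-dt / trig.tau_ms))
        thresh_f = trig.threshold * dt / (1.0 - decay)
    else:
        lam_pres = np.zeros((1, NR))
        lockout_steps = 0
        decay = 0.0
        thresh_f = np.inf
    trig_f = np.zeros(1)
    trig_i = np.array([-1, -10 ** 9], dtype=np.int64)
    n_trig_cap = n_total // max(lockout_steps, 1) + 16 if trigger else 1
    trig_times = np.zeros(n_trig_cap, dtype=np.int64)
    trig_n = np.zeros(1, dtype=np.int64)

    rec_flags = np.array([p in record for p in POPULATIONS], dtype=np.bool_)
    n_rec_neurons = sum(offsets[p][1] for p in POPULATIONS if p in record)
    norm_steps = int(round(cfg.norm.interval_ms / dt)) if cfg.norm.enabled else 0

    all_t: list[np.ndarray] = []
    all_g: list[np.ndarray] = []
    counts = np.zeros(NE + NI + 3 * NR, dtype=np.int64)
    clips = np.zeros(4, dtype=np.int64)
    err = np.zeros(3, dtype=np.int64)

    trace_idx = np.asarray(record_traces if record_traces else [], dtype=np.int32)
    if trace_every < 1:
        raise ConfigError("trace_every must be >= 1")
    trace_rows: list[dict[str, np.ndarray]] = []
    clip_log: list[tuple[float, dict[str, int]]] = []
    clips_prev = np.zeros(4, dtype=np.int64)

    chunk_steps = max(int(round(chunk_ms / dt)), 1)
    step0 = 0
    while step0 < n_total:
        n_chunk = min(chunk_steps, n_total - step0)
        cap = int(n_rec_neurons * (n_chunk * dt) * rate_cap_hz * 1e-3) + 1024 \
            if n_rec_neurons else 1
        rec_t = np.zeros(cap, dtype=np.int64)
        rec_gid = np.zeros(cap, dtype=np.int32)
        rec_n = np.zeros(1, dtype=np.int64)
        chunk_seed = (seed * 1_000_003 + step0 // chunk_steps + 7) % (2 ** 31 - 1)
        n_sel = len(trace_idx)
        tr_cap = n_chunk // trace_every + 1 if n_sel else 1
        tr_V = np.zeros((tr_cap, max(n_sel, 1)))
        tr_VT = np.zeros_like(tr_V); tr_a = np.zeros_like(tr_V)
        tr_ge = np.zeros_like(tr_V); tr_gi = np.zeros_like(tr_V)
        tr_n = np.zeros(1, dtype=np.int64)
        _kernel.simulate_chunk(
            n_chunk, step0, dt, chunk_seed,
            pE, pI, pR, pS, pH, kern, stdp, inh, bounds, w_ext,
            syn.W["EE"], masks["EE"], syn.W["EI"], masks["EI"],
            syn.W["IE"], masks["IE"], syn.W["II"], masks["II"],
            syn.W["RE"], w_SR, w_HR,
            syn.K, ee_p, ei_p, re_p, norm_steps,
            state.V_E, state.VT_E, state.a_E, state.ref_E,
            state.xrEe, state.xdEe, state.xrEi, state.xdEi,
            state.u_E, state.v_E, state.xEE, state.xRE, state.yE,
            state.V_I, state.ref_I,
            state.xrIe, state.xdIe, state.xrIi, state.xdIi, state.yI,
            state.V_R, state.VT_R, state.a_R, state.ref_R,
            state.xrRe, state.xdRe, state.xrRi, state.xdRi,
            state.u_R, state.v_R,
            state.V_S, state.VT_S, state.a_S, state.ref_S,
            state.xrSe, state.xdSe,
            state.V_H, state.ref_H, state.xrHe, state.xdHe,
            d_steps, histE_idx, histE_n, histI_idx, histI_n,
            histS_idx, histS_n, histH_idx, histH_n,
            period_steps, seg_of_step, lam_exc, lam_inh, grp_E,
            g_I, g_S0, g_H,
            trigger, decay, thresh_f, lockout_steps, lam_pres,
            trig_f, trig_i, trig_times, trig_n,
            rec_flags, rec_t, rec_gid, rec_n, counts,
            trace_idx, trace_every, tr_V, tr_VT, tr_a, tr_ge, tr_gi, tr_n,
            clips, err,
        )
        if err[0] == 1:
            raise NumericalBlowup(
                f"non-finite membrane potential at neuron gid {err[1]}, "
                f"t = {(err[2] + 1) * dt:.1f} ms into the phase"
            )
        if err[0] == 2:
            raise SpikeBufferOverflow(
                "spike buffer overflowed; increase rate_cap_hz in run_phase"
            )
        m = int(rec_n[0])
        if m:
            all_t.append(rec_t[:m] * dt)
            all_g.append(rec_gid[:m].copy())
        if n_sel:
            k = int(tr_n[0])
            trace_rows.append({"V": tr_V[:k], "V_T": tr_VT[:k], "a": tr_a[:k],
                               "g_e": tr_ge[:k], "g_i": tr_gi[:k]})
        step0 += n_chunk
        delta = clips - clips_prev
        clip_log.append((step0 * dt, {"EE": int(delta[0]), "EI": int(delta[1]),
                                      "RE": int(delta[2]), "norm": int(delta[3])}))
        clips_prev = clips.copy()

    if all_t:
        spikes = SpikeRecord(np.concatenate(all_t), np.concatenate(all_g), offsets)
    else:
        spikes = SpikeRecord.empty(offsets)
    traces = None
    if len(trace_idx):
        joined = {k: np.concatenate([r[k] for r in trace_rows])
                  for k in ("V", "V_T", "a", "g_e", "g_i")}
        n_samples = joined["V"].shape[0]
        time_ms = (np.arange(1, n_samples + 1) * trace_every) * dt
        traces = TraceDump(neuron_ids=trace_idx.copy(), time_ms=time_ms,
                           **joined)
    return PhaseResult(
        spikes=spikes,
        counts=counts,
        clips={"EE": int(clips[0]), "EI": int(clips[1]),
               "RE": int(clips[2]), "norm": int(clips[3])},
        trigger_times_ms=trig_times[:int(trig_n[0])] * dt,
        duration_ms=duration_ms,
        traces=traces,
        clip_log=clip_log,
    )


# ---------------------------------------------------------------------------
# learning workflow
# ---------------------------------------------------------------------------

@dataclass
class ClockTrainingResult:
    state: SimState
    W_after_phase1: np.ndarray
    W_after_phase2: np.ndarray
    phase1: PhaseResult
    phase2: PhaseResult


def train_clock(cfg: SimulationConfig, *, freeze: bool = True) -> ClockTrainingResult:
    """Learn the neural clock: sequential phase, then spontaneous phase.

    EE and EI synapses are plastic in both phases; EE weights are normalized
    every tau_norm.  After the second phase the clock weights are frozen (the
    read-out stage never modifies them).
    """
    topo = build_connectivity(cfg, cfg.seeds.topology)
    syn = init_weights(topo, cfg)
    state = SimState.init(cfg, topo, syn)

    sched1 = schedule_for_phase(cfg, "phase1")
    res1 = run_phase(state, sched1, plastic=("EE", "EI"),
                     seed=cfg.seeds.dynamics)
    W1 = syn.W["EE"].copy()

    sched2 = schedule_for_phase(cfg, "phase2")
    res2 = run_phase(state, sched2, plastic=("EE", "EI"),
                     seed=cfg.seeds.dynamics + 1)
    W2 = syn.W["EE"].copy()

    if freeze:
        syn.frozen = True
    return ClockTrainingResult(state, W1, W2, res1, res2)


def train_readout(state: SimState, seq: SequenceSpec,
                  cfg: SimulationConfig | None = None) -> PhaseResult:
    """Teach the read-out layer a sequence with the clock frozen.

    A short warmup under spontaneous drive (RNN only) re-establishes the
    sequential dynamics; presentations are then locked to each detected
    activation of cluster 0.  Only RE synapses are plastic; the frozen clock
    weights are untouched.  Raises if the presentation does not fit within
    one nominal clock cycle.
    """
    if cfg is None:
        cfg = state.cfg
    if not state.synapses.frozen:
        raise ConfigError("clock weights must be frozen before read-out training")
    p_nom = phase1_period(state.topology.N_C, cfg.stim.t_stim, cfg.stim.t_gap)
    if seq.presentation_ms > p_nom + 1e-9:
        raise ConfigError(
            f"presentation of {seq.presentation_ms} ms exceeds the clock "
            f"period of {p_nom} ms"
        )
    if seq.n_readout != state.topology.N_R:
        raise ConfigError("sequence alphabet size differs from the number of read-out neurons")

    warm = schedule_for_phase(cfg, "warmup")
    run_phase(state, warm, seed=cfg.seeds.dynamics + 2)

    # RE must be temporarily plastic although the clock is frozen
    state.synapses.frozen = False
    try:
        s = cfg.stim
        sched = schedule_for_phase(cfg, "phase2", T_ms=cfg.protocol.readout_ms)
        # constant S baseline + H drive on top of spontaneous RNN drive
        lay = sched.layout
        for kk in range(state.topology.N_R):
            sched.rate_exc[:, lay.s_group(kk)] = s.rbaseS
        sched.rate_exc[:, lay.h_group] = s.rexcH
        result = run_phase(
            state, sched, plastic=("RE",), seq=seq, trigger=True,
            seed=cfg.seeds.dynamics + 3,
        )
    finally:
        state.synapses.frozen = True
    return result


def replay(state: SimState, duration_ms: float | None = None,
           cfg: SimulationConfig | None = None,
           record: tuple[str, ...] = ("E", "I", "R")) -> PhaseResult:
    """Autonomous replay: spontaneous drive to the RNN alone, all frozen.

    Supervisor neurons and interneurons receive no external input; read-out
    spikes are driven purely by the clock through the learned RE weights.
    """
    if cfg is None:
        cfg = state.cfg
    if duration_ms is None:
        duration_ms = cfg.protocol.replay_ms
    if not state.synapses.frozen:
        raise ConfigError("replay requires frozen weights")
    sched = schedule_for_phase(cfg, "replay", T_ms=duration_ms)
    return run_phase(state, sched, record=record, seed=cfg.seeds.dynamics + 4)
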