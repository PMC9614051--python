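"""External Poisson drive: schedules as piecewise-constant rate functions.

Three kinds of drive are used by the learning protocol:

* phase 1 -- sequential cluster stimulation: clusters are excited one by one
  (t_stim each, separated by t_gap) and receive inhibitory external drive
  whenever they are not excited; the inhibitory population is driven at a
  constant rate throughout;
* phase 2 / replay -- spontaneous (unstructured) constant drive;
* read-out training -- per-element supervisor windows locked to the clock
  cycle, with constant interneuron drive.

A schedule assigns rates per *drive group*; the groups are the N_C clusters,
the I population, the R population (never driven), one group per supervisor
neuron, and the H population.  Rates are in spikes/s, times in ms.  Each
neuron of a group independently samples a Poisson spike count per time bin
(full Poisson counts, not Bernoulli -- at the stimulation rates used here the
expected count per 0.1 ms bin exceeds 2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import ConfigError, SimulationConfig

__all__ = [
    "SequenceSpec",
    "StimulusSchedule",
    "group_layout",
    "sequential_schedule",
    "spontaneous_schedule",
    "readout_schedule",
    "sample_poisson",
    "phase1_period",
    "rounds_in",
    "presentation_rates",
]


def phase1_period(N_C: int, t_stim: float, t_gap: float) -> float:
    """Period of the sequential stimulation pattern: N_C * (t_stim + t_gap)."""
    return N_C * (t_stim + t_gap)


def rounds_in(T_ms: float, period_ms: float) -> int:
    """Complete stimulation rounds within T_ms: floor(T / P)."""
    return int(np.floor(T_ms / period_ms + 1e-9))


@dataclass(frozen=True)
class SequenceSpec:
    """An ordered sequence of elements over an alphabet, one R/S/H triple per
    alphabet symbol.  ``elements`` may repeat symbols (higher-order
    sequences such as ABCBA); ``alphabet`` order fixes the read-out index."""

    elements: tuple[str, ...]
    alphabet: tuple[str, ...]
    t_element: float  # ms per element presentation
    lead: float  # ms of lead time before the first element

    def __post_init__(self):
        if len(set(self.alphabet)) != len(self.alphabet):
            raise ConfigError("sequence alphabet contains duplicate symbols")
        unknown = [e for e in self.elements if e not in self.alphabet]
        if unknown:
            raise ConfigError(f"sequence elements {unknown} not in alphabet {self.alphabet}")

    @classmethod
    def from_string(cls, s: str, t_element: float, lead: float) -> "SequenceSpec":
        return cls(tuple(s), tuple(sorted(set(s))), t_element, lead)

    @property
    def n_readout(self) -> int:
        return len(self.alphabet)

    @property
    def element_indices(self) -> tuple[int, ...]:
        return tuple(self.alphabet.index(e) for e in self.elements)

    @property
    def presentation_ms(self) -> float:
        """Total presentation duration: lead + len(elements) * t_element."""
        return self.lead + len(self.elements) * self.t_element


@dataclass(frozen=True)
class GroupLayout:
    """Index bookkeeping for drive groups (clusters, I, R, S_k, H)."""

    N_C: int
    N_R: int

    @property
    def n_groups(self) -> int:
        return self.N_C + self.N_R + 3

    @property
    def i_group(self) -> int:
        return self.N_C

    @property
    def r_group(self) -> int:
        return self.N_C + 1

    def s_group(self, k: int) -> int:
        return self.N_C + 2 + k

    @property
    def h_group(self) -> int:
        return self.N_C + 2 + self.N_R

    def names(self) -> list[str]:
        return (
            [f"cluster{c}" for c in range(self.N_C)]
            + ["I", "R"]
            + [f"S{k}" for k in range(self.N_R)]
            + ["H"]
        )


def group_layout(N_C: int, N_R: int) -> GroupLayout:
    return GroupLayout(N_C, N_R)


@dataclass
class StimulusSchedule:
    """Piecewise-constant rates over one period, tiled over [0, duration).

    ``bounds`` are the segment boundaries in ms (length n_seg + 1, from 0 to
    ``period_ms``); ``rate_exc``/``rate_inh`` have shape (n_seg, n_groups) in
    spikes/s.  Every neuron of a group receives an independent Poisson
    realization of its group's rate on each channel.
    """

    duration_ms: float
    period_ms: float
    bounds: np.ndarray
    rate_exc: np.ndarray
    rate_inh: np.ndarray
    layout: GroupLayout
    kind: str = "custom"

    @property
    def n_segments(self) -> int:
        return len(self.bounds) - 1

    def _segment(self, t: float) -> int:
        if self.duration_ms == 0:
            raise ConfigError("empty schedule (duration 0) has no rates")
        tp = t % self.period_ms
        i = int(np.searchsorted(self.bounds, tp, side="right")) - 1
        return min(max(i, 0), self.n_segments - 1)

    def rate_at(self, group: int, t: float, channel: str = "exc") -> float:
        """Rate (spk/s) of a drive group at time t on one channel."""
        seg = self._segment(t)
        table = self.rate_exc if channel == "exc" else self.rate_inh
        return float(table[seg, group])

    def cluster_rates(self, c: int, t: float) -> tuple[float, float]:
        """(excitatory, inhibitory) external rate of cluster c at time t."""
        return self.rate_at(c, t, "exc"), self.rate_at(c, t, "inh")


def _check_multiple(name: str, value: float, dt: float) -> None:
    n = round(value / dt)
    if abs(value - n * dt) > 1e-9 * max(1.0, abs(value)):
        raise ConfigError(f"{name}={value} ms is not an integer multiple of dt={dt} ms")


def sequential_schedule(
    N_C: int, t_stim: float, t_gap: float,
    rexc1E: float, rinhE: float, rexcI: float,
    T_ms: float, *, N_R: int = 1, dt: float = 0.1,
) -> StimulusSchedule:
    """Phase-1 drive: cluster c is excited during
    [k*P + c*(t_stim+t_gap), ... + t_stim) for every round k, with
    P = N_C*(t_stim+t_gap), and receives inhibitory drive at all other
    times (exactly one of the two channels is active for every E neuron at
    every instant).  I neurons are driven at rexcI throughout."""
    if T_ms < 0:
        raise ConfigError("T must be >= 0")
    for name, v in (("t_stim", t_stim), ("t_gap", t_gap), ("T", T_ms)):
        _check_multiple(name, v, dt)
    lay = group_layout(N_C, N_R)
    period = phase1_period(N_C, t_stim, t_gap)
    bounds = [0.0]
    rate_exc = []
    rate_inh = []
    for c in range(N_C):
        # excitation window of cluster c, then the gap before cluster c+1
        for width, excited in ((t_stim, True), (t_gap, False)):
            if width == 0:
                continue
            bounds.append(bounds[-1] + width)
            re = np.zeros(lay.n_groups)
            ri = np.zeros(lay.n_groups)
            ri[:N_C] = rinhE
            if excited:
                re[c] = rexc1E
                ri[c] = 0.0
            re[lay.i_group] = rexcI
            rate_exc.append(re)
            rate_inh.append(ri)
    return StimulusSchedule(
        duration_ms=T_ms, period_ms=period, bounds=np.array(bounds),
        rate_exc=np.array(rate_exc), rate_inh=np.array(rate_inh),
        layout=lay, kind="sequential",
    )


def spontaneous_schedule(
    rexc2E: float, rexcI: float, T_ms: float,
    *, N_C: int, N_R: int = 1, rexcH: float = 0.0, rbaseS: float = 0.0,
    dt: float = 0.1,
) -> StimulusSchedule:
    """Unstructured constant drive: rexc2E on all E, rexcI on all I; S and H
    rates default to silent (replay) and can be set for warm phases."""
    if T_ms < 0:
        raise ConfigError("T must be >= 0")
    _check_multiple("T", T_ms, dt)
    lay = group_layout(N_C, N_R)
    re = np.zeros((1, lay.n_groups))
    ri = np.zeros((1, lay.n_groups))
    re[0, :N_C] = rexc2E
    re[0, lay.i_group] = rexcI
    for k in range(N_R):
        re[0, lay.s_group(k)] = rbaseS
    re[0, lay.h_group] = rexcH
    period = max(T_ms, dt)
    return StimulusSchedule(
        duration_ms=T_ms, period_ms=period, bounds=np.array([0.0, period]),
        rate_exc=re, rate_inh=ri, layout=lay, kind="spontaneous",
    )


def readout_schedule(
    seq: SequenceSpec,
    rexcS: float, rbaseS: float, rexcH: float, rexc2E: float, rexcI: float,
    n_repeats: int, clock_period: float,
    *, N_C: int, dt: float = 0.1,
) -> StimulusSchedule:
    """Read-out training drive, one presentation per clock cycle.

    Element k's supervisor is driven at rexcS during
    [lead + k*t_element, lead + (k+1)*t_element) of each repetition and at
    rbaseS otherwise; H neurons are driven constantly; repetitions are locked
    to clock-period boundaries.  The presentation must fit within one clock
    cycle."""
    for name, v in (("t_element", seq.t_element), ("lead", seq.lead),
                    ("clock_period", clock_period)):
        _check_multiple(name, v, dt)
    if seq.presentation_ms > clock_period + 1e-9:
        raise ConfigError(
            f"presentation of {seq.presentation_ms} ms exceeds the clock "
            f"period of {clock_period} ms; the presentation time of a "
            "sequence may not exceed the duration of a clock cycle"
        )
    lay = group_layout(N_C, seq.n_readout)
    bounds = [0.0]
    segs: list[tuple[float, int | None]] = []  # (width, active element R index)
    if seq.lead > 0:
        segs.append((seq.lead, None))
    for k in seq.element_indices:
        segs.append((seq.t_element, k))
    tail = clock_period - seq.presentation_ms
    if tail > 0:
        segs.append((tail, None))
    rate_exc = []
    rate_inh = []
    for width, active in segs:
        bounds.append(bounds[-1] + width)
        re = np.zeros(lay.n_groups)
        ri = np.zeros(lay.n_groups)
        re[:N_C] = rexc2E
        re[lay.i_group] = rexcI
        for k in range(seq.n_readout):
            re[lay.s_group(k)] = rexcS if k == active else rbaseS
        re[lay.h_group] = rexcH
        rate_exc.append(re)
        rate_inh.append(ri)
    return StimulusSchedule(
        duration_ms=n_repeats * clock_period, period_ms=clock_period,
        bounds=np.array(bounds), rate_exc=np.array(rate_exc),
        rate_inh=np.array(rate_inh), layout=lay, kind="readout",
    )


def presentation_rates(
    seq: SequenceSpec, rexcS: float, rbaseS: float, dt: float
) -> np.ndarray:
    """Per-step supervisor rates (spk/s) over one presentation, shape
    (presentation_steps, n_readout).  Used by the trigger-locked engine mode
    to overlay a presentation at each detected clock-cycle start."""
    steps = int(round(seq.presentation_ms / dt))
    out = np.full((steps, seq.n_readout), rbaseS, dtype=float)
    lead_steps = int(round(seq.lead / dt))
    el_steps = int(round(seq.t_element / dt))
    for pos, k in enumerate(seq.element_indices):
        s0 = lead_steps + pos * el_steps
        out[s0:s0 + el_steps, :] = rbaseS
        out[s0:s0 + el_steps, k] = rexcS
    return out


def sample_poisson(
    schedule: StimulusSchedule, dt: float, rng: np.random.Generator | int
) -> tuple[np.ndarray, np.ndarray]:
    """Sample per-bin Poisson spike counts for one neuron of every group.

    Returns (counts_exc, counts_inh), each of shape (n_steps, n_groups).
    Counts in a bin follow the Poisson law with mean rate*dt; bins are
    independent; the same seed reproduces the same counts exactly.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    n_steps = int(round(schedule.duration_ms / dt))
    lam_e = np.empty((n_steps, schedule.layout.n_groups))
    lam_i = np.empty_like(lam_e)
    for n in range(n_steps):
        seg = schedule._segment(n * dt)
        lam_e[n] = schedule.rate_exc[seg] * dt * 1e-3
        lam_i[n] = schedule.rate_inh[seg] * dt * 1e-3
    return rng.poisson(lam_e), rng.poisson(lam_i)


def schedule_for_phase(cfg: SimulationConfig, phase: str,
                       T_ms: float | None = None) -> StimulusSchedule:
    """Convenience builder of the standard schedules from a configuration."""
    s, net = cfg.stim, cfg.network
    if phase == "phase1":
        return sequential_schedule(
            net.N_C, s.t_stim, s.t_gap, s.rexc1E, s.rinhE, s.rexcI,
            cfg.protocol.phase1_ms if T_ms is None else T_ms,
            N_R=net.N_R, dt=cfg.dt,
        )
    if phase in ("phase2", "replay", "warmup"):
        if T_ms is None:
            T_ms = {"phase2": cfg.protocol.phase2_ms,
                    "replay": cfg.protocol.replay_ms,
                    "warmup": cfg.protocol.warmup_ms}[phase]
        return spontaneous_schedule(
            s.rexc2E, s.rexcI, T_ms, N_C=net.N_C, N_R=net.N_R, dt=cfg.dt,
        )
    raise ConfigError(f"unknown phase '{phase}'")
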