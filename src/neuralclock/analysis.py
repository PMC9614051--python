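"""Result objects: block weight structure, spectra, clock metrics, decoding.

These are the measurements used to verify the learned network: the N_C x N_C
matrix of mean inter-cluster EE weights (the learned ring reads as a strong
superdiagonal), the eigenvalue spectrum of the full signed weight matrix
(leading ring, circular-law bulk, E/I balance pair), the clock period and
per-cluster activation statistics extracted from spike rasters, and the
decoder that reads the replayed element sequence off the read-out spikes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .engine import SpikeRecord
from .topology import NetworkTopology, SynapseState

__all__ = [
    "ClusterBlockMatrix",
    "SpectrumResult",
    "ClockMetrics",
    "DecodeResult",
    "cluster_block_means",
    "build_signed_matrix",
    "full_spectrum",
    "clock_metrics",
    "decode_replay",
]


# ---------------------------------------------------------------------------
# block structure
# ---------------------------------------------------------------------------

@dataclass
class ClusterBlockMatrix:
    """Mean EE weight between cluster pairs; entry (a, b) averages the
    existing edges from cluster b onto cluster a.  Empty blocks are NaN
    (recorded as missing, never as zero)."""

    means: np.ndarray  # (N_C, N_C), target row, source column
    counts: np.ndarray  # (N_C, N_C) edge counts

    @property
    def n_clusters(self) -> int:
        return self.means.shape[0]

    def diagonal_mean(self) -> float:
        return float(np.nanmean(np.diag(self.means)))

    def superdiagonal_mean(self) -> float:
        """Mean feedforward weight cluster i -> i+1 (wrap-around included)."""
        n = self.n_clusters
        return float(np.nanmean([self.means[(i + 1) % n, i] for i in range(n)]))

    def subdiagonal_mean(self) -> float:
        """Mean backward weight cluster i -> i-1 (wrap-around included)."""
        n = self.n_clusters
        return float(np.nanmean([self.means[(i - 1) % n, i] for i in range(n)]))

    def distant_mean(self) -> float:
        """Mean weight over all blocks other than diagonal and first off-ring."""
        n = self.n_clusters
        vals = []
        for a in range(n):
            for b in range(n):
                if a == b or a == (b + 1) % n or a == (b - 1) % n:
                    continue
                vals.append(self.means[a, b])
        return float(np.nanmean(vals)) if vals else float("nan")


def cluster_block_means(W_EE: np.ndarray, labels: np.ndarray,
                        mask: np.ndarray) -> ClusterBlockMatrix:
    """Average EE weights per ordered cluster pair over existing edges only."""
    labels = np.asarray(labels)
    n_c = int(labels.max()) + 1
    means = np.full((n_c, n_c), np.nan)
    counts = np.zeros((n_c, n_c), dtype=np.int64)
    for a in range(n_c):
        rows = labels == a
        for b in range(n_c):
            cols = labels == b
            m = mask[np.ix_(rows, cols)]
            cnt = int(m.sum())
            counts[a, b] = cnt
            if cnt:
                means[a, b] = W_EE[np.ix_(rows, cols)][m].mean()
    return ClusterBlockMatrix(means, counts)


# ---------------------------------------------------------------------------
# spectrum
# ---------------------------------------------------------------------------

@dataclass
class SpectrumResult:
    """Eigenvalues of the full signed RNN weight matrix.

    ``leading`` are the n_leading eigenvalues of largest real part (the ring
    signalling the learned cyclic feedforward structure); ``balance_pair``
    is the conjugate pair with the most negative real part; ``bulk_radius``
    estimates the circular-law radius of the remaining bulk.
    """

    eigenvalues: np.ndarray
    leading: np.ndarray
    balance_pair: np.ndarray
    bulk_radius: float


def build_signed_matrix(syn: SynapseState, topo: NetworkTopology) -> np.ndarray:
    """Full (N_E+N_I) square matrix with E columns positive, I columns
    negative (target row, source column) -- the adopted sign convention."""
    top = np.hstack([syn.W["EE"], -syn.W["EI"]])
    bot = np.hstack([syn.W["IE"], -syn.W["II"]])
    return np.vstack([top, bot])


def full_spectrum(W_full: np.ndarray, n_leading: int) -> SpectrumResult:
    """All eigenvalues plus the classified subsets."""
    W_full = np.asarray(W_full)
    if W_full.ndim != 2 or W_full.shape[0] != W_full.shape[1]:
        raise ValueError("full_spectrum requires a square matrix")
    ev = np.linalg.eigvals(W_full)
    # the ring members are the eigenvalues of largest modulus: selecting by
    # real part alone cannot recover the left half of the ring
    order = np.argsort(-np.abs(ev))
    leading = ev[order[:n_leading]]
    rest = ev[order[n_leading:]]
    # balance pair: conjugate pair with most negative real part
    tail = ev[np.argsort(ev.real)][:2]
    bulk = rest[rest.real > tail.real.min() + 1e-12] if len(rest) else rest
    radius = float(np.quantile(np.abs(bulk), 0.95)) if len(bulk) else 0.0
    return SpectrumResult(ev, leading, tail, radius)


# ---------------------------------------------------------------------------
# clock metrics
# ---------------------------------------------------------------------------

@dataclass
class ClockMetrics:
    """Sequential-dynamics summary of a spontaneous-drive raster."""

    ok: bool
    periods_ms: np.ndarray
    period_mean_ms: float
    activation_mean_ms: float
    sequentiality: float
    activations: list[tuple[int, float, float]] = field(default_factory=list)
    onsets_ms: np.ndarray = field(default_factory=lambda: np.empty(0))
    message: str = ""


def clock_metrics(
    spikes: SpikeRecord | tuple[np.ndarray, np.ndarray],
    labels: np.ndarray,
    *,
    bin_ms: float = 1.0,
    sigma_ms: float = 2.0,
    rate_threshold_hz: float = 10.0,
    min_run_ms: float = 2.0,
    reference_cluster: int = 0,
) -> ClockMetrics:
    """Estimate clock period, activation durations and sequentiality.

    Per-cluster population rates (per neuron, Hz) are computed in ``bin_ms``
    bins and smoothed with a Gaussian kernel; a cluster is *active* in a bin
    when it holds the arg-max rate and exceeds the threshold.  Activation
    runs shorter than ``min_run_ms`` are treated as noise.  The period is the
    mean interval between successive activation onsets of the reference
    cluster; the sequentiality score is the fraction of activation
    transitions going i -> i+1 (mod N_C).  Returns an explicit
    "no sequential dynamics" result when nothing crosses threshold.
    """
    if isinstance(spikes, SpikeRecord):
        ids, times = spikes.population("E")
    else:
        ids, times = spikes
    labels = np.asarray(labels)
    n_c = int(labels.max()) + 1
    cluster_size = np.bincount(labels, minlength=n_c)
    no_seq = ClockMetrics(False, np.empty(0), float("nan"), float("nan"),
                          0.0, [], np.empty(0), "no sequential dynamics detected")
    if len(times) == 0:
        return no_seq

    t0 = np.floor(times.min() / bin_ms) * bin_ms
    n_bins = int(np.ceil((times.max() - t0) / bin_ms)) + 1
    rate = np.zeros((n_c, n_bins))
    bins = ((times - t0) / bin_ms).astype(np.int64)
    np.add.at(rate, (labels[ids], bins), 1.0)
    rate /= cluster_size[:, None] * bin_ms * 1e-3  # per-neuron Hz
    rate = gaussian_filter1d(rate, sigma_ms / bin_ms, axis=1, mode="constant")

    peak = rate.max(axis=0)
    active = np.where(peak >= rate_threshold_hz, rate.argmax(axis=0), -1)

    # runs of constant activity, noise-filtered
    runs: list[tuple[int, float, float]] = []
    start = 0
    for i in range(1, n_bins + 1):
        if i == n_bins or active[i] != active[start]:
            if active[start] >= 0:
                runs.append((int(active[start]), t0 + start * bin_ms, t0 + i * bin_ms))
            start = i
    runs = [r for r in runs if r[2] - r[1] >= min_run_ms]
    merged: list[tuple[int, float, float]] = []
    for r in runs:
        if merged and merged[-1][0] == r[0]:
            merged[-1] = (r[0], merged[-1][1], r[2])
        else:
            merged.append(r)
    if not merged:
        return no_seq

    seq = [r[0] for r in merged]
    n_trans = len(seq) - 1
    good = sum(1 for a, b in zip(seq[:-1], seq[1:]) if b == (a + 1) % n_c)
    score = good / n_trans if n_trans else 0.0

    onsets = np.array([r[1] for r in merged if r[0] == reference_cluster])
    periods = np.diff(onsets)
    durations = np.array([r[2] - r[1] for r in merged])
    return ClockMetrics(
        ok=True,
        periods_ms=periods,
        period_mean_ms=float(periods.mean()) if len(periods) else float("nan"),
        activation_mean_ms=float(durations.mean()),
        sequentiality=float(score),
        activations=merged,
        onsets_ms=onsets,
    )


# ---------------------------------------------------------------------------
# replay decoding
# ---------------------------------------------------------------------------

@dataclass
class DecodeResult:
    """Per-cycle decoded element sequences and spike counts.

    ``decoded`` is the common sequence when every cycle agrees, else None;
    ``failure`` marks the explicit no-read-out-spikes outcome.
    """

    cycles: list[tuple[tuple[str, ...], tuple[int, ...]]]
    consistent: bool
    decoded: tuple[str, ...] | None
    failure: bool = False
    message: str = ""

    @property
    def n_cycles(self) -> int:
        return len(self.cycles)

    def max_consecutive(self, target: tuple[str, ...]) -> int:
        """Longest run of consecutive cycles decoding exactly ``target``."""
        best = run = 0
        for seq, _ in self.cycles:
            run = run + 1 if seq == tuple(target) else 0
            best = max(best, run)
        return best


def trigger_cycle_bounds(
    spikes: SpikeRecord | tuple[np.ndarray, np.ndarray],
    labels: np.ndarray,
    *,
    dt: float = 0.1,
    tau_ms: float = 3.0,
    threshold: float = 1.0,
    lockout_ms: float = 90.0,
    reference_cluster: int = 0,
    shift_ms: float = 5.0,
) -> np.ndarray:
    """Cycle boundaries from the same rate-trigger used to lock training.

    Replicates the engine's online clock-phase detector offline: the
    reference cluster's spike count per dt bin is smoothed with an
    exponential filter (``tau_ms``); an upward crossing of ``threshold``
    (spk/ms), at least ``lockout_ms`` after the previous one, marks a cycle
    start.  ``shift_ms`` offsets the returned bounds so that a presentation
    locked to the trigger falls inside one window.  Using the same phase
    reference for training and decoding avoids boundary rotation between
    the two estimates.
    """
    if isinstance(spikes, SpikeRecord):
        ids, times = spikes.population("E")
    else:
        ids, times = spikes
    labels = np.asarray(labels)
    m = labels[ids] == reference_cluster
    ts = np.sort(times[m])
    if len(ts) == 0:
        return np.empty(0)
    n_bins = int(np.ceil(ts.max() / dt)) + 1
    counts = np.bincount((ts / dt).astype(np.int64), minlength=n_bins)
    decay = np.exp(-dt / tau_ms)
    thresh_f = threshold * dt / (1.0 - decay)
    f = 0.0
    last = -np.inf
    bounds = []
    for n in range(n_bins):
        f_new = f * decay + counts[n]
        t = (n + 1) * dt
        if f < thresh_f <= f_new and t - last > lockout_ms:
            bounds.append(t)
            last = t
        f = f_new
    return np.asarray(bounds) + shift_ms


def decode_replay(
    readout_spikes: SpikeRecord | tuple[np.ndarray, np.ndarray],
    alphabet: tuple[str, ...],
    cycle_bounds_ms: np.ndarray,
    *,
    merge_ms: float = 15.0,
) -> DecodeResult:
    """Read the element order off the read-out spikes, cycle by cycle.

    Within each clock cycle (between successive bounds), each read-out
    neuron's spikes are grouped into *element events* (a gap larger than
    ``merge_ms`` starts a new event, so an element that occurs twice in the
    sequence yields two events); the decoded sequence is all events ordered
    by their median spike time, with per-event spike counts reported.  Zero
    read-out spikes yield an explicit decode-failure result.
    """
    if isinstance(readout_spikes, SpikeRecord):
        ids, times = readout_spikes.population("R")
    else:
        ids, times = readout_spikes
    if len(times) == 0:
        return DecodeResult([], False, None, failure=True,
                            message="no read-out spikes")
    order = np.argsort(times, kind="stable")
    ids, times = ids[order], times[order]

    # events are clustered over the whole record first, so an event that
    # straddles a cycle boundary is assigned (by its median time) to exactly
    # one cycle instead of being split in two
    events: list[tuple[float, str, int]] = []  # (median t, element, count)
    for r in np.unique(ids):
        ts = times[ids == r]
        start = 0
        for i in range(1, len(ts) + 1):
            if i == len(ts) or ts[i] - ts[i - 1] > merge_ms:
                chunk = ts[start:i]
                events.append((float(np.median(chunk)), alphabet[int(r)], len(chunk)))
                start = i
    events.sort()

    cycles = []
    for k in range(len(cycle_bounds_ms) - 1):
        lo, hi = cycle_bounds_ms[k], cycle_bounds_ms[k + 1]
        ev = [e for e in events if lo <= e[0] < hi]
        cycles.append((tuple(e for _, e, _ in ev), tuple(c for _, _, c in ev)))

    seqs = [c[0] for c in cycles if c[0]]
    if not seqs:
        return DecodeResult(cycles, False, None, failure=True,
                            message="no read-out spikes inside the analysed cycles")
    consistent = len(seqs) == len(cycles) and all(s == seqs[0] for s in seqs)
    return DecodeResult(cycles, consistent, seqs[0] if consistent else None)
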