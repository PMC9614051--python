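"""On-disk artifacts: spike TSV, weight MTX + JSON sidecar, metrics JSON.

All indices are 0-based (stated in every header).  Weights are stored per
connection class in Matrix Market coordinate format with explicit entries
for every existing edge -- including edges whose weight is exactly zero, so
structure is never conflated with value.  The JSON sidecar holds sizes,
cluster labels, bounds, plastic flags, the normalization targets K and the
creating config hash.  Floats round-trip via repr (1e-12 relative or
better); integers and ids round-trip bit-exactly.
"""

from __future__ import annotations

import json
import os

import numpy as np
import scipy.io
import scipy.sparse

from .engine import SpikeRecord
from .stimulation import StimulusSchedule
from .topology import ALL_CLASSES, NetworkTopology, SynapseState

__all__ = [
    "write_spikes_tsv",
    "read_spikes_tsv",
    "write_weights",
    "read_weights",
    "write_metrics_json",
    "read_metrics_json",
    "write_schedule_tsv",
    "write_traces_h5",
    "read_traces_h5",
    "write_clip_log_tsv",
]

FORMAT_VERSION = "1"


def write_spikes_tsv(record: SpikeRecord, path: str, config_hash: str = "") -> None:
    """population, neuron_id (0-based, population-local), time_ms."""
    inv = sorted(record.offsets.items(), key=lambda kv: kv[1][0])
    with open(path, "w") as fh:
        fh.write(f"# neuralclock spikes v{FORMAT_VERSION}; 0-based ids; "
                 f"config={config_hash}\n")
        fh.write("population\tneuron_id\ttime_ms\n")
        for gid, t in zip(record.gids, record.times_ms):
            for pop, (off, size) in inv:
                if off <= gid < off + size:
                    fh.write(f"{pop}\t{gid - off}\t{float(t)!r}\n")
                    break


def read_spikes_tsv(path: str, offsets: dict[str, tuple[int, int]]) -> SpikeRecord:
    pops, ids, times = [], [], []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or line.startswith("population"):
                continue
            p, i, t = line.rstrip("\n").split("\t")
            pops.append(p); ids.append(int(i)); times.append(float(t))
    gids = np.array([offsets[p][0] + i for p, i in zip(pops, ids)], dtype=np.int32)
    return SpikeRecord(np.array(times, dtype=float), gids, offsets)


def write_weights(topology: NetworkTopology, syn: SynapseState, directory: str,
                  config_hash: str = "") -> None:
    """One MTX file per connection class plus a JSON metadata sidecar."""
    os.makedirs(directory, exist_ok=True)
    for cls in ALL_CLASSES:
        mask = topology.adjacency[cls]
        i, j = np.nonzero(mask)
        coo = scipy.sparse.coo_matrix(
            (syn.W[cls][i, j], (i, j)), shape=mask.shape)
        scipy.io.mmwrite(
            os.path.join(directory, f"W_{cls}.mtx"), coo,
            comment=f"neuralclock weights v{FORMAT_VERSION} class={cls} "
                    f"(target<-source, 0-based) config={config_hash}",
        )
    meta = {
        "format_version": FORMAT_VERSION,
        "config_hash": config_hash,
        "N_E": topology.N_E, "N_I": topology.N_I,
        "N_C": topology.N_C, "N_R": topology.N_R,
        "delay_ms": topology.delay_ms,
        "cluster_label": topology.cluster_label.tolist(),
        "W_min": syn.W_min, "W_max": syn.W_max,
        "plastic": syn.plastic,
        "K": syn.K.tolist(),
        "frozen": syn.frozen,
    }
    with open(os.path.join(directory, "meta.json"), "w") as fh:
        json.dump(meta, fh, indent=1)


def read_weights(directory: str) -> tuple[NetworkTopology, SynapseState]:
    with open(os.path.join(directory, "meta.json")) as fh:
        meta = json.load(fh)
    W: dict[str, np.ndarray] = {}
    adjacency: dict[str, np.ndarray] = {}
    for cls in ALL_CLASSES:
        coo = scipy.io.mmread(os.path.join(directory, f"W_{cls}.mtx")).tocoo()
        dense = np.zeros(coo.shape)
        mask = np.zeros(coo.shape, dtype=bool)
        dense[coo.row, coo.col] = coo.data
        mask[coo.row, coo.col] = True  # explicit zeros are existing edges
        W[cls] = dense
        adjacency[cls] = mask
    topo = NetworkTopology(
        N_E=meta["N_E"], N_I=meta["N_I"], N_C=meta["N_C"], N_R=meta["N_R"],
        cluster_label=np.array(meta["cluster_label"], dtype=np.int64),
        adjacency=adjacency, delay_ms=meta["delay_ms"],
    )
    syn = SynapseState(
        W=W,
        W_min={k: float(v) for k, v in meta["W_min"].items()},
        W_max={k: float(v) for k, v in meta["W_max"].items()},
        plastic=meta["plastic"],
        K=np.array(meta["K"], dtype=float),
        frozen=meta["frozen"],
    )
    return topo, syn


def write_metrics_json(metrics: dict, path: str, config_hash: str = "") -> None:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(f"not JSON-serializable: {type(o)}")

    payload = {"format_version": FORMAT_VERSION, "config_hash": config_hash,
               "metrics": metrics}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, default=default)


def read_metrics_json(path: str) -> dict:
    with open(path) as fh:
        return json.load(fh)["metrics"]


def write_traces_h5(traces, path: str, config_hash: str = "") -> None:
    """Recorded analog traces to HDF5: one group per neuron, one dataset per
    state variable, plus a shared time axis in ms."""
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = FORMAT_VERSION
        f.attrs["config_hash"] = config_hash
        f.create_dataset("time_ms", data=traces.time_ms)
        for q, nid in enumerate(traces.neuron_ids):
            grp = f.create_group(f"neuron_{int(nid)}")
            for var in ("V", "V_T", "a", "g_e", "g_i"):
                grp.create_dataset(var, data=getattr(traces, var)[:, q])


def read_traces_h5(path: str):
    import h5py

    from .engine import TraceDump

    with h5py.File(path, "r") as f:
        time_ms = f["time_ms"][...]
        nids = sorted(
            int(k.split("_")[1]) for k in f.keys() if k.startswith("neuron_"))
        cols = {var: [] for var in ("V", "V_T", "a", "g_e", "g_i")}
        for nid in nids:
            for var in cols:
                cols[var].append(f[f"neuron_{nid}"][var][...])
    return TraceDump(
        neuron_ids=np.array(nids, dtype=np.int32), time_ms=time_ms,
        **{var: np.stack(v, axis=1) for var, v in cols.items()},
    )


def write_clip_log_tsv(clip_log, path: str, config_hash: str = "") -> None:
    """Per-interval clipping/normalization statistics (one row per recording
    interval, cumulative counts reset each interval)."""
    with open(path, "w") as fh:
        fh.write(f"# neuralclock clip log v{FORMAT_VERSION}; config={config_hash}\n")
        fh.write("t_end_ms\tclip_EE\tclip_EI\tclip_RE\tclip_norm\n")
        for t_end, d in clip_log:
            fh.write(f"{float(t_end)!r}\t{d['EE']}\t{d['EI']}\t{d['RE']}\t{d['norm']}\n")


def write_schedule_tsv(schedule: StimulusSchedule, path: str) -> None:
    """Audit export: group, channel, t_start_ms, t_end_ms, rate_hz (one
    period; groups expand to their neurons in the engine)."""
    names = schedule.layout.names()
    with open(path, "w") as fh:
        fh.write(f"# neuralclock schedule v{FORMAT_VERSION} kind={schedule.kind} "
                 f"period_ms={schedule.period_ms} duration_ms={schedule.duration_ms}\n")
        fh.write("group\tchannel\tt_start_ms\tt_end_ms\trate_hz\n")
        for s in range(schedule.n_segments):
            t0, t1 = schedule.bounds[s], schedule.bounds[s + 1]
            for g, name in enumerate(names):
                for channel, table in (("exc", schedule.rate_exc),
                                       ("inh", schedule.rate_inh)):
                    r = table[s, g]
                    if r > 0:
                        fh.write(f"{name}\t{channel}\t{float(t0)!r}\t"
                                 f"{float(t1)!r}\t{float(r)!r}\n")
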