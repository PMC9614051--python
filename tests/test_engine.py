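import copy

import numpy as np
import pytest

from neuralclock.config import ConfigError
from neuralclock.engine import SimState, replay, run_phase, train_readout
from neuralclock.stimulation import SequenceSpec, schedule_for_phase
from neuralclock.topology import build_connectivity, init_weights


def fresh_state(cfg, seed=1):
    topo = build_connectivity(cfg, seed)
    syn = init_weights(topo, cfg)
    return SimState.init(cfg, topo, syn)


def test_zero_duration_phase_changes_nothing(tiny_cfg):
    state = fresh_state(tiny_cfg)
    W0 = {k: v.copy() for k, v in state.synapses.W.items()}
    sched = schedule_for_phase(tiny_cfg, "phase2", T_ms=0.0)
    res = run_phase(state, sched, plastic=("EE", "EI"))
    assert res.spikes.n_spikes == 0
    for k in W0:
        np.testing.assert_array_equal(state.synapses.W[k], W0[k])


def test_frozen_phase_leaves_weights_bit_identical(tiny_cfg):
    state = fresh_state(tiny_cfg)
    state.synapses.frozen = True
    W0 = {k: v.copy() for k, v in state.synapses.W.items()}
    sched = schedule_for_phase(tiny_cfg, "phase1", T_ms=500.0)
    run_phase(state, sched, plastic=("EE", "EI"), seed=5)
    for k in W0:
        assert (state.synapses.W[k] == W0[k]).all()  # not one ULP


def test_identical_seeds_reproduce_spike_records(tiny_cfg):
    sched = schedule_for_phase(tiny_cfg, "phase1", T_ms=500.0)
    records = []
    for _ in range(2):
        state = fresh_state(tiny_cfg, seed=3)
        res = run_phase(state, sched, plastic=("EE", "EI"),
                        record=("E", "I"), seed=11)
        records.append(res.spikes)
    np.testing.assert_array_equal(records[0].times_ms, records[1].times_ms)
    np.testing.assert_array_equal(records[0].gids, records[1].gids)


def test_different_seeds_differ(tiny_cfg):
    sched = schedule_for_phase(tiny_cfg, "phase1", T_ms=500.0)
    a = run_phase(fresh_state(tiny_cfg, 3), sched, record=("E",), seed=11)
    b = run_phase(fresh_state(tiny_cfg, 3), sched, record=("E",), seed=12)
    assert not (
        a.spikes.n_spikes == b.spikes.n_spikes
        and np.array_equal(a.spikes.times_ms, b.spikes.times_ms)
    )


def test_zero_learning_rates_leave_weights_unchanged(tiny_cfg):
    cfg = copy.deepcopy(tiny_cfg)
    cfg.stdp.A_LTD = cfg.stdp.A_LTP = 0.0
    cfg.stdp.A_LTD_RE = cfg.stdp.A_LTP_RE = 0.0
    cfg.inhib.A_inh = 0.0
    cfg.norm.enabled = False
    state = fresh_state(cfg)
    W0 = {k: v.copy() for k, v in state.synapses.W.items()}
    sched = schedule_for_phase(cfg, "phase1", T_ms=500.0)
    run_phase(state, sched, plastic=("EE", "EI", "RE"), seed=5)
    for k in W0:
        np.testing.assert_array_equal(state.synapses.W[k], W0[k])


def test_plasticity_changes_magnitudes_not_structure(tiny_cfg):
    state = fresh_state(tiny_cfg)
    mask0 = {k: v.copy() for k, v in state.topology.adjacency.items()}
    sched = schedule_for_phase(tiny_cfg, "phase1", T_ms=500.0)
    run_phase(state, sched, plastic=("EE", "EI"), seed=5)
    for k, m in mask0.items():
        assert (state.topology.adjacency[k] == m).all()
        assert (state.synapses.W[k][~m] == 0.0).all()  # autapse/absent stay 0


def test_weight_bounds_hold_after_every_phase(tiny_cfg):
    state = fresh_state(tiny_cfg)
    sched = schedule_for_phase(tiny_cfg, "phase1", T_ms=500.0)
    run_phase(state, sched, plastic=("EE", "EI"), seed=5)
    syn = state.synapses
    w = tiny_cfg.weights
    m = state.topology.adjacency
    assert (syn.W["EE"][m["EE"]] >= w.w_EE_min - 1e-12).all()
    assert (syn.W["EE"][m["EE"]] <= w.w_EE_max + 1e-12).all()
    assert (syn.W["EI"][m["EI"]] >= w.w_EI_min - 1e-12).all()
    assert (syn.W["EI"][m["EI"]] <= w.w_EI_max + 1e-12).all()


def test_normalization_restores_K_at_interval_boundaries(tiny_cfg):
    cfg = copy.deepcopy(tiny_cfg)
    cfg.norm.interval_ms = 500.0  # exactly one boundary at the phase end
    cfg.weights.w_EE_max = 1e9  # no clipping: the pre-clip sum is exact
    state = fresh_state(cfg)
    sched = schedule_for_phase(cfg, "phase1", T_ms=500.0)
    run_phase(state, sched, plastic=("EE", "EI"), seed=5)
    W = state.synapses.W["EE"]
    mask = state.topology.adjacency["EE"]
    for i in range(cfg.network.N_E):
        if mask[i].any():
            assert abs(W[i].sum() - state.synapses.K[i]) < 1e-9


def test_readout_training_requires_frozen_clock(tiny_cfg):
    state = fresh_state(tiny_cfg)
    seq = SequenceSpec.from_string("AB", 10.0, 5.0)
    with pytest.raises(ConfigError, match="frozen"):
        train_readout(state, seq, tiny_cfg)


def test_readout_presentation_must_fit_clock_cycle(tiny_cfg):
    # tiny network: nominal period 4 * 15 = 60 ms
    state = fresh_state(tiny_cfg)
    state.synapses.frozen = True
    seq = SequenceSpec.from_string("AB", 40.0, 5.0)  # 85 ms > 60 ms
    with pytest.raises(ConfigError, match="exceeds the clock period"):
        train_readout(state, seq, tiny_cfg)


def test_replay_requires_frozen_weights(tiny_cfg):
    state = fresh_state(tiny_cfg)
    with pytest.raises(ConfigError, match="frozen"):
        replay(state, 100.0, tiny_cfg)


def test_replay_records_populations_and_dt_aligned_times(tiny_cfg):
    state = fresh_state(tiny_cfg)
    state.synapses.frozen = True
    res = replay(state, 500.0, tiny_cfg)
    t = res.spikes.times_ms
    assert res.spikes.n_spikes > 0
    # spike times are positive multiples of dt
    assert (t > 0).all()
    np.testing.assert_allclose(np.round(t / tiny_cfg.dt), t / tiny_cfg.dt,
                               atol=1e-9)
    # per-neuron times non-decreasing
    for pop in ("E", "I"):
        ids, times = res.spikes.population(pop)
        for i in np.unique(ids):
            assert (np.diff(times[ids == i]) >= 0).all()


def test_state_persists_across_phases_no_silent_reset(tiny_cfg):
    state = fresh_state(tiny_cfg)
    sched = schedule_for_phase(tiny_cfg, "phase1", T_ms=300.0)
    run_phase(state, sched, seed=5)
    V_after = state.V_E.copy()
    # a fresh state differs: membrane potentials must carry over, not reset
    assert not np.array_equal(V_after, np.full_like(V_after, tiny_cfg.neuron_E.E_L))
    sched2 = schedule_for_phase(tiny_cfg, "phase2", T_ms=0.0)
    run_phase(state, sched2)
    np.testing.assert_array_equal(state.V_E, V_after)


def test_analog_trace_recording_and_h5_round_trip(tiny_cfg, tmp_path):
    from neuralclock.artifacts import read_traces_h5, write_traces_h5

    state = fresh_state(tiny_cfg)
    sched = schedule_for_phase(tiny_cfg, "phase2", T_ms=100.0)
    res = run_phase(state, sched, seed=5, record_traces=(0, 7), trace_every=5)
    tr = res.traces
    assert tr is not None
    assert tr.V.shape == (int(100.0 / tiny_cfg.dt / 5), 2)
    assert np.isfinite(tr.V).all()
    assert (tr.V < tiny_cfg.neuron_E.V_peak).all()
    assert (tr.g_e >= 0).all() and (tr.g_i >= 0).all()
    np.testing.assert_allclose(np.diff(tr.time_ms), 0.5)
    path = str(tmp_path / "traces.h5")
    write_traces_h5(tr, path, config_hash="abc")
    back = read_traces_h5(path)
    np.testing.assert_array_equal(back.neuron_ids, tr.neuron_ids)
    np.testing.assert_array_equal(back.V, tr.V)
    np.testing.assert_array_equal(back.g_i, tr.g_i)


def test_clip_log_accumulates_per_interval(tiny_cfg, tmp_path):
    from neuralclock.artifacts import write_clip_log_tsv

    state = fresh_state(tiny_cfg)
    sched = schedule_for_phase(tiny_cfg, "phase1", T_ms=400.0)
    res = run_phase(state, sched, plastic=("EE", "EI"), seed=5, chunk_ms=100.0)
    assert len(res.clip_log) == 4  # one entry per chunk
    total = {k: sum(d[k] for _, d in res.clip_log) for k in ("EE", "EI", "RE", "norm")}
    assert total == res.clips
    path = tmp_path / "clips.tsv"
    write_clip_log_tsv(res.clip_log, str(path))
    lines = path.read_text().strip().splitlines()
    assert len(lines) == 2 + 4
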