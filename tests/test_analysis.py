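import numpy as np
import pytest

from neuralclock.analysis import (
    cluster_block_means,
    clock_metrics,
    decode_replay,
    full_spectrum,
)
from neuralclock.engine import SpikeRecord
from neuralclock.fixtures import make_ring_matrix, make_sequential_raster


class TestClusterBlockMeans:
    def test_identity_structured_matrix(self):
        labels = np.repeat([0, 1], 3)
        mask = np.ones((6, 6), dtype=bool)
        np.fill_diagonal(mask, False)
        W = np.zeros((6, 6))
        for c in (0, 1):
            blk = np.ix_(labels == c, labels == c)
            W[blk] = 2.5
        W[~mask] = 0.0
        bm = cluster_block_means(W, labels, mask)
        assert bm.means[0, 0] == 2.5 and bm.means[1, 1] == 2.5
        assert bm.means[0, 1] == 0.0 and bm.means[1, 0] == 0.0

    def test_hand_built_two_cluster_example(self):
        # 4 neurons, clusters {0,1} and {2,3}; weights chosen for easy sums
        labels = np.array([0, 0, 1, 1])
        mask = np.zeros((4, 4), dtype=bool)
        W = np.zeros((4, 4))
        # edges: 1<-0 (1.0), 0<-1 (3.0), 2<-0 (2.0), 2<-1 (4.0), 3<-2 (5.0)
        for i, j, w in [(1, 0, 1.0), (0, 1, 3.0), (2, 0, 2.0), (2, 1, 4.0),
                        (3, 2, 5.0)]:
            mask[i, j] = True
            W[i, j] = w
        bm = cluster_block_means(W, labels, mask)
        assert bm.means[0, 0] == (1.0 + 3.0) / 2  # within cluster 0
        assert bm.means[1, 0] == (2.0 + 4.0) / 2  # cluster 0 -> cluster 1
        assert bm.means[1, 1] == 5.0
        assert np.isnan(bm.means[0, 1])  # no edges: missing, not zero
        assert bm.counts.sum() == mask.sum()

    def test_empty_block_is_missing_not_zero(self):
        labels = np.array([0, 1])
        mask = np.zeros((2, 2), dtype=bool)
        bm = cluster_block_means(np.zeros((2, 2)), labels, mask)
        assert np.isnan(bm.means).all()


class TestFullSpectrum:
    def test_ring_matrix_closed_form(self):
        # block-cyclic feedforward matrix: leading eigenvalues are
        # m * w_ff * (N_C-th roots of unity)
        N_C, m, w = 10, 5, 0.3
        W = make_ring_matrix(N_C, m, 0.0, w)
        spec = full_spectrum(W, n_leading=N_C)
        expected = m * w * np.exp(2j * np.pi * np.arange(N_C) / N_C)
        got = np.sort_complex(spec.leading)
        np.testing.assert_allclose(got, np.sort_complex(expected), atol=1e-6)

    def test_zero_matrix(self):
        spec = full_spectrum(np.zeros((8, 8)), n_leading=2)
        np.testing.assert_array_equal(spec.eigenvalues, np.zeros(8))

    def test_conjugate_pair_symmetry_for_real_matrices(self, rng):
        for _ in range(5):
            W = rng.normal(size=(40, 40))
            ev = full_spectrum(W, 5).eigenvalues
            paired = np.sort_complex(np.conj(ev))
            np.testing.assert_allclose(np.sort_complex(ev), paired, atol=1e-8)

    def test_balanced_random_matrix_obeys_circular_law(self, rng):
        # i.i.d. zero-mean entries with variance s^2/n: eigenvalues fall in
        # a disk of radius ~s; check 95% containment with margin
        n, s = 300, 1.0
        W = rng.normal(0.0, s / np.sqrt(n), size=(n, n))
        ev = full_spectrum(W, 0).eigenvalues
        frac_inside = np.mean(np.abs(ev) <= 1.05 * s)
        assert frac_inside >= 0.95

    def test_non_square_rejected(self):
        with pytest.raises(ValueError):
            full_spectrum(np.zeros((3, 4)), 1)


class TestClockMetrics:
    def test_recovers_constructed_period_and_order(self):
        rec, labels = make_sequential_raster(10, 15.0, 8, jitter_ms=0.0)
        cm = clock_metrics(rec, labels)
        assert cm.ok
        assert abs(cm.period_mean_ms - 150.0) < 1.0
        assert cm.sequentiality == 1.0
        assert cm.activation_mean_ms <= cm.period_mean_ms

    def test_shuffled_labels_not_sequential(self, rng):
        rec, labels = make_sequential_raster(10, 15.0, 8)
        shuffled = labels.copy()
        rng.shuffle(shuffled)
        cm = clock_metrics(rec, shuffled)
        # score near the 1/N_C chance level, far from 1
        assert cm.sequentiality < 0.5

    def test_time_translation_invariance(self):
        rec, labels = make_sequential_raster(8, 15.0, 6)
        shifted = SpikeRecord(rec.times_ms + 1000.0, rec.gids, rec.offsets)
        a = clock_metrics(rec, labels)
        b = clock_metrics(shifted, labels)
        assert a.sequentiality == b.sequentiality
        np.testing.assert_allclose(a.period_mean_ms, b.period_mean_ms, atol=1e-9)

    def test_empty_record_reports_no_sequential_dynamics(self):
        rec = SpikeRecord(np.empty(0), np.empty(0, dtype=np.int32),
                          {"E": (0, 10)})
        cm = clock_metrics(rec, np.zeros(10, dtype=int))
        assert not cm.ok
        assert "no sequential dynamics" in cm.message


class TestDecodeReplay:
    def encode(self, seq, alphabet, n_cycles, period=150.0, t0=10.0,
               spacing=30.0, n_spikes=1):
        ids, times = [], []
        for k in range(n_cycles):
            for pos, el in enumerate(seq):
                r = alphabet.index(el)
                for s in range(n_spikes):
                    ids.append(r)
                    times.append(k * period + t0 + pos * spacing + s * 2.0)
        order = np.argsort(times)
        return (np.array(ids, dtype=np.int32)[order],
                np.array(times, dtype=float)[order])

    def test_round_trip_of_constructed_encoding(self):
        alphabet = ("A", "B", "C")
        ids, times = self.encode("ABCBA", alphabet, 4, period=200.0)
        bounds = np.arange(5) * 200.0
        dec = decode_replay((ids, times), alphabet, bounds, merge_ms=20.0)
        assert dec.consistent
        assert dec.decoded == tuple("ABCBA")
        assert all(c == (1, 1, 1, 1, 1) for _, c in dec.cycles)

    def test_doubled_spikes_counted_not_reordered(self):
        alphabet = ("A", "B", "C")
        ids, times = self.encode("ABC", alphabet, 3, n_spikes=2)
        bounds = np.arange(4) * 150.0
        dec = decode_replay((ids, times), alphabet, bounds, merge_ms=20.0)
        assert dec.decoded == tuple("ABC")
        assert all(c == (2, 2, 2) for _, c in dec.cycles)

    def test_no_spikes_is_explicit_failure(self):
        dec = decode_replay(
            (np.empty(0, dtype=np.int32), np.empty(0)), ("A",),
            np.array([0.0, 100.0]))
        assert dec.failure and dec.decoded is None

    def test_inconsistent_cycles_flagged(self):
        alphabet = ("A", "B")
        ids = np.array([0, 1, 1, 0], dtype=np.int32)
        times = np.array([10.0, 40.0, 160.0, 190.0])
        bounds = np.array([0.0, 150.0, 300.0])
        dec = decode_replay((ids, times), alphabet, bounds, merge_ms=20.0)
        assert not dec.consistent
        assert dec.decoded is None

    def test_max_consecutive_run(self):
        alphabet = ("A", "B")
        # cycles: AB, AB, BA, AB
        ids = np.array([0, 1, 0, 1, 1, 0, 0, 1], dtype=np.int32)
        times = np.array([10, 40, 110, 140, 210, 240, 310, 340], dtype=float)
        bounds = np.array([0.0, 100.0, 200.0, 300.0, 400.0])
        dec = decode_replay((ids, times), alphabet, bounds, merge_ms=20.0)
        assert dec.max_consecutive(("A", "B")) == 2
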