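"""Spike-level bookkeeping: binning, ISIs, correlograms, relay annotation,
tuples, spike-triggered averages."""

import numpy as np
import pytest

import infodyn as idy
from infodyn.errors import DegenerateInputError, InputError
from infodyn.series import LocalSeries


class TestBinning:
    def test_hand_binning(self):
        tr = idy.SpikeTrain(np.array([0.2, 0.7, 3.1]), 5.0)
        with pytest.warns(UserWarning, match="clipped"):
            b = idy.bin_spikes(tr, 1.0)
        np.testing.assert_array_equal(b.values, [1, 0, 0, 1, 0])

    def test_empty_train_all_zeros(self):
        b = idy.bin_spikes(idy.SpikeTrain(np.empty(0), 10.0))
        assert b.values.sum() == 0 and len(b) == 10

    def test_edge_spike_goes_to_later_bin(self):
        b = idy.bin_spikes(idy.SpikeTrain(np.array([2.0]), 5.0))
        np.testing.assert_array_equal(b.values, [0, 0, 1, 0, 0])

    def test_spike_count_bound(self, rng):
        times = np.unique(rng.uniform(0, 1000, 500))
        tr = idy.SpikeTrain(times, 1000.0)
        b = idy.bin_spikes(tr)
        assert b.values.sum() <= tr.n_spikes


class TestISI:
    def test_arithmetic(self):
        tr = idy.SpikeTrain(np.array([2.0, 5.0, 9.0]), 20.0)
        np.testing.assert_array_equal(idy.isi(tr), [3.0, 4.0])

    def test_regular_train(self):
        tr = idy.SpikeTrain(np.arange(0, 1000, 100.0), 1000.0)
        assert np.all(idy.isi(tr) == 100.0)
        assert idy.isi(tr).size == tr.n_spikes - 1

    def test_single_spike_empty(self):
        assert idy.isi(idy.SpikeTrain(np.array([5.0]), 10.0)).size == 0


class TestCrossCorrelogram:
    def test_shifted_train_peak_at_delay(self, rng):
        times = np.unique(rng.uniform(0, 50_000, 2000))
        rgc = idy.SpikeTrain(times, 50_000.0)
        jitter = rng.uniform(-0.15, 0.15, times.size)
        lgn_t = np.unique(times + 3.0 + jitter)
        lgn = idy.SpikeTrain(lgn_t[lgn_t < 50_000], 50_000.0)
        ccg = idy.cross_correlogram(rgc, lgn)
        assert ccg.has_peak()
        assert ccg.peak_lag_ms == pytest.approx(3.0, abs=0.1)

    def test_independent_trains_mostly_no_peak(self):
        no_peak = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            a = idy.SpikeTrain(np.unique(r.uniform(0, 60_000, 1200)), 60_000.0)
            b = idy.SpikeTrain(np.unique(r.uniform(0, 60_000, 1200)), 60_000.0)
            no_peak += not idy.cross_correlogram(a, b).has_peak()
        assert no_peak >= 18

    def test_counts_conserve_pairs(self, rng):
        a = idy.SpikeTrain(np.unique(rng.uniform(0, 5000, 200)), 5000.0)
        b = idy.SpikeTrain(np.unique(rng.uniform(0, 5000, 200)), 5000.0)
        ccg = idy.cross_correlogram(a, b, max_lag_ms=50.0)
        n_pairs = sum(
            np.sum(np.abs(b.times_ms - t) <= 50.0 + 0.05) for t in a.times_ms
        )
        assert np.issubdtype(ccg.counts.dtype, np.integer)
        assert np.all(ccg.counts >= 0)
        assert abs(ccg.counts.sum() - n_pairs) <= 2  # edge-of-window rounding


class TestRelayAnnotation:
    def test_hand_enumerated_example(self):
        rgc = np.zeros(20, dtype=int)
        rgc[[5, 12, 14]] = 1
        lgn = np.zeros(20, dtype=int)
        lgn[17] = 1
        ann = idy.annotate_relayed(
            idy.BinnedSeries(rgc), idy.BinnedSeries(lgn), u=3
        )
        np.testing.assert_array_equal(ann.spike_bins, [5, 12, 14])
        np.testing.assert_array_equal(ann.relayed, [False, False, True])
        assert ann.efficacy == pytest.approx(100 / 3)
        assert ann.contribution == pytest.approx(100.0)

    def test_perfect_relay(self, rng):
        x = (rng.random(1000) < 0.05).astype(int)
        y = np.roll(x, 4)
        y[:4] = 0
        ann = idy.annotate_relayed(idy.BinnedSeries(x), idy.BinnedSeries(y), 4)
        # spikes whose target bin falls beyond the end are non-relayed
        in_range = ann.spike_bins + 4 < 1000
        assert ann.relayed[in_range].all()
        assert ann.contribution == pytest.approx(100.0)

    def test_empty_output_flagged(self):
        x = np.zeros(50, dtype=int)
        x[10] = 1
        ann = idy.annotate_relayed(
            idy.BinnedSeries(x), idy.BinnedSeries(np.zeros(50, dtype=int)), 2
        )
        assert ann.efficacy == 0.0
        assert ann.contribution == 0.0
        assert not ann.contribution_defined

    def test_partition_is_exact(self, rng):
        x = (rng.random(5000) < 0.03).astype(int)
        y = (rng.random(5000) < 0.03).astype(int)
        ann = idy.annotate_relayed(idy.BinnedSeries(x), idy.BinnedSeries(y), 3)
        assert ann.relayed.size == x.sum()
        assert 0 <= ann.efficacy <= 100


class TestTuples:
    def test_definition(self):
        tr = idy.SpikeTrain(np.array([100.0, 103.0]), 200.0)
        assert idy.find_tuples(tr) == [(100.0, 103.0)]

    def test_silence_required_before_first_spike(self):
        tr = idy.SpikeTrain(np.array([100.0, 103.0, 106.0]), 200.0)
        # (103, 106) lacks the preceding silence
        assert idy.find_tuples(tr) == [(100.0, 103.0)]

    def test_high_rate_train_few_tuples(self, rng):
        # dense Poisson train: the 20 ms silence condition is rarely met
        times = np.unique(np.sort(rng.uniform(0, 10_000, 5000)))
        tr = idy.SpikeTrain(times, 10_000.0)
        assert len(idy.find_tuples(tr)) < 0.02 * tr.n_spikes


class TestSTA:
    def test_constant_series_flat(self):
        local = LocalSeries.from_values(np.full(200, 0.7), np.ones(200, bool))
        sta = idy.spike_triggered_average(local, [60, 100, 140], (10, 10))
        np.testing.assert_allclose(sta.mean, 0.7)
        np.testing.assert_allclose(sta.sd, 0.0, atol=1e-12)
        assert sta.n_events == 3

    def test_single_event_returns_raw_window(self, rng):
        v = rng.normal(size=100)
        local = LocalSeries.from_values(v, np.ones(100, bool))
        sta = idy.spike_triggered_average(local, [50], (5, 5))
        np.testing.assert_array_equal(sta.mean, v[45:56])

    def test_align_shift(self, rng):
        v = rng.normal(size=100)
        local = LocalSeries.from_values(v, np.ones(100, bool))
        sta = idy.spike_triggered_average(local, [40], (2, 2), align_shift=3)
        np.testing.assert_array_equal(sta.mean, v[41:46])

    def test_no_complete_window_raises(self):
        local = LocalSeries.from_values(np.zeros(20), np.ones(20, bool))
        with pytest.raises(DegenerateInputError):
            idy.spike_triggered_average(local, [1], (5, 5))


class TestSpikeTrainIO:
    def test_round_trip(self, tmp_path, rng):
        tr = idy.SpikeTrain(np.unique(rng.uniform(0, 500, 40)), 500.0)
        path = tmp_path / "train.txt"
        tr.to_file(path)
        tr2 = idy.SpikeTrain.from_file(path, duration_ms=500.0)
        np.testing.assert_allclose(tr2.times_ms, tr.times_ms, atol=1e-4)

    def test_invalid_times_rejected(self):
        with pytest.raises(InputError):
            idy.SpikeTrain(np.array([3.0, 2.0]), 10.0)
        with pytest.raises(InputError):
            idy.SpikeTrain(np.array([3.0, 12.0]), 10.0)
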