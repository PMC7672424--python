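"""Burst search: binning convention, run detection, oracle equivalence."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import brute_force_bursts, random_stream
from gqfret.bursts import (
    Burst,
    BurstSearchParams,
    bin_photons,
    burst_rate,
    bursts_to_frame,
    search_bursts,
)
from gqfret.simulate import SimulationConfig, simulate_photon_stream
from gqfret.stream import PhotonStream


def _stream(times_ms, duration_ms, channel=None, excitation=None):
    t = np.asarray(times_ms, dtype=float) * 1e-3
    n = t.size
    return PhotonStream(
        timestamps=t,
        channel=np.zeros(n, np.uint8) if channel is None else np.asarray(channel, np.uint8),
        excitation=np.zeros(n, np.uint8) if excitation is None else np.asarray(excitation, np.uint8),
        duration=duration_ms * 1e-3,
    )


class TestBinning:
    def test_all_photons_in_first_bin(self):
        assert bin_photons(_stream([0.1, 0.4, 0.7], 1.0), 1e-3).tolist() == [3]

    def test_empty_stream_gives_zero_bins(self):
        assert bin_photons(_stream([], 3.0), 1e-3).tolist() == [0, 0, 0]

    def test_boundary_photon_goes_to_later_bin(self):
        counts = bin_photons(_stream([1.0], 3.0), 1e-3)
        assert counts.tolist() == [0, 1, 0]

    def test_counts_conserved(self):
        rng = np.random.default_rng(0)
        s = random_stream(rng)
        assert bin_photons(s, 1e-3).sum() == s.size

    def test_unsorted_stream_rejected(self):
        s = _stream([0.2, 0.5], 1.0)
        s.timestamps = np.array([0.5e-3, 0.2e-3])  # bypass constructor check
        with pytest.raises(ValueError):
            bin_photons(s, 1e-3)

    def test_invalid_bin_width_rejected(self):
        with pytest.raises(ValueError):
            bin_photons(_stream([0.1], 1.0), 0.0)


class TestSearchBursts:
    params = BurstSearchParams(threshold=5, min_photons=25)

    def test_single_dense_bin_is_one_burst(self):
        s = _stream(np.linspace(1.05, 1.95, 30), 5.0)
        bursts = search_bursts(s, self.params)
        assert len(bursts) == 1
        assert bursts[0].n_photons == 30

    def test_min_photons_discards_small_candidates(self):
        s = _stream(np.linspace(1.05, 1.95, 10), 5.0)
        assert search_bursts(s, self.params) == []

    def test_adjacent_bins_merge_into_one_burst(self):
        s = _stream(np.concatenate([np.linspace(1.05, 1.95, 15), np.linspace(2.05, 2.95, 15)]), 5.0)
        bursts = search_bursts(s, self.params)
        assert len(bursts) == 1
        assert bursts[0].n_photons == 30
        assert bursts[0].start_time == pytest.approx(1e-3)
        assert bursts[0].stop_time == pytest.approx(3e-3)

    def test_gap_tolerance_merges_across_empty_bin(self):
        times = np.concatenate([np.linspace(1.05, 1.95, 15), np.linspace(3.05, 3.95, 15)])
        s = _stream(times, 6.0)
        strict = search_bursts(s, BurstSearchParams(threshold=5, min_photons=25))
        tolerant = search_bursts(s, BurstSearchParams(threshold=5, min_photons=25, gap_tolerance=1))
        assert strict == []  # two 15-photon candidates, each below 25
        assert len(tolerant) == 1 and tolerant[0].n_photons == 30

    def test_per_class_counts(self):
        # 30 photons: 10 dd, 12 da, 8 aa
        channel = [0] * 10 + [1] * 12 + [1] * 8
        excitation = [0] * 10 + [0] * 12 + [1] * 8
        s = _stream(np.linspace(1.05, 1.95, 30), 5.0, channel, excitation)
        (b,) = search_bursts(s, self.params)
        assert (b.n_dd, b.n_da, b.n_aa) == (10, 12, 8)

    @given(seed=st.integers(0, 10_000))
    @settings(derandomize=True, max_examples=60, deadline=None)
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        s = random_stream(rng)
        for threshold in (4, 9):
            params = BurstSearchParams(threshold=threshold, min_photons=25)
            got = [(b.start_time, b.stop_time, *b.photon_slice) for b in search_bursts(s, params)]
            assert got == pytest.approx(brute_force_bursts(s, params))

    @given(seed=st.integers(0, 10_000))
    @settings(derandomize=True, max_examples=30, deadline=None)
    def test_monotonicity_in_min_photons_and_threshold(self, seed):
        """Raising min_photons never adds bursts; raising the threshold never
        adds burst photons (a run may split into several shorter runs, so the
        burst *count* is not monotone in the threshold, but their photon
        content shrinks)."""
        rng = np.random.default_rng(seed)
        s = random_stream(rng)
        by_min = [len(search_bursts(s, BurstSearchParams(threshold=4, min_photons=mp)))
                  for mp in (10, 25, 40)]
        assert by_min[0] >= by_min[1] >= by_min[2]

        def burst_photons(threshold):
            bursts = search_bursts(s, BurstSearchParams(threshold=threshold, min_photons=1))
            return set().union(*(range(*b.photon_slice) for b in bursts)) if bursts else set()

        assert burst_photons(9) <= burst_photons(4)

    def test_bursts_are_ordered_and_disjoint(self):
        cfg = SimulationConfig(duration=20.0, seed=2)
        bursts = search_bursts(simulate_photon_stream(cfg), self.params)
        assert len(bursts) > 10
        for a, b in zip(bursts, bursts[1:]):
            assert a.stop_time <= b.start_time

    def test_appending_later_photons_leaves_earlier_bursts_unchanged(self):
        times = np.linspace(1.05, 1.95, 30)
        s1 = _stream(times, 10.0)
        s2 = _stream(np.concatenate([times, np.linspace(7.05, 7.95, 30)]), 10.0)
        b1 = search_bursts(s1, self.params)
        b2 = search_bursts(s2, self.params)
        assert b2[0] == b1[0]
        assert len(b2) == 2


class TestBurstRate:
    def test_rate_arithmetic(self):
        assert burst_rate([], 10.0) == 0.0
        dummy = [Burst(0, 1e-3, (0, 30), 10, 10, 10)] * 20
        assert burst_rate(dummy, 10.0) == 2.0
        with pytest.raises(ValueError):
            burst_rate([], 0.0)

    def test_detected_rate_tracks_simulated_rate(self):
        """Generous thresholds recover the simulated Poisson burst rate."""
        cfg = SimulationConfig(
            duration=100.0, burst_rate=5.0, burst_size_mean=120.0,
            bg_rate_dd=0.0, bg_rate_da=0.0, bg_rate_aa=0.0, seed=8,
        )
        s = simulate_photon_stream(cfg)
        bursts = search_bursts(s, BurstSearchParams(threshold=2, min_photons=5))
        rate = burst_rate(bursts, cfg.duration)
        assert rate == pytest.approx(5.0, abs=3 * np.sqrt(500) / 100)


def test_burst_table_layout():
    s = _stream(np.linspace(1.05, 1.95, 30), 5.0)
    frame = bursts_to_frame(search_bursts(s, BurstSearchParams()))
    assert list(frame.columns) == ["burst_id", "start_s", "stop_s", "n_dd", "n_da", "n_aa", "duration_s"]
    assert len(frame) == 1
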