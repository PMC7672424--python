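"""Simulator: binding law, photon statistics, titration seeds, melting curves."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from gqfret.bursts import bin_photons
from gqfret.simulate import (
    BindingModelParams,
    SimulationConfig,
    derive_seed,
    population_from_binding,
    population_from_binding_depletion,
    simulate_melting_curve,
    simulate_photon_stream,
    simulate_titration,
)
from gqfret.stream import ACCEPTOR, ACCEPTOR_WINDOW, DONOR, DONOR_WINDOW, infer_excitation


class TestBindingLaw:
    @pytest.mark.parametrize(
        ("conc", "expected"),
        [
            (0.0, 0.62),  # f(0) = f0
            (0.53, 0.81),  # f(kd) = midpoint (f0 + f_inf) / 2
            (1e6, 1.0),  # saturation
        ],
    )
    def test_anchor_points(self, binding_params, conc, expected):
        assert population_from_binding(binding_params, conc) == pytest.approx(expected, abs=1e-3)

    def test_negative_concentration_rejected(self, binding_params):
        with pytest.raises(ValueError):
            population_from_binding(binding_params, -0.1)

    @given(
        conc=st.floats(0.001, 1e4),
        kd1=st.floats(0.01, 50),
        kd2=st.floats(0.01, 50),
    )
    @settings(derandomize=True, max_examples=60)
    def test_monotone_in_conc_and_kd(self, conc, kd1, kd2):
        p = BindingModelParams(kd=kd1, f0=0.2, f_inf=0.9)
        assert population_from_binding(p, conc * 2) > population_from_binding(p, conc)
        if kd1 < kd2:  # larger kd = weaker binding = smaller shift at fixed conc
            p2 = BindingModelParams(kd=kd2, f0=0.2, f_inf=0.9)
            assert population_from_binding(p, conc) > population_from_binding(p2, conc)

    def test_depletion_form_reduces_to_hyperbolic_at_trace_receptor(self, binding_params):
        for conc in (0.1, 0.53, 2.0):
            hyp = population_from_binding(binding_params, conc)
            dep = population_from_binding_depletion(binding_params, conc, receptor_conc=1e-6)
            assert dep == pytest.approx(hyp, abs=1e-5)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            BindingModelParams(kd=-1.0, f0=0.2, f_inf=0.8)
        with pytest.raises(ValueError):
            BindingModelParams(kd=1.0, f0=0.9, f_inf=0.8)


class TestPhotonStream:
    def test_no_sources_gives_empty_stream(self):
        cfg = SimulationConfig(
            duration=1.0, burst_rate=0.0, bg_rate_dd=0.0, bg_rate_da=0.0, bg_rate_aa=0.0
        )
        assert simulate_photon_stream(cfg).size == 0

    def test_zero_duration_gives_empty_stream(self):
        assert simulate_photon_stream(SimulationConfig(duration=0.0)).size == 0

    def test_unit_efficiency_puts_all_donor_window_photons_in_acceptor(self):
        cfg = SimulationConfig(
            duration=5.0,
            bg_rate_dd=0.0,
            bg_rate_da=0.0,
            bg_rate_aa=0.0,
            states=[(1.0, 1.0)],
            aa_fraction=0.0,
            seed=3,
        )
        s = simulate_photon_stream(cfg)
        assert s.size > 0
        assert np.all(s.channel == ACCEPTOR)
        assert np.all(s.excitation == DONOR_WINDOW)

    def test_stream_is_sorted_and_bounded(self):
        s = simulate_photon_stream(SimulationConfig(duration=3.0, seed=5))
        assert np.all(np.diff(s.timestamps) >= 0)
        assert s.timestamps[0] >= 0 and s.timestamps[-1] <= s.duration

    def test_determinism_and_seed_sensitivity(self):
        cfg = SimulationConfig(duration=2.0, seed=9)
        a = simulate_photon_stream(cfg)
        b = simulate_photon_stream(cfg)
        np.testing.assert_array_equal(a.timestamps, b.timestamps)
        np.testing.assert_array_equal(a.channel, b.channel)
        c = simulate_photon_stream(SimulationConfig(duration=2.0, seed=10))
        assert a.size != c.size or not np.array_equal(a.timestamps, c.timestamps)

    def test_background_bin_counts_are_poisson(self):
        """Pure background at 1000/s: 1-ms bin counts follow Poisson(1)."""
        cfg = SimulationConfig(
            duration=10.0, burst_rate=0.0, bg_rate_dd=1000.0, bg_rate_da=0.0, bg_rate_aa=0.0, seed=21
        )
        s = simulate_photon_stream(cfg)
        assert np.all(s.channel == DONOR)
        counts = bin_photons(s, 1e-3)
        # chi-square GOF against Poisson(1), pooling the tail
        kmax = 5
        observed = np.array([np.sum(counts == k) for k in range(kmax)] + [np.sum(counts >= kmax)])
        pmf = stats.poisson.pmf(np.arange(kmax), 1.0)
        probs = np.append(pmf, 1.0 - pmf.sum())
        chi2 = stats.chisquare(observed, probs * counts.size)
        assert chi2.pvalue > 0.01

    def test_single_state_acceptor_fraction_matches_true_E(self, clean_single_state_stream):
        _, s = clean_single_state_stream
        donor_window = s.excitation == DONOR_WINDOW
        n_dw = int(donor_window.sum())
        n_da = int(np.sum(donor_window & (s.channel == ACCEPTOR)))
        se = np.sqrt(0.7 * 0.3 / n_dw)
        assert n_da / n_dw == pytest.approx(0.7, abs=3 * se)

    def test_state_frequencies_match_weights(self):
        cfg = SimulationConfig(duration=100.0, seed=17)
        s = simulate_photon_stream(cfg)
        idx = s.truth.state_index
        frac_high = np.mean(idx == 1)
        se = np.sqrt(0.62 * 0.38 / idx.size)
        assert frac_high == pytest.approx(0.62, abs=3 * se)

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(states=[(0.6, 0.5), (0.8, 0.6)])

    def test_conc_requires_binding(self):
        with pytest.raises(ValueError):
            simulate_photon_stream(SimulationConfig(duration=1.0), conc=1.0)


class TestTitration:
    def test_empty_concs_rejected(self, binding_params):
        with pytest.raises(ValueError):
            simulate_titration(SimulationConfig(duration=1.0), binding_params, [])

    def test_state_fractions_follow_binding_law(self, binding_params):
        binding = BindingModelParams(kd=0.53, f0=0.4, f_inf=1.0)
        cfg = SimulationConfig(duration=60.0, seed=23)
        pts = simulate_titration(cfg, binding, [0.0, 1e6])
        for conc, stream in pts:
            truth = stream.truth
            frac = np.mean(truth.state_index == np.argmax(truth.state_E))
            expected = 0.4 if conc == 0 else 1.0
            se = np.sqrt(max(expected * (1 - expected), 0.25 / truth.state_index.size) / truth.state_index.size)
            assert frac == pytest.approx(expected, abs=max(3 * se, 1e-12))

    def test_titration_is_deterministic(self, binding_params):
        cfg = SimulationConfig(duration=5.0, seed=31)
        a = simulate_titration(cfg, binding_params, [0.0, 0.5])
        b = simulate_titration(cfg, binding_params, [0.0, 0.5])
        for (_, sa), (_, sb) in zip(a, b):
            np.testing.assert_array_equal(sa.timestamps, sb.timestamps)

    def test_per_point_seeds_differ(self):
        assert derive_seed(1, 0) != derive_seed(1, 1)
        assert derive_seed(1, 0) == derive_seed(1, 0)
        assert 0 <= derive_seed(123456, 7) < 2**31


class TestMeltingCurveSimulation:
    def test_midpoint_and_asymptotes(self):
        temps = np.arange(4.0, 96.0)
        c = simulate_melting_curve(60.0, 3.0, (0.0, 1.0), temps)
        i_tm = int(np.argmin(np.abs(temps - 60.0)))
        assert c.signal[i_tm] == pytest.approx(0.5, abs=1e-9)
        assert c.signal[0] == pytest.approx(0.0, abs=1e-6)
        assert c.signal[-1] == pytest.approx(1.0, abs=1e-4)

    def test_half_transition_point_by_bisection(self):
        """Interpolated half-transition of the noiseless curve sits at tm."""
        temps = np.arange(4.0, 96.0)
        c = simulate_melting_curve(60.0, 3.0, (0.2, 1.2), temps)
        target = 0.7  # (low + high) / 2
        lo, hi = 4.0, 95.0
        for _ in range(60):
            mid = (lo + hi) / 2.0
            if np.interp(mid, temps, c.signal) < target:
                lo = mid
            else:
                hi = mid
        assert (lo + hi) / 2.0 == pytest.approx(60.0, abs=0.01)

    def test_invalid_width_rejected(self):
        with pytest.raises(ValueError):
            simulate_melting_curve(60.0, 0.0, (0.0, 1.0), np.arange(4.0, 96.0))

    def test_noise_is_seeded(self):
        temps = np.arange(4.0, 96.0)
        a = simulate_melting_curve(60.0, 3.0, (0.0, 1.0), temps, noise_sd=0.05, seed=2)
        b = simulate_melting_curve(60.0, 3.0, (0.0, 1.0), temps, noise_sd=0.05, seed=2)
        np.testing.assert_array_equal(a.signal, b.signal)


def test_infer_excitation_splits_sync_period():
    period = 1.0 / 32e6
    t = np.array([0.1, 0.4, 0.6, 0.9]) * period
    assert infer_excitation(t).tolist() == [
        DONOR_WINDOW, DONOR_WINDOW, ACCEPTOR_WINDOW, ACCEPTOR_WINDOW,
    ]
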