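"""Shared fixtures and independent reference implementations (oracles)."""

import math

import numpy as np
import pytest

from gqfret.bursts import BurstSearchParams
from gqfret.simulate import BindingModelParams, SimulationConfig, simulate_photon_stream
from gqfret.stream import PhotonStream


def brute_force_bursts(stream: PhotonStream, params: BurstSearchParams):
    """Reference burst search: explicit per-bin enumeration, no vectorization.

    Returns (start_time, stop_time, i0, i1) tuples for comparison against
    the production search.
    """
    n_bins = max(1, math.ceil(stream.duration / params.bin_width)) if stream.duration > 0 else 1
    counts = [0] * n_bins
    bin_of = []
    for t in stream.timestamps:
        b = min(int(t // params.bin_width), n_bins - 1)
        bin_of.append(b)
        counts[b] += 1
    bursts = []
    i = 0
    while i < n_bins:
        if counts[i] >= params.threshold:
            j = i
            while j + 1 < n_bins and counts[j + 1] >= params.threshold:
                j += 1
            idxs = [p for p, b in enumerate(bin_of) if i <= b <= j]
            if len(idxs) >= params.min_photons:
                bursts.append(
                    (i * params.bin_width, (j + 1) * params.bin_width, min(idxs), max(idxs) + 1)
                )
            i = j + 1
        else:
            i += 1
    return bursts


def random_stream(rng: np.random.Generator, max_photons: int = 200) -> PhotonStream:
    """A small random photon stream with clustered and scattered photons."""
    duration = rng.uniform(0.005, 0.05)
    n_scatter = rng.integers(0, max_photons // 2)
    times = [rng.uniform(0, duration, n_scatter)]
    # a few dense clusters so thresholds actually trigger
    budget = max_photons - n_scatter
    while budget > 0:
        size = int(rng.integers(1, min(60, budget) + 1))
        center = rng.uniform(0, duration)
        times.append(np.clip(center + rng.normal(0, 5e-4, size), 0, duration))
        budget -= size
    t = np.sort(np.concatenate(times))
    n = t.size
    return PhotonStream(
        timestamps=t,
        channel=rng.integers(0, 2, n).astype(np.uint8),
        excitation=rng.integers(0, 2, n).astype(np.uint8),
        duration=duration,
    )


@pytest.fixture(scope="session")
def apo_sample():
    """5000 burst-E draws from the apo two-species model (0.38 at 0.6, 0.62 at 0.8)."""
    rng = np.random.default_rng(42)
    n = 5000
    high = rng.random(n) < 0.62
    return np.where(high, rng.normal(0.8, 0.05, n), rng.normal(0.6, 0.05, n))


@pytest.fixture(scope="session")
def clean_single_state_stream():
    """A background-free single-state (E=0.7) simulation with >=1000 bursts."""
    cfg = SimulationConfig(
        duration=120.0,
        burst_rate=20.0,
        bg_rate_dd=0.0,
        bg_rate_da=0.0,
        bg_rate_aa=0.0,
        states=[(0.7, 1.0)],
        seed=11,
    )
    return cfg, simulate_photon_stream(cfg)


@pytest.fixture
def binding_params():
    return BindingModelParams(kd=0.53, f0=0.62, f_inf=1.0)
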