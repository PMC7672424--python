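"""Synthetic confocal PIE photon streams, ligand titrations and melting curves.

The generator emulates a diffusion-based single-molecule FRET measurement of a
doubly labelled (donor + acceptor) molecule at ~100 pM: rare single-molecule
transits of the confocal volume appear as photon bursts over a Poisson
background.  Each burst belongs to one conformational state with a true FRET
efficiency ``E``; its donor-excitation photons are split between donor and
acceptor channels binomially with acceptor probability ``E``, and a configurable
fraction of its photons falls in the acceptor-excitation (PIE) window, which
probes the acceptor directly and enables stoichiometry.  Ligand binding follows
a conformational-selection (population-shift) law: the weight of the high-FRET
state increases hyperbolically with ligand concentration.

Modelling choices (deliberately minimal, matched to what a 1-ms binned burst
search can resolve):

- burst arrivals are Poisson in time; burst sizes follow a geometric law
  (heavy-tailed, like real diffusing-molecule bursts);
- photons of a burst are spread uniformly over an exponential-duration window
  (mean 1 ms); finer within-burst kinetics are unobservable after binning;
- no photophysics (bleaching/blinking) — experimentally these are suppressed
  with a photostabilizing buffer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from gqfret.stream import (
    ACCEPTOR,
    ACCEPTOR_WINDOW,
    DEFAULT_SYNC_RATE_HZ,
    DONOR,
    DONOR_WINDOW,
    PhotonStream,
)

_SIZE_LAWS = ("geometric", "lognormal")


@dataclass
class BindingModelParams:
    """Parameters of the 1:1 conformational-selection population-shift model.

    ``kd`` is the dissociation constant in μM; ``f0`` and ``f_inf`` are the
    high-FRET population fractions at zero ligand and at saturation.
    """

    kd: float
    f0: float
    f_inf: float

    def __post_init__(self) -> None:
        if self.kd <= 0:
            raise ValueError("kd must be positive")
        if not (0.0 <= self.f0 <= self.f_inf <= 1.0):
            raise ValueError("require 0 <= f0 <= f_inf <= 1")


def population_from_binding(params: BindingModelParams, conc: float) -> float:
    """High-FRET population fraction at ligand concentration ``conc`` (μM).

    Evaluates the 1:1 hyperbolic population-shift law

        f(L) = f0 + (f_inf - f0) * L / (kd + L),

    valid when the labelled DNA is far below the ligand concentration so that
    ligand depletion is negligible (here DNA is at ~100 pM against μM ligand).
    """
    conc = float(conc)
    if conc < 0:
        raise ValueError("concentration must be non-negative")
    if conc == 0:
        return params.f0
    return params.f0 + (params.f_inf - params.f0) * conc / (params.kd + conc)


def population_from_binding_depletion(
    params: BindingModelParams, conc: float, receptor_conc: float
) -> float:
    """Depletion-corrected population fraction (quadratic 1:1 binding).

    Uses the exact bound fraction of a 1:1 equilibrium at total ligand
    ``conc`` and total receptor ``receptor_conc`` (both μM).  Reduces to
    :func:`population_from_binding` as ``receptor_conc -> 0``.
    """
    conc = float(conc)
    if conc < 0:
        raise ValueError("concentration must be non-negative")
    if receptor_conc <= 0:
        raise ValueError("receptor_conc must be positive")
    r, l, kd = receptor_conc, conc, params.kd
    # bound complex from the quadratic root; numerically stable form
    b = r + l + kd
    complex_conc = (b - np.sqrt(b * b - 4.0 * r * l)) / 2.0
    theta = complex_conc / r
    return params.f0 + (params.f_inf - params.f0) * float(theta)


@dataclass
class SimulationConfig:
    """Configuration of a synthetic photon-stream acquisition.

    Parameters
    ----------
    duration
        Acquisition length in seconds.
    burst_rate
        Single-molecule transit rate, bursts per second.
    burst_size_mean
        Mean photons per burst under ``size_law`` (default geometric, mean 60).
    size_law
        ``"geometric"`` or ``"lognormal"`` (lognormal uses ``size_sigma``).
    bg_rate_dd, bg_rate_da, bg_rate_aa
        Background photon rates (counts/s) in the donor-window/donor-channel,
        donor-window/acceptor-channel and acceptor-window/acceptor-channel
        classes.
    states
        List of ``(true_E, weight)`` pairs defining the conformational
        mixture; weights must sum to 1.
    aa_fraction
        Fraction of a burst's photons emitted during the acceptor-excitation
        window (direct acceptor probing for stoichiometry).
    burst_duration_mean
        Mean of the exponential burst-duration law, seconds.
    seed
        Master seed for reproducibility.
    """

    duration: float = 60.0
    burst_rate: float = 20.0
    burst_size_mean: float = 60.0
    size_law: str = "geometric"
    size_sigma: float = 0.7
    bg_rate_dd: float = 300.0
    bg_rate_da: float = 150.0
    bg_rate_aa: float = 150.0
    states: list[tuple[float, float]] = field(default_factory=lambda: [(0.6, 0.38), (0.8, 0.62)])
    aa_fraction: float = 0.25
    burst_duration_mean: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration < 0:
            raise ValueError("duration must be non-negative")
        for name in ("burst_rate", "bg_rate_dd", "bg_rate_da", "bg_rate_aa"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.burst_size_mean < 1:
            raise ValueError("burst_size_mean must be >= 1")
        if self.size_law not in _SIZE_LAWS:
            raise ValueError(f"size_law must be one of {_SIZE_LAWS}")
        if not self.states:
            raise ValueError("at least one state is required")
        for e, w in self.states:
            if not (0.0 <= e <= 1.0):
                raise ValueError("true_E must lie in [0, 1]")
            if w < 0:
                raise ValueError("state weights must be non-negative")
        total = sum(w for _, w in self.states)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"state weights must sum to 1 (got {total})")
        if not (0.0 <= self.aa_fraction < 1.0):
            raise ValueError("aa_fraction must lie in [0, 1)")
        if self.burst_duration_mean <= 0:
            raise ValueError("burst_duration_mean must be positive")

    @property
    def true_E(self) -> np.ndarray:
        return np.array([e for e, _ in self.states], dtype=float)

    @property
    def weights(self) -> np.ndarray:
        return np.array([w for _, w in self.states], dtype=float)


@dataclass
class SimulationTruth:
    """Ground-truth burst bookkeeping attached to simulated streams."""

    burst_start: np.ndarray  # seconds
    burst_stop: np.ndarray  # seconds
    state_index: np.ndarray  # index into state_E
    burst_size: np.ndarray  # photons per burst (before clipping at duration)
    state_E: np.ndarray  # true efficiency per state
    state_weight: np.ndarray  # weights actually used (possibly conc-adjusted)


def derive_seed(master: int, index: int) -> int:
    """Deterministically derive a per-stream seed from (master seed, index)."""
    ss = np.random.SeedSequence([int(master), int(index)])
    return int(ss.generate_state(1)[0] % (2**31))


def _adjusted_weights(config: SimulationConfig, f_high: float) -> np.ndarray:
    """Set the highest-E state weight to ``f_high``, rescaling the others."""
    weights = config.weights.copy()
    high = int(np.argmax(config.true_E))
    if len(weights) == 1:
        return np.array([1.0])
    others = np.delete(np.arange(len(weights)), high)
    rest = weights[others].sum()
    out = np.empty_like(weights)
    out[high] = f_high
    if rest > 0:
        out[others] = weights[others] * (1.0 - f_high) / rest
    else:
        out[others] = (1.0 - f_high) / len(others)
    return out


def _burst_sizes(rng: np.random.Generator, config: SimulationConfig, n: int) -> np.ndarray:
    if config.size_law == "geometric":
        return rng.geometric(1.0 / config.burst_size_mean, size=n)
    # lognormal with the requested arithmetic mean
    mu = np.log(config.burst_size_mean) - config.size_sigma**2 / 2.0
    return np.maximum(1, np.round(rng.lognormal(mu, config.size_sigma, size=n))).astype(np.int64)


def simulate_photon_stream(
    config: SimulationConfig,
    conc: float | None = None,
    binding: BindingModelParams | None = None,
) -> PhotonStream:
    """Simulate one PIE photon stream under ``config``.

    If ``conc`` (μM) is given, ``binding`` must be given too and the weight of
    the highest-E state is overridden by :func:`population_from_binding`.
    Reproducible under a fixed ``config.seed``; an empty stream results from
    zero duration or zero source rates.
    """
    if conc is not None and binding is None:
        raise ValueError("binding parameters are required when conc is given")
    weights = config.weights
    if conc is not None:
        weights = _adjusted_weights(config, population_from_binding(binding, conc))

    rng = np.random.default_rng(config.seed)
    n_bursts = rng.poisson(config.burst_rate * config.duration)
    starts = np.sort(rng.uniform(0.0, config.duration, size=n_bursts)) if n_bursts else np.empty(0)
    state_idx = rng.choice(len(config.states), size=n_bursts, p=weights)
    sizes = _burst_sizes(rng, config, n_bursts)
    durations = rng.exponential(config.burst_duration_mean, size=n_bursts)

    # per-burst photon partition: acceptor-window first, then donor-window
    # photons split donor/acceptor binomially with p = state true_E
    n_aa = rng.binomial(sizes, config.aa_fraction) if n_bursts else np.empty(0, dtype=np.int64)
    n_dw = sizes - n_aa
    p_accept = config.true_E[state_idx] if n_bursts else np.empty(0)
    n_da = rng.binomial(n_dw, p_accept) if n_bursts else np.empty(0, dtype=np.int64)
    n_dd = n_dw - n_da

    burst_ids = np.concatenate([
        np.repeat(np.arange(n_bursts), n_dd),
        np.repeat(np.arange(n_bursts), n_da),
        np.repeat(np.arange(n_bursts), n_aa),
    ])
    channel = np.concatenate([
        np.full(int(n_dd.sum()), DONOR, dtype=np.uint8),
        np.full(int(n_da.sum()), ACCEPTOR, dtype=np.uint8),
        np.full(int(n_aa.sum()), ACCEPTOR, dtype=np.uint8),
    ])
    excitation = np.concatenate([
        np.full(int(n_dd.sum()), DONOR_WINDOW, dtype=np.uint8),
        np.full(int(n_da.sum()), DONOR_WINDOW, dtype=np.uint8),
        np.full(int(n_aa.sum()), ACCEPTOR_WINDOW, dtype=np.uint8),
    ])
    if burst_ids.size:
        times = starts[burst_ids] + rng.uniform(size=burst_ids.size) * durations[burst_ids]
        times = np.clip(times, 0.0, config.duration)
    else:
        times = np.empty(0)

    # Poisson background per photon class, uniform in time
    bg_specs = [
        (config.bg_rate_dd, DONOR, DONOR_WINDOW),
        (config.bg_rate_da, ACCEPTOR, DONOR_WINDOW),
        (config.bg_rate_aa, ACCEPTOR, ACCEPTOR_WINDOW),
    ]
    for rate, ch, exc in bg_specs:
        n_bg = rng.poisson(rate * config.duration)
        if n_bg == 0:
            continue
        times = np.concatenate([times, rng.uniform(0.0, config.duration, size=n_bg)])
        channel = np.concatenate([channel, np.full(n_bg, ch, dtype=np.uint8)])
        excitation = np.concatenate([excitation, np.full(n_bg, exc, dtype=np.uint8)])

    order = np.argsort(times, kind="stable")
    truth = SimulationTruth(
        burst_start=starts,
        burst_stop=np.minimum(starts + durations, config.duration) if n_bursts else np.empty(0),
        state_index=state_idx,
        burst_size=sizes,
        state_E=config.true_E,
        state_weight=weights,
    )
    return PhotonStream(
        timestamps=times[order],
        channel=channel[order],
        excitation=excitation[order],
        duration=config.duration,
        sync_rate_hz=DEFAULT_SYNC_RATE_HZ,
        truth=truth,
    )


def simulate_titration(
    config: SimulationConfig,
    binding: BindingModelParams,
    concs: list[float],
) -> list[tuple[float, PhotonStream]]:
    """Simulate one photon stream per ligand concentration (μM).

    The high-E state weight at each concentration follows
    :func:`population_from_binding`; each stream's seed is derived
    deterministically from ``(config.seed, index)``.
    """
    if len(concs) == 0:
        raise ValueError("concs must be non-empty")
    if any(c < 0 for c in concs):
        raise ValueError("concentrations must be non-negative")
    out = []
    for i, conc in enumerate(concs):
        cfg_i = SimulationConfig(**{**config.__dict__, "seed": derive_seed(config.seed, i)})
        out.append((float(conc), simulate_photon_stream(cfg_i, conc=conc, binding=binding)))
    return out


def simulate_melting_curve(
    tm: float,
    width: float,
    baselines: tuple[float, float],
    temps,
    noise_sd: float = 0.0,
    seed: int = 0,
    label: str = "synthetic",
):
    """Synthetic thermal-melting curve (e.g. ellipticity at a fixed wavelength).

    The noiseless signal is a Boltzmann sigmoid

        s(T) = low + (high - low) / (1 + exp((tm - T) / width)),

    so ``s(tm)`` is the mid-transition value; Gaussian noise of standard
    deviation ``noise_sd`` is added, reproducibly under ``seed``.
    """
    from gqfret.melting import MeltingCurve, boltzmann

    temps = np.asarray(temps, dtype=float)
    if temps.size == 0:
        raise ValueError("temps must be non-empty")
    if width <= 0:
        raise ValueError("width must be positive")
    low, high = baselines
    signal = boltzmann(temps, tm, width, low, high)
    if noise_sd > 0:
        signal = signal + np.random.default_rng(seed).normal(0.0, noise_sd, size=temps.size)
    return MeltingCurve(temps=temps, signal=signal, label=label)
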