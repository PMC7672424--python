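"""Melting-midpoint (Tm) fitting and ligand-induced stabilization (delta-Tm).

A thermal melting curve (signal such as ellipticity at a structure-diagnostic
wavelength vs temperature) of a two-state unfolding transition is modelled as
a Boltzmann sigmoid with horizontal baselines,

    s(T) = low + (high - low) / (1 + exp((tm - T) / width)),

where ``tm`` is the midpoint temperature and ``width`` the transition
steepness (°C).  The primary estimator is a nonlinear least-squares fit of
that sigmoid, initialized from the extremum of the smoothed numerical
derivative; a derivative-extremum estimate is reported alongside as a
cross-check and a warning is emitted when the two disagree by more than 1 °C.
The ligand-induced stabilization is the difference of fitted midpoints,
delta-Tm = tm(with ligand) - tm(without).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.ndimage import uniform_filter1d


class NoTransitionError(ValueError):
    """Raised when a curve shows no resolvable melting transition."""


@dataclass
class MeltingCurve:
    """Temperature (°C, strictly increasing) vs signal (arbitrary units)."""

    temps: np.ndarray
    signal: np.ndarray
    label: str = ""
    temp_range: tuple[float, float] = (0.0, 100.0)

    def __post_init__(self) -> None:
        self.temps = np.asarray(self.temps, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.temps.size != self.signal.size:
            raise ValueError("temps and signal must have equal length")
        if self.temps.size < 8:
            raise ValueError("a melting curve needs at least 8 points")
        if np.any(np.diff(self.temps) <= 0):
            raise ValueError("temperatures must be strictly increasing")
        lo, hi = self.temp_range
        if self.temps[0] < lo or self.temps[-1] > hi:
            raise ValueError(f"temperatures must lie within the instrument range {self.temp_range}")


@dataclass
class TmResult:
    """Fitted melting midpoint with transition width and baselines."""

    tm: float
    width: float
    baselines: tuple[float, float]
    rss: float
    method: str = "boltzmann"
    tm_derivative: float | None = None
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("width must be positive")


def boltzmann(temps, tm, width, low, high):
    """Boltzmann sigmoid with horizontal baselines."""
    temps = np.asarray(temps, dtype=float)
    return low + (high - low) / (1.0 + np.exp((tm - temps) / width))


def _boltzmann_sloped(temps, tm, width, low, high, slope_low, slope_high):
    temps = np.asarray(temps, dtype=float)
    frac = 1.0 / (1.0 + np.exp((tm - temps) / width))
    return (low + slope_low * temps) * (1.0 - frac) + (high + slope_high * temps) * frac


def derivative_tm(curve: MeltingCurve, smooth_points: int = 5) -> float:
    """Midpoint estimate as the extremum of the smoothed numerical derivative."""
    smoothed = uniform_filter1d(curve.signal, size=max(1, smooth_points), mode="nearest")
    dsdt = np.gradient(smoothed, curve.temps)
    idx = int(np.argmax(np.abs(dsdt)))
    return float(curve.temps[idx])


def fit_tm(curve: MeltingCurve, sloped_baselines: bool = False) -> TmResult:
    """Least-squares Boltzmann sigmoid fit of a melting curve.

    Deterministic: initialized from the derivative-extremum midpoint, the
    signal extrema as baselines and a width from the data span.  The result
    carries the derivative-based midpoint (``tm_derivative``) as an
    independent cross-check; disagreement beyond 1 °C adds a flag and a
    warning.  Sign of the transition is irrelevant (an inverted band fits
    with swapped baselines).

    Raises :class:`NoTransitionError` when the amplitude is indistinguishable
    from the residual noise; warns when the fitted midpoint sits outside the
    measured temperature range.
    """
    t, s = curve.temps, curve.signal
    tm0 = derivative_tm(curve)
    low0 = float(s[0])
    high0 = float(s[-1])
    width0 = max((t[-1] - t[0]) / 20.0, 0.5)

    def model(temps, *p):
        return (_boltzmann_sloped if sloped_baselines else boltzmann)(temps, *p)

    p0 = [tm0, width0, low0, high0] + ([0.0, 0.0] if sloped_baselines else [])
    lower = [t[0] - 50.0, 1e-3, -np.inf, -np.inf] + ([-np.inf] * 2 if sloped_baselines else [])
    upper = [t[-1] + 50.0, (t[-1] - t[0]), np.inf, np.inf] + ([np.inf] * 2 if sloped_baselines else [])
    try:
        popt, _ = optimize.curve_fit(
            model, t, s, p0=p0, bounds=(lower, upper), maxfev=20000, xtol=1e-14, ftol=1e-14
        )
    except RuntimeError as exc:
        raise NoTransitionError(f"sigmoid fit did not converge: {exc}") from exc

    resid = s - model(t, *popt)
    rss = float(np.sum(resid**2))
    resid_sd = float(np.std(resid))
    tm, width, low, high = (float(v) for v in popt[:4])
    # amplitude realized inside the measured window: a "transition" whose
    # midpoint escaped the range contributes almost nothing here
    amplitude = abs(float(model(np.array([t[-1]]), *popt)[0] - model(np.array([t[0]]), *popt)[0]))

    flags = []
    if amplitude <= 3.0 * max(resid_sd, 1e-12):
        raise NoTransitionError(
            f"transition amplitude {amplitude:.3g} not distinguishable from noise (sd {resid_sd:.3g})"
        )
    if not (t[0] <= tm <= t[-1]):
        warnings.warn(f"fitted tm {tm:.2f} lies outside the measured range", stacklevel=2)
        flags.append("tm_out_of_range")
    if abs(tm - tm0) > 1.0:
        warnings.warn(
            f"sigmoid tm {tm:.2f} and derivative tm {tm0:.2f} disagree by more than 1 degree",
            stacklevel=2,
        )
        flags.append("method_disagreement")
    return TmResult(
        tm=tm, width=float(width), baselines=(low, high), rss=rss,
        method="boltzmann_sloped" if sloped_baselines else "boltzmann",
        tm_derivative=tm0, flags=flags,
    )


def delta_tm(with_ligand: TmResult, without: TmResult) -> float:
    """Ligand-induced midpoint shift, tm(with) - tm(without); °C, signed."""
    return with_ligand.tm - without.tm


def read_melting_csv(path, label: str | None = None) -> MeltingCurve:
    """Read a melting curve from CSV with columns temperature_C, signal."""
    df = pd.read_csv(path, comment="#")
    missing = {"temperature_C", "signal"} - set(df.columns)
    if missing:
        raise ValueError(f"melting CSV {path} lacks column(s): {sorted(missing)}")
    return MeltingCurve(
        temps=df["temperature_C"].to_numpy(),
        signal=df["signal"].to_numpy(),
        label=label or Path(path).stem,
    )


def batch_delta_tm(manifest_path) -> pd.DataFrame:
    """Compute a delta-Tm table from a manifest CSV (label, file, ligand_flag).

    Curves sharing a label are paired by ``ligand_flag`` (0 = apo,
    1 = with ligand); the output has one row per label with both fitted
    midpoints and their difference.
    """
    manifest = pd.read_csv(manifest_path)
    missing = {"label", "file", "ligand_flag"} - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest lacks column(s): {sorted(missing)}")
    base = Path(manifest_path).parent
    rows = []
    for label, group in manifest.groupby("label", sort=False):
        fits = {}
        for _, row in group.iterrows():
            p = Path(row["file"])
            curve = read_melting_csv(p if p.is_absolute() else base / p, label=str(label))
            fits[int(row["ligand_flag"])] = fit_tm(curve)
        if set(fits) != {0, 1}:
            raise ValueError(f"label {label!r} needs exactly one apo and one ligand curve")
        rows.append(
            {
                "label": label,
                "tm_apo_C": fits[0].tm,
                "tm_ligand_C": fits[1].tm,
                "delta_tm_C": delta_tm(fits[1], fits[0]),
            }
        )
    return pd.DataFrame(rows)
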