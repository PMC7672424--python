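"""Corrected per-burst FRET efficiency, PIE stoichiometry and E histograms.

Implements the standard PIE/ALEX correction algebra.  For a burst with raw
counts ``n_dd`` (donor excitation, donor channel), ``n_da`` (donor excitation,
acceptor channel) and ``n_aa`` (acceptor excitation, acceptor channel), after
subtracting the expected background for the burst duration, the corrected
acceptor signal is

    F_A = F_DA - alpha * F_DD - delta * F_AA

where ``alpha`` is donor spectral leakage into the acceptor channel and
``delta`` the acceptor direct-excitation factor, and

    E = F_A / (F_A + gamma * F_DD)
    S = (gamma * F_DD + F_A) / (gamma * F_DD + F_A + F_AA)

with ``gamma`` the detection-efficiency/quantum-yield ratio.  With default
factors (gamma=1, alpha=delta=0, zero background) E reduces to the proximity
ratio ``n_da / (n_da + n_dd)``.  E is deliberately not clamped to [0, 1]:
shot noise places some bursts slightly outside and clamping would distort the
mixture tails.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from gqfret.bursts import Burst

logger = logging.getLogger(__name__)


class UndefinedRatioError(ZeroDivisionError):
    """Raised when an efficiency or stoichiometry denominator is not positive."""


@dataclass
class CorrectionFactors:
    """Instrument calibration for converting counts to corrected E and S.

    ``gamma`` (>0) rescales donor counts for detection-efficiency and
    quantum-yield imbalance; ``leakage_alpha`` removes donor bleed-through
    into the acceptor channel; ``direct_delta`` removes acceptor emission from
    direct donor-laser excitation; ``bg_rate_*`` are per-class background
    rates (counts/s) subtracted in proportion to burst duration.  Defaults
    are the identity correction (proximity ratio).
    """

    gamma: float = 1.0
    leakage_alpha: float = 0.0
    direct_delta: float = 0.0
    bg_rate_dd: float = 0.0
    bg_rate_da: float = 0.0
    bg_rate_aa: float = 0.0

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.leakage_alpha < 0 or self.direct_delta < 0:
            raise ValueError("leakage_alpha and direct_delta must be >= 0")
        if min(self.bg_rate_dd, self.bg_rate_da, self.bg_rate_aa) < 0:
            raise ValueError("background rates must be >= 0")

    def corrected_counts(self, burst: Burst) -> tuple[float, float, float]:
        """Background-corrected (F_DD, F_A, F_AA) for one burst."""
        dur = burst.duration
        f_dd = burst.n_dd - self.bg_rate_dd * dur
        f_da = burst.n_da - self.bg_rate_da * dur
        f_aa = burst.n_aa - self.bg_rate_aa * dur
        f_a = f_da - self.leakage_alpha * f_dd - self.direct_delta * f_aa
        return f_dd, f_a, f_aa


def proximity_ratio(n_dd: int, n_da: int) -> float:
    """Uncorrected FRET estimate ``n_da / (n_da + n_dd)``."""
    if n_dd < 0 or n_da < 0:
        raise ValueError("photon counts must be non-negative")
    total = n_dd + n_da
    if total <= 0:
        raise UndefinedRatioError("proximity ratio undefined for zero donor-window counts")
    return n_da / total


def corrected_E(burst: Burst, corr: CorrectionFactors | None = None) -> float:
    """Corrected FRET efficiency of one burst; may fall slightly outside [0,1].

    Raises :class:`UndefinedRatioError` when the corrected denominator
    ``F_A + gamma * F_DD`` is not positive (e.g. a background-only episode);
    callers batch-processing bursts should exclude and log such bursts.
    """
    corr = corr or CorrectionFactors()
    f_dd, f_a, _ = corr.corrected_counts(burst)
    denom = f_a + corr.gamma * f_dd
    if denom <= 0:
        raise UndefinedRatioError(
            f"non-positive corrected denominator ({denom:.3g}) for burst at {burst.start_time:.6f} s"
        )
    return f_a / denom


def stoichiometry(burst: Burst, corr: CorrectionFactors | None = None) -> float:
    """PIE stoichiometry S of one burst: ~1 donor-only, ~0 acceptor-only."""
    corr = corr or CorrectionFactors()
    f_dd, f_a, f_aa = corr.corrected_counts(burst)
    num = corr.gamma * f_dd + f_a
    denom = num + f_aa
    if denom <= 0:
        raise UndefinedRatioError(
            f"non-positive total corrected signal for burst at {burst.start_time:.6f} s"
        )
    return num / denom


def burst_efficiencies(
    bursts: list[Burst], corr: CorrectionFactors | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vector of (E, S, retained) across bursts, excluding undefined ones.

    Bursts whose corrected denominators are non-positive are flagged
    ``retained=False`` (their E/S are NaN) and logged, not raised.
    """
    corr = corr or CorrectionFactors()
    e = np.full(len(bursts), np.nan)
    s = np.full(len(bursts), np.nan)
    retained = np.zeros(len(bursts), dtype=bool)
    n_excluded = 0
    for i, b in enumerate(bursts):
        try:
            e[i] = corrected_E(b, corr)
            retained[i] = True
        except UndefinedRatioError:
            n_excluded += 1
            continue
        try:
            s[i] = stoichiometry(b, corr)
        except UndefinedRatioError:
            s[i] = np.nan
    if n_excluded:
        logger.warning("excluded %d burst(s) with undefined corrected E", n_excluded)
    return e, s, retained


def filter_dual_label(
    bursts: list[Burst],
    corr: CorrectionFactors | None = None,
    s_min: float = 0.25,
    s_max: float = 0.85,
) -> list[Burst]:
    """Keep bursts whose stoichiometry lies in ``[s_min, s_max]``.

    The gate rejects donor-only (S ~ 1) and acceptor-only (S ~ 0) molecules,
    retaining dual-labelled ones; order is preserved.  Bursts with undefined
    S are dropped.
    """
    if not (0.0 <= s_min < s_max <= 1.0):
        raise ValueError("require 0 <= s_min < s_max <= 1")
    corr = corr or CorrectionFactors()
    kept = []
    for b in bursts:
        try:
            s = stoichiometry(b, corr)
        except UndefinedRatioError:
            continue
        if s_min <= s <= s_max:
            kept.append(b)
    return kept


@dataclass
class FretDistribution:
    """Per-burst E values with an optional histogram over a fixed E range."""

    e_values: np.ndarray
    s_values: np.ndarray | None = None
    edges: np.ndarray | None = None
    counts: np.ndarray | None = None
    n_underflow: int = 0
    n_overflow: int = 0
    flags: list[str] = field(default_factory=list)


def build_histogram(e_values, edges=None) -> FretDistribution:
    """Histogram burst E values over strictly increasing bin ``edges``.

    Default edges span -0.1 to 1.1 in steps of 0.025 (E is not clamped, so
    the range extends slightly beyond [0, 1]).  Values outside the range are
    tallied as under/overflow so totals are conserved.
    """
    e_values = np.asarray(e_values, dtype=float)
    if edges is None:
        edges = np.arange(-0.1, 1.1 + 1e-12, 0.025)
    edges = np.asarray(edges, dtype=float)
    if edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("edges must be strictly increasing with at least two values")
    flags = []
    if e_values.size == 0:
        flags.append("empty")
        logger.warning("building histogram from an empty E list")
    counts, _ = np.histogram(e_values, bins=edges)
    n_under = int(np.sum(e_values < edges[0]))
    n_over = int(np.sum(e_values > edges[-1]))
    return FretDistribution(
        e_values=e_values,
        edges=edges,
        counts=counts,
        n_underflow=n_under,
        n_overflow=n_over,
        flags=flags,
    )
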