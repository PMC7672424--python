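"""Dissociation-constant estimation from ligand-driven population shifts.

Under conformational selection, a ligand that preferentially binds the
high-FRET conformation enriches it without shifting its FRET efficiency; the
high-FRET population fraction f as a function of total ligand concentration L
(μM) follows the 1:1 hyperbolic law

    f(L) = f0 + (f_inf - f0) * L / (kd + L)

when the labelled DNA is far below L (no ligand depletion), or the exact
quadratic 1:1 form otherwise.  ``fit_kd`` fits (kd, f0, f_inf) by weighted
nonlinear least squares, weighting each titration point by its burst count
(more bursts, more information), with a deterministic multistart over kd
decades to avoid local minima.  f_inf is free, not pinned to 1: a residual
low-FRET population can survive at the highest measured concentrations.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from gqfret.mixture import MixtureModel, population_fractions
from gqfret.simulate import BindingModelParams, population_from_binding_depletion


class IdentifiabilityError(ValueError):
    """Raised when the titration carries no usable concentration dependence."""


@dataclass
class TitrationSeries:
    """High-FRET fraction vs ligand concentration, sorted by concentration."""

    concs: np.ndarray  # μM
    fractions: np.ndarray  # high-FRET population fraction in [0, 1]
    n_bursts: np.ndarray  # bursts contributing to each point

    def __post_init__(self) -> None:
        self.concs = np.asarray(self.concs, dtype=float)
        self.fractions = np.asarray(self.fractions, dtype=float)
        self.n_bursts = np.asarray(self.n_bursts, dtype=np.int64)
        if not (self.concs.size == self.fractions.size == self.n_bursts.size):
            raise ValueError("concs, fractions and n_bursts must have equal length")
        if np.any(self.concs < 0):
            raise ValueError("concentrations must be non-negative")
        if np.any((self.fractions < 0) | (self.fractions > 1)):
            raise ValueError("fractions must lie in [0, 1]")
        order = np.argsort(self.concs, kind="stable")
        self.concs = self.concs[order]
        self.fractions = self.fractions[order]
        self.n_bursts = self.n_bursts[order]
        if np.any(np.diff(self.concs) == 0):
            raise ValueError("duplicate concentrations are not allowed")

    def __len__(self) -> int:
        return int(self.concs.size)


@dataclass
class BindingFit:
    """Fitted population-shift isotherm: kd (μM), f0, f_inf and diagnostics."""

    kd: float
    f0: float
    f_inf: float
    rss: float
    se_kd: float
    se_f0: float
    se_f_inf: float
    n_points: int
    model: str = "hyperbolic"
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.kd <= 0:
            raise ValueError("kd must be positive")
        if self.f0 > self.f_inf:
            raise ValueError("f0 must not exceed f_inf")

    def predict(self, conc) -> np.ndarray:
        conc = np.asarray(conc, dtype=float)
        return _isotherm(conc, self.kd, self.f0, self.f_inf, self.model)

    def to_dict(self) -> dict:
        return {
            "kd_uM": float(self.kd),
            "f0": float(self.f0),
            "f_inf": float(self.f_inf),
            "se_kd": float(self.se_kd),
            "se_f0": float(self.se_f0),
            "se_f_inf": float(self.se_f_inf),
            "rss": float(self.rss),
            "n_points": int(self.n_points),
            "model": self.model,
            "flags": list(self.flags),
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def build_titration(models: list[tuple[float, MixtureModel]]) -> TitrationSeries:
    """Extract the high-FRET (largest-mean) component weight at each point.

    A single-component model contributes fraction 1.0 with a warning (the low
    species is below detection at that concentration).  Warns when no apo
    (zero-concentration) point is present.
    """
    if len(models) < 3:
        raise ValueError("need at least 3 titration points")
    concs, fracs, ns = [], [], []
    for conc, model in models:
        if model.k == 1:
            warnings.warn(
                f"single-component model at {conc} uM treated as high-FRET fraction 1.0",
                stacklevel=2,
            )
            frac = 1.0
        else:
            frac = float(population_fractions(model)[-1])
        concs.append(float(conc))
        fracs.append(frac)
        ns.append(model.n_points)
    if min(concs) > 0:
        warnings.warn("no apo (conc=0) point in titration", stacklevel=2)
    return TitrationSeries(concs=np.array(concs), fractions=np.array(fracs), n_bursts=np.array(ns))


def _isotherm(conc, kd, f0, f_inf, model: str, receptor_conc: float = 1e-4):
    conc = np.asarray(conc, dtype=float)
    if model == "hyperbolic":
        return f0 + (f_inf - f0) * conc / (kd + conc)
    if model == "quadratic_depletion":
        params = BindingModelParams(kd=kd, f0=min(f0, f_inf), f_inf=max(f0, f_inf))
        out = np.array(
            [population_from_binding_depletion(params, c, receptor_conc) for c in conc]
        )
        return out if f0 <= f_inf else f0 + f_inf - out
    raise ValueError("model must be 'hyperbolic' or 'quadratic_depletion'")


def fit_kd(
    series: TitrationSeries,
    model: str = "hyperbolic",
    weighted: bool = True,
    receptor_conc: float = 1e-4,
) -> BindingFit:
    """Fit the population-shift isotherm and return the dissociation constant.

    Weighted least squares (weights proportional to per-point burst counts
    unless ``weighted=False``) with a deterministic multistart over
    log10(kd) in {-2, ..., 2}; the best-RSS solution is kept.  Standard
    errors come from the Gauss-Newton curvature at the optimum.
    ``receptor_conc`` (μM) is used only by the ``quadratic_depletion`` model.

    Raises :class:`IdentifiabilityError` for a flat series; warns when the
    fraction dynamic range is below 0.05.
    """
    if model not in ("hyperbolic", "quadratic_depletion"):
        raise ValueError("model must be 'hyperbolic' or 'quadratic_depletion'")
    if len(series) < 3:
        raise ValueError("need at least 3 distinct concentrations")
    f = series.fractions
    span = float(f.max() - f.min())
    if span < 1e-12:
        raise IdentifiabilityError("fractions are constant across concentrations")
    flags = []
    if span < 0.05:
        warnings.warn(f"fraction dynamic range {span:.3g} < 0.05; kd poorly constrained", stacklevel=2)
        flags.append("low_dynamic_range")

    w = series.n_bursts.astype(float) if weighted else np.ones(len(series))
    if np.all(w <= 0):
        w = np.ones(len(series))
    sw = np.sqrt(w / w.sum())

    def residuals(theta):
        log_kd, f0, f_inf = theta
        pred = _isotherm(series.concs, 10.0**log_kd, f0, f_inf, model, receptor_conc)
        return sw * (pred - f)

    f0_init = float(f[0])
    finf_init = float(f[-1])
    bounds = ([-6.0, 0.0, 0.0], [6.0, 1.0, 1.0])
    best = None
    for log_kd0 in range(-2, 3):
        theta0 = np.array([float(log_kd0), f0_init, finf_init])
        try:
            sol = optimize.least_squares(residuals, theta0, bounds=bounds, xtol=1e-15, ftol=1e-15, gtol=1e-15)
        except Exception:
            continue
        rss = float(2.0 * sol.cost)
        if best is None or rss < best[1]:
            best = (sol, rss)
    if best is None:
        raise RuntimeError("isotherm fit failed to converge from any start")
    sol, rss = best
    log_kd, f0, f_inf = sol.x
    kd = float(10.0**log_kd)
    if f0 > f_inf:
        f0, f_inf = f_inf, f0
        flags.append("inverted_transition")

    # standard errors from the Jacobian (Gauss-Newton approximation);
    # residual variance from weighted residuals with 3 fitted parameters
    se = np.full(3, np.nan)
    dof = len(series) - 3
    if dof > 0:
        try:
            jtj = sol.jac.T @ sol.jac
            cov = np.linalg.inv(jtj) * (rss / dof)
            se = np.sqrt(np.diag(cov))
            se[0] = se[0] * kd * np.log(10.0)  # delta method: log10(kd) -> kd
        except np.linalg.LinAlgError:
            flags.append("singular_covariance")
    return BindingFit(
        kd=kd, f0=float(f0), f_inf=float(f_inf), rss=rss,
        se_kd=float(se[0]), se_f0=float(se[1]), se_f_inf=float(se[2]),
        n_points=len(series), model=model, flags=flags,
    )
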