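"""Bragg-peak fitting for partially ordered systems and derived order parameters.

Peaks are modelled as Gaussian, Lorentzian or pseudo-Voigt (their linear
mixture) profiles, each parameterised by position s0, full width at half
maximum, and integrated area — area rather than height, so changing the
Lorentzian fraction eta does not silently rescale the intensity.  A
two-parameter linear background c0 + c1 s is refined simultaneously.

From the fitted profile the classical order parameters follow:
repeat distance d = 2 pi / s0; long-range order dimension L = 2 pi K / fwhm
(Scherrer-type, K = 1 by default); paracrystalline disorder
Delta/d = (1/pi) sqrt(fwhm d / 2); interaction radius R_m = L / 2.
These relations are deliberately collected in one overridable constants
table (``ORDER_CONSTANTS``) and echoed in every result, since different
communities use slightly different prefactors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from scipy import optimize

from .exceptions import DataError, FitError
from .sas_io import Curve

__all__ = [
    "PeakModel",
    "Background",
    "OrderParameters",
    "profile_eval",
    "fit_peaks",
    "order_parameters",
    "ORDER_CONSTANTS",
]

#: Prefactors of the order-parameter relations; every entry may be overridden.
ORDER_CONSTANTS = {
    "scherrer_K": 1.0,       # L = 2 pi K / fwhm
    "rm_factor": 0.5,        # R_m = rm_factor * L
    "delta_norm": 1.0,       # Delta/d = (1/pi) sqrt(fwhm d / 2) / delta_norm
}

_SHAPES = ("gaussian", "lorentzian", "pseudo_voigt")


@dataclass
class PeakModel:
    """One Bragg peak: position, width, integrated area, profile shape."""

    s0: float
    fwhm: float
    area: float
    shape: str = "gaussian"
    eta: float = 0.0        # Lorentzian fraction; fixed 0/1 unless pseudo_voigt

    def __post_init__(self):
        if self.shape not in _SHAPES:
            raise DataError(f"unknown peak shape {self.shape!r}")
        if self.shape == "gaussian":
            self.eta = 0.0
        elif self.shape == "lorentzian":
            self.eta = 1.0
        if self.fwhm <= 0 or self.area <= 0:
            raise DataError("fwhm and area must be positive")
        if not 0.0 <= self.eta <= 1.0:
            raise DataError("eta must lie in [0, 1]")


@dataclass
class Background:
    """Linear background I_bg(s) = c0 + c1 s."""

    c0: float = 0.0
    c1: float = 0.0


@dataclass
class OrderParameters:
    d: float
    L: float
    Rm: float
    delta_over_d: float
    formulas: dict = None


def _gauss_unit(s, s0, fwhm):
    """Unit-area Gaussian with the given FWHM."""
    return (2.0 * math.sqrt(math.log(2.0) / math.pi) / fwhm
            * np.exp(-4.0 * math.log(2.0) * (s - s0) ** 2 / fwhm ** 2))


def _lorentz_unit(s, s0, fwhm):
    """Unit-area Lorentzian with the given FWHM."""
    return (fwhm / (2.0 * math.pi)) / ((s - s0) ** 2 + (fwhm / 2.0) ** 2)


def profile_eval(model: PeakModel, s) -> np.ndarray:
    """Evaluate the peak profile on the grid.

    pV(s) = area * [eta L(s) + (1 - eta) G(s)] with G, L unit-area
    profiles sharing s0 and fwhm; eta = 0 is a pure Gaussian, eta = 1 a
    pure Lorentzian.
    """
    s = np.asarray(s, dtype=float)
    g = _gauss_unit(s, model.s0, model.fwhm) if model.eta < 1.0 else 0.0
    l = _lorentz_unit(s, model.s0, model.fwhm) if model.eta > 0.0 else 0.0
    return model.area * (model.eta * l + (1.0 - model.eta) * g)


def _pack(peaks: Sequence[PeakModel], bg: Background, fit_eta: bool):
    theta = []
    for p in peaks:
        theta += [p.s0, p.fwhm, p.area]
        if fit_eta and p.shape == "pseudo_voigt":
            theta.append(p.eta)
    theta += [bg.c0, bg.c1]
    return np.array(theta, dtype=float)


def _unpack(theta, peaks: Sequence[PeakModel], fit_eta: bool):
    out, j = [], 0
    for p in peaks:
        s0, fwhm, area = theta[j:j + 3]
        j += 3
        eta = p.eta
        if fit_eta and p.shape == "pseudo_voigt":
            eta = theta[j]
            j += 1
        out.append(replace(p, s0=s0, fwhm=fwhm, area=area, eta=eta))
    return out, Background(c0=float(theta[j]), c1=float(theta[j + 1]))


def fit_peaks(curve: Curve, initial: Sequence[PeakModel],
              background: Background = None, fix_eta: bool = False,
              max_nfev: int = 5000):
    """Simultaneous weighted fit of all peaks plus the linear background.

    Bounds keep every fwhm above the grid step and eta inside [0, 1];
    peak positions are confined to the measured grid. Returns the refined
    models sorted by position, the background, and the reduced chi-square.
    Raises :class:`FitError` with the last iterate attached when the
    optimiser fails to converge.
    """
    if not initial:
        raise DataError("need at least one initial peak")
    for p in initial:
        if not (curve.s[0] <= p.s0 <= curve.s[-1]):
            raise DataError(f"initial peak position {p.s0} outside the grid")
    if background is None:
        background = Background()
    fit_eta = not fix_eta

    theta0 = _pack(initial, background, fit_eta)
    if len(theta0) >= len(curve):
        raise DataError("more free parameters than data points")

    use = curve.has_sigma
    w = np.where(use, 1.0 / np.where(use, curve.sigma, 1.0), 0.0)
    if not np.any(w > 0):
        w = np.ones_like(curve.I)

    step = float(np.min(np.diff(curve.s)))
    lo, hi = [], []
    for p in initial:
        lo += [curve.s[0], step, 1e-300]
        hi += [curve.s[-1], np.inf, np.inf]
        if fit_eta and p.shape == "pseudo_voigt":
            lo.append(0.0)
            hi.append(1.0)
    lo += [-np.inf, -np.inf]
    hi += [np.inf, np.inf]
    theta0 = np.clip(theta0, lo, hi)

    def residuals(theta):
        peaks, bg = _unpack(theta, initial, fit_eta)
        model = bg.c0 + bg.c1 * curve.s
        for p in peaks:
            model = model + profile_eval(p, curve.s)
        return w * (model - curve.I)

    sol = optimize.least_squares(residuals, theta0, bounds=(lo, hi),
                                 max_nfev=max_nfev)
    if not sol.success:
        raise FitError("peak fit did not converge", last_iterate=sol.x)
    peaks, bg = _unpack(sol.x, initial, fit_eta)
    order = np.argsort([p.s0 for p in peaks])
    peaks = [peaks[i] for i in order]
    dof = max(np.count_nonzero(w > 0) - len(sol.x), 1)
    chi2 = float(np.sum(residuals(sol.x) ** 2) / dof)
    return peaks, bg, chi2


def order_parameters(model: PeakModel,
                     constants: Optional[dict] = None) -> OrderParameters:
    """Structural order parameters derived from one fitted peak.

    d = 2 pi / s0 (repeat distance); L = 2 pi K / fwhm (coherently ordered
    dimension, diverging as the peak sharpens); Delta/d =
    (1/pi) sqrt(fwhm d / 2) / delta_norm (relative paracrystalline
    next-neighbour disorder); R_m = rm_factor * L (interaction radius).
    The formulas used are echoed in ``formulas`` so reports are
    self-describing.
    """
    if model.s0 <= 0:
        raise DataError("order parameters need a positive peak position")
    c = dict(ORDER_CONSTANTS)
    if constants:
        c.update(constants)
    d = 2.0 * math.pi / model.s0
    L = 2.0 * math.pi * c["scherrer_K"] / model.fwhm
    delta_over_d = (1.0 / math.pi) * math.sqrt(model.fwhm * d / 2.0) / c["delta_norm"]
    Rm = c["rm_factor"] * L
    return OrderParameters(
        d=d, L=L, Rm=Rm, delta_over_d=delta_over_d,
        formulas={
            "d": "2*pi/s0",
            "L": f"2*pi*K/fwhm (K={c['scherrer_K']})",
            "Rm": f"{c['rm_factor']}*L",
            "delta_over_d": f"(1/pi)*sqrt(fwhm*d/2)/{c['delta_norm']}",
        })
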