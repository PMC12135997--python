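"""Primary structural parameters of a scattering curve: Guinier and Porod.

At low momentum transfer a compact particle obeys the Guinier law
``I(s) = I(0) exp(-s^2 Rg^2 / 3)``, so a weighted linear fit of ``ln I``
on ``s^2`` gives the radius of gyration Rg and the forward scattering
I(0).  The Porod invariant ``Q = int s^2 I(s) ds`` combined with I(0)
yields the (excluded) Porod volume ``Vp = 2 pi^2 I(0) / Q``, from which a
molecular-weight estimate follows via the empirical nm^3-per-kDa divisor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .exceptions import DataError
from .sas_io import Curve

__all__ = [
    "GuinierResult",
    "PorodResult",
    "guinier_fit",
    "auto_guinier_range",
    "porod",
]

#: Conventional upper bound of s*Rg for the Guinier range of globular particles.
DEFAULT_SRG_LIMIT = 1.3
#: Default Porod-volume-to-mass divisor: Vp [nm^3] / 1.6 ~ MW [kDa].
VP_PER_KDA = 1.6
#: Minimum number of points in a Guinier fit.
MIN_GUINIER_POINTS = 5


@dataclass
class GuinierResult:
    """Guinier fit outcome.

    ``ok`` is False when no Guinier region exists (non-negative slope);
    then Rg/I0 are NaN but the object is still returned so callers can
    report the failure without exception handling.
    """

    Rg: float
    I0: float
    fit_range: tuple
    sRg_max: float
    sd_Rg: float
    sd_I0: float
    r_xy: float
    ok: bool = True


@dataclass
class PorodResult:
    Q: float
    Vp: float
    MW: float
    tail_constant: Optional[float] = None


def _weighted_linfit(x: np.ndarray, y: np.ndarray, w: np.ndarray):
    """Weighted least squares y = a + b x; returns a, b, sd_a, sd_b, r_xy."""
    W = w.sum()
    xb = (w * x).sum() / W
    yb = (w * y).sum() / W
    sxx = (w * (x - xb) ** 2).sum()
    sxy = (w * (x - xb) * (y - yb)).sum()
    syy = (w * (y - yb) ** 2).sum()
    if sxx <= 0:
        raise DataError("degenerate abscissa in linear fit")
    b = sxy / sxx
    a = yb - b * xb
    # parameter variances from the weight matrix (sigma known)
    var_b = 1.0 / sxx
    var_a = 1.0 / W + xb ** 2 / sxx
    r_xy = sxy / math.sqrt(sxx * syy) if syy > 0 else 0.0
    return a, b, math.sqrt(var_a), math.sqrt(var_b), r_xy


def guinier_fit(curve: Curve, fit_range: Optional[tuple] = None) -> GuinierResult:
    """Weighted Guinier fit ``ln I = ln I0 - s^2 Rg^2 / 3``.

    ``fit_range`` is an inclusive index pair ``(first, last)``; default is
    all points. Only points with I > 0 enter the fit (ln requires it);
    weights follow from error propagation ``sigma_lnI = sigma_I / I``.
    Points lacking uncertainties are weighted uniformly. A non-negative
    slope is reported as a flagged non-determinable result, not an error.
    """
    if fit_range is None:
        lo, hi = 0, len(curve) - 1
    else:
        lo, hi = int(fit_range[0]), int(fit_range[1])
        if lo < 0 or hi >= len(curve) or hi < lo:
            raise DataError("fit range outside the curve")

    s = curve.s[lo:hi + 1]
    I = curve.I[lo:hi + 1]
    sig = curve.sigma[lo:hi + 1]
    pos = I > 0
    if np.count_nonzero(pos) < MIN_GUINIER_POINTS:
        raise DataError(
            f"Guinier fit needs >= {MIN_GUINIER_POINTS} points with I > 0")
    s, I, sig = s[pos], I[pos], sig[pos]

    x = s ** 2
    y = np.log(I)
    good_sig = np.isfinite(sig) & (sig > 0)
    if np.all(good_sig):
        w = (I / sig) ** 2
    else:
        w = np.ones_like(I)

    a, b, sd_a, sd_b, r_xy = _weighted_linfit(x, y, w)
    if b >= 0:
        return GuinierResult(math.nan, math.nan, (lo, hi), math.nan,
                             math.nan, math.nan, r_xy, ok=False)
    Rg = math.sqrt(-3.0 * b)
    I0 = math.exp(a)
    sd_Rg = 3.0 * sd_b / (2.0 * Rg)
    sd_I0 = I0 * sd_a
    return GuinierResult(Rg, I0, (lo, hi), float(s[-1] * Rg),
                         sd_Rg, sd_I0, r_xy, ok=True)


def auto_guinier_range(curve: Curve, sRg_limit: float = DEFAULT_SRG_LIMIT,
                       sRg_min: float = 0.0, max_rounds: int = 50) -> tuple:
    """Choose a Guinier fit range automatically.

    Deterministic fixed-point iteration: fit the first 10 positive-I
    points, then set the range to all points with
    ``sRg_min <= s*Rg <= sRg_limit`` using the current Rg, refit, and
    repeat until the range stops changing (at most ``max_rounds``).
    Raises :class:`DataError` for very short curves and returns a flagged
    non-determinable result via ``guinier_fit`` semantics if no slope is
    negative.
    """
    pos_idx = np.flatnonzero(curve.I > 0)
    if len(pos_idx) < 10:
        raise DataError("automatic Guinier range needs >= 10 points with I > 0")

    lo, hi = int(pos_idx[0]), int(pos_idx[min(9, len(pos_idx) - 1)])
    prev = None
    for _ in range(max_rounds):
        res = guinier_fit(curve, (lo, hi))
        if not res.ok:
            return (lo, hi)
        sRg = curve.s * res.Rg
        admissible = np.flatnonzero(
            (sRg >= sRg_min) & (sRg <= sRg_limit) & (curve.I > 0))
        if len(admissible) < MIN_GUINIER_POINTS:
            return (lo, hi)
        new = (int(admissible[0]), int(admissible[-1]))
        if new == (lo, hi) or new == prev:
            lo, hi = new
            break
        prev = (lo, hi)
        lo, hi = new
    return (lo, hi)


def _porod_tail_constant(curve: Curve, window: int = 20) -> float:
    """Porod constant K from the flattest stretch of s^4 I(s) in the last decade.

    Scans sliding windows over the points with s >= s_max/10 and takes the
    mean of s^4 I over the window with the lowest relative spread
    (std/mean); oscillating form factors average out over such a window.
    """
    s_max = curve.s[-1]
    tail = np.flatnonzero(curve.s >= s_max / 10.0)
    if len(tail) < window:
        tail = np.arange(max(len(curve) - window, 0), len(curve))
    y = curve.s[tail] ** 4 * curve.I[tail]
    best, K = None, float(np.mean(y))
    for start in range(0, len(y) - window + 1):
        seg = y[start:start + window]
        m = seg.mean()
        if m <= 0:
            continue
        spread = seg.std() / m
        if best is None or spread < best:
            best, K = spread, float(m)
    return K


def porod(curve: Curve, I0: float, extrapolate: bool = True,
          vp_per_kda: float = VP_PER_KDA) -> PorodResult:
    """Porod invariant, volume and molecular-weight estimate.

    ``Q`` is the trapezoidal integral of ``s^2 I(s)`` over the measured
    range; with ``extrapolate=True`` the high-angle tail beyond s_max is
    added analytically assuming Porod behaviour ``I ~ K / s^4`` (the tail
    integral is K / s_max). ``Vp = 2 pi^2 I0 / Q``; MW = Vp / vp_per_kda
    assumes Vp in nm^3 and MW in kDa. Vp is invariant under rescaling the
    intensities (I0 and Q scale together).
    """
    if I0 <= 0:
        raise DataError("Porod analysis needs I(0) > 0")
    if curve.s[-1] <= 0 or curve.s[-1] / max(curve.s[0], 1e-300) < 10:
        raise DataError("Porod analysis needs the curve to span at least a decade in s")

    Q = float(np.trapezoid(curve.s ** 2 * curve.I, curve.s))
    K = None
    if extrapolate:
        K = _porod_tail_constant(curve)
        Q += K / curve.s[-1]
    if Q <= 0:
        raise DataError("non-positive Porod invariant")
    Vp = 2.0 * math.pi ** 2 * I0 / Q
    return PorodResult(Q=Q, Vp=Vp, MW=Vp / vp_per_kda, tail_constant=K)
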