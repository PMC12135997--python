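"""Synthetic SEC-SAXS series, peak patterns and mixture curves with known truth.

Every downstream module (chromatogram, EFA, peak fitting, mixture fitting)
is tested against data produced here, so the generator returns the ground
truth alongside the data: the elution (concentration) matrix C, the pure
component curves S, the peak parameters, etc.

The elution model is a Gaussian profile per component in frame index —
real SEC peaks are skewed, but a Gaussian keeps the ground truth analytic;
an exponentially modified Gaussian tail (``skew_tau``) is available where
asymmetry matters. Noise emulates photon counting: sigma_ij =
noise_scale * sqrt(max(D_ij, floor)), so weaker frames are relatively
noisier, and the floor keeps weights finite where D is ~0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .exceptions import DataError
from .sas_io import Curve, FrameSeries
from . import mixtures
from .mixtures import ComponentModel

__all__ = [
    "SyntheticSECSpec",
    "make_sec_series",
    "make_peak_pattern",
    "default_s_grid",
]


def default_s_grid(n: int = 100, s_max: float = 3.0) -> np.ndarray:
    """Default momentum-transfer grid in nm^-1, starting just above zero."""
    return np.linspace(s_max / n, s_max, n)


@dataclass
class SyntheticSECSpec:
    """Recipe for a synthetic SEC-SAXS series.

    Components elute first-in/first-out: ``elution_centers`` must be
    strictly increasing. ``component_models`` are mixture-module component
    specs whose form factors become the pure component curves; by default
    spheres of 3, 5, 7 ... nm radius.
    """

    n_components: int = 2
    elution_centers: Sequence[float] = (45.0, 56.0)
    elution_widths: Sequence[float] = (8.0, 8.0)
    amplitudes: Sequence[float] = (1.0, 0.8)
    component_models: Optional[Sequence[ComponentModel]] = None
    s_grid: np.ndarray = field(default_factory=default_s_grid)
    n_frames: int = 100
    noise_model: str = "gaussian"      # "gaussian" or "none"
    noise_scale: float = 0.0
    noise_floor: float = 1e-6
    buffer_level: float = 0.0
    skew_tau: float = 0.0              # EMG tail constant in frames; 0 = pure Gaussian
    seed: int = 0

    def validate(self) -> None:
        k = self.n_components
        if k < 1:
            raise DataError("need at least one component")
        if not (len(self.elution_centers) == len(self.elution_widths)
                == len(self.amplitudes) == k):
            raise DataError("centers, widths and amplitudes must have one entry per component")
        if np.any(np.diff(self.elution_centers) <= 0):
            raise DataError("elution centers must be strictly increasing (FIFO elution)")
        if min(self.elution_widths) <= 0 or min(self.amplitudes) <= 0:
            raise DataError("elution widths and amplitudes must be positive")
        if self.noise_model not in ("gaussian", "none"):
            raise DataError(f"unknown noise model {self.noise_model!r}")


def _default_components(k: int) -> list:
    return [ComponentModel("sphere", {"R": 3.0 + 2.0 * i}) for i in range(k)]


def _elution_profile(frames: np.ndarray, center: float, width: float,
                     tau: float) -> np.ndarray:
    gauss = np.exp(-0.5 * ((frames - center) / width) ** 2)
    if tau <= 0:
        return gauss
    # exponentially modified Gaussian (tail toward later frames)
    from scipy import special
    lam = 1.0 / tau
    arg = lam / 2.0 * (lam * width ** 2 + 2.0 * (center - frames))
    z = (center + lam * width ** 2 - frames) / (math.sqrt(2.0) * width)
    emg = lam / 2.0 * np.exp(np.clip(arg, -700, 700)) * special.erfc(z)
    return emg / emg.max()


def make_sec_series(spec: SyntheticSECSpec):
    """Build a frame series D = C S^T (+ noise) with known C and S.

    Returns ``(series, true_C, true_S)`` where ``true_C`` has one column
    per component (Gaussian elution profiles scaled by the amplitudes) and
    ``true_S`` is the list of pure component curves on the series grid.
    Output is reproducible bit-for-bit for a fixed seed.
    """
    spec.validate()
    comps = (list(spec.component_models) if spec.component_models is not None
             else _default_components(spec.n_components))
    if len(comps) != spec.n_components:
        raise DataError("one component model per component required")

    s = np.asarray(spec.s_grid, dtype=float)
    frames_idx = np.arange(spec.n_frames, dtype=float)

    C = np.column_stack([
        amp * _elution_profile(frames_idx, c, w, spec.skew_tau)
        for c, w, amp in zip(spec.elution_centers, spec.elution_widths,
                             spec.amplitudes)
    ])
    S = np.vstack([mixtures.polydisperse(c, s) for c in comps])
    # normalise component curves to I(0)~1 so amplitudes set peak heights
    S = S / S.max(axis=1, keepdims=True)

    D = C @ S + spec.buffer_level

    if spec.noise_model == "gaussian" and spec.noise_scale > 0:
        rng = np.random.default_rng(spec.seed)
        sigma = spec.noise_scale * np.sqrt(np.maximum(D, spec.noise_floor))
        D = D + rng.standard_normal(D.shape) * sigma
    else:
        sigma = np.full_like(D, spec.noise_floor)

    series = FrameSeries(s, D, sigma)
    true_S = [Curve(s.copy(), S[i].copy(), np.full_like(s, np.nan),
                    label=f"component_{i}") for i in range(len(comps))]
    return series, C, true_S


def make_peak_pattern(peaks, background=(0.0, 0.0), s_grid=None,
                      noise: float = 0.0, seed: int = 0) -> Curve:
    """Sum of Bragg-peak profiles plus a linear background, optionally noisy.

    ``peaks`` is a list of ``(s0, fwhm, area, shape, eta)`` tuples using the
    peak-analysis profile definitions; ``background`` is ``(c0, c1)`` for
    ``c0 + c1 s``. Gaussian noise of absolute scale ``noise`` (same units
    as I) is added when requested; sigma is set accordingly so weighted
    fits are correctly calibrated.
    """
    from .peak_analysis import PeakModel, profile_eval

    if s_grid is None:
        s_grid = np.linspace(0.2, 3.0, 400)
    s = np.asarray(s_grid, dtype=float)
    c0, c1 = background
    I = c0 + c1 * s
    for (s0, fwhm, area, shape, eta) in peaks:
        if not (s[0] <= s0 <= s[-1]):
            raise DataError(f"peak position {s0} outside the grid")
        model = PeakModel(s0=s0, fwhm=fwhm, area=area, shape=shape, eta=eta)
        I = I + profile_eval(model, s)
    if noise > 0:
        rng = np.random.default_rng(seed)
        I = I + rng.standard_normal(len(s)) * noise
        sigma = np.full_like(s, noise)
    else:
        sigma = np.full_like(s, np.nan)
    return Curve(s, I, sigma, label="synthetic_peaks")
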