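"""SEC-SAXS chromatogram handling: trace, peak and buffer detection, subtraction.

The chromatogram ("trace") is the mean scattering intensity per frame over
a chosen s window, plotted against elution frame. Sample peaks are found
on a smoothed trace by prominence; buffer regions are suggested as the
most stable (minimum-variance) stretch of frames outside every peak.
Multiple independent named selections can then be subtracted, propagating
uncertainties through the frame averages.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import signal

from .exceptions import DataError, DetectionError
from .sas_io import Curve, FrameSeries

__all__ = [
    "Trace",
    "Selection",
    "compute_trace",
    "find_peaks",
    "suggest_buffer",
    "subtract",
    "screen_frames",
]


@dataclass
class Trace:
    """Mean intensity per frame over the window ``s_window`` = (s_lo, s_hi)."""

    frame_ids: np.ndarray
    values: np.ndarray
    s_window: tuple

    def __post_init__(self):
        self.frame_ids = np.asarray(self.frame_ids, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.frame_ids) != len(self.values):
            raise DataError("trace frame_ids and values must align")


@dataclass
class Selection:
    """A named pair of sample and buffer frame-id ranges for one subtraction."""

    name: str
    sample_frames: Sequence[int]
    buffer_frames: Sequence[int]

    def validate(self, series: FrameSeries) -> None:
        sample = set(int(f) for f in self.sample_frames)
        buffer = set(int(f) for f in self.buffer_frames)
        if not sample or not buffer:
            raise DataError("sample and buffer selections must be non-empty")
        if sample & buffer:
            raise DataError("sample and buffer selections must be disjoint")
        known = set(int(f) for f in series.frame_ids)
        missing = (sample | buffer) - known
        if missing:
            raise DataError(f"selection references unknown frame ids {sorted(missing)}")


def compute_trace(series: FrameSeries, s_window: Optional[tuple] = None) -> Trace:
    """Mean intensity of every frame over ``s_window`` (default: full grid).

    The mean (not the sum) makes the trace independent of grid density.
    """
    if s_window is None:
        mask = np.ones(len(series.s), dtype=bool)
        s_window = (float(series.s[0]), float(series.s[-1]))
    else:
        lo, hi = s_window
        mask = (series.s >= lo) & (series.s <= hi)
        if np.count_nonzero(mask) < 2:
            raise DataError("s window must intersect the grid in at least 2 points")
    values = series.frames[:, mask].mean(axis=1)
    return Trace(series.frame_ids.copy(), values, tuple(s_window))


def _smooth(values: np.ndarray, width: int) -> np.ndarray:
    """Centred moving average with edge-shrinking window."""
    if width <= 1:
        return values.astype(float)
    kernel = np.ones(width)
    num = np.convolve(values, kernel, mode="same")
    den = np.convolve(np.ones_like(values), kernel, mode="same")
    return num / den


def find_peaks(trace: Trace, min_prominence_frac: float = 0.1,
               min_width: int = 3, smooth_width: int = 5):
    """Detect elution peaks on the smoothed trace.

    A peak is a local maximum whose prominence is at least
    ``min_prominence_frac`` of the full trace span (max - min) and whose
    width is at least ``min_width`` frames. Returns
    ``[(apex_frame, left_base, right_base), ...]`` in elution order, with
    bases at the points where the trace has descended by 90% of the
    prominence (i.e. 10% of the prominence above the base level).
    Invariant under adding a constant to the trace.
    """
    m = len(trace.values)
    if m < 2 * min_width:
        raise DataError("trace too short for the requested minimum peak width")
    smoothed = _smooth(trace.values, smooth_width)
    span = smoothed.max() - smoothed.min()
    if span <= 0:
        return []
    idx, props = signal.find_peaks(smoothed,
                                   prominence=min_prominence_frac * span,
                                   width=min_width)
    if len(idx) == 0:
        return []
    widths = signal.peak_widths(smoothed, idx, rel_height=0.9)
    out = []
    for apex, lo, hi in zip(idx, widths[2], widths[3]):
        out.append((int(trace.frame_ids[apex]),
                    int(trace.frame_ids[int(np.floor(lo))]),
                    int(trace.frame_ids[int(np.ceil(hi))])))
    return sorted(out)


def suggest_buffer(trace: Trace, peaks, window_len: int) -> np.ndarray:
    """Suggest the most stable buffer region outside all peaks.

    Scans every contiguous window of ``window_len`` frames that avoids all
    peak base intervals and returns the one with minimal variance of the
    trace values; ties go to the earliest window. Raises
    :class:`DetectionError` if no window fits.
    """
    m = len(trace.values)
    if window_len < 1 or window_len > m:
        raise DataError("window length must be between 1 and the trace length")
    blocked = np.zeros(m, dtype=bool)
    id_to_pos = {int(f): j for j, f in enumerate(trace.frame_ids)}
    for (_apex, lo, hi) in peaks:
        blocked[id_to_pos[lo]:id_to_pos[hi] + 1] = True

    best_var, best_start = None, None
    for start in range(0, m - window_len + 1):
        if blocked[start:start + window_len].any():
            continue
        var = float(np.var(trace.values[start:start + window_len]))
        if best_var is None or var < best_var:
            best_var, best_start = var, start
    if best_start is None:
        raise DetectionError("no contiguous buffer window outside the peaks")
    return trace.frame_ids[best_start:best_start + window_len].copy()


def _average_frames(series: FrameSeries, frame_ids) -> tuple:
    pos = [series.index_of(int(f)) for f in frame_ids]
    I = series.frames[pos].mean(axis=0)
    sig = series.sigma[pos]
    n = len(pos)
    # sigma of the mean: sqrt(sum sigma^2) / N
    sigma = np.sqrt(np.nansum(sig ** 2, axis=0)) / n
    sigma = np.where(np.all(np.isnan(sig), axis=0), np.nan, sigma)
    return I, sigma


def subtract(series: FrameSeries, sel: Selection) -> Curve:
    """Average sample and buffer frames and return the subtracted curve.

    I = <sample> - <buffer>, with uncertainties added in quadrature:
    sigma^2 = sigma_sample^2 + sigma_buffer^2, each average carrying
    sigma_mean = sqrt(sum sigma_i^2) / N. Subtraction is linear in the
    frame matrix.
    """
    sel.validate(series)
    A, sig_A = _average_frames(series, sel.sample_frames)
    B, sig_B = _average_frames(series, sel.buffer_frames)
    I = A - B
    sigma = np.sqrt(sig_A ** 2 + sig_B ** 2)
    return Curve(series.s.copy(), I, sigma, label=sel.name or "subtracted")


def screen_frames(series: FrameSeries, frame_ids, chi2_max: float = 3.0):
    """Discard frames inconsistent with the running average.

    For each candidate frame the reduced chi-square against the mean of
    the frames accepted so far is computed from the per-point
    uncertainties; frames exceeding ``chi2_max`` are dropped. This is a
    deliberately simple consistency screen for outlier rejection before
    averaging (bubbles, radiation damage), not a full pairwise similarity
    test. Returns the accepted frame ids in input order.
    """
    ids = [int(f) for f in frame_ids]
    if not ids:
        raise DataError("no frames to screen")
    accepted = [ids[0]]
    for f in ids[1:]:
        pos = [series.index_of(g) for g in accepted]
        ref = series.frames[pos].mean(axis=0)
        j = series.index_of(f)
        sig = series.sigma[j]
        ok = np.isfinite(sig) & (sig > 0)
        if not np.any(ok):
            accepted.append(f)
            continue
        chi2 = float(np.mean(((series.frames[j][ok] - ref[ok]) / sig[ok]) ** 2))
        if chi2 <= chi2_max:
            accepted.append(f)
    return accepted
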