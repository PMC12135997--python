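"""Read and write 1D small-angle scattering curves and SEC-SAXS frame series.

The on-disk dialect is the ASCII ``.dat`` convention used across the SAS
field: any leading non-numeric lines are free-text header, the first line
whose whitespace-separated tokens are mostly numeric starts the data block,
and each data row carries ``s  I  sigma`` (a third column is optional; rows
without one have their uncertainty flagged missing and are excluded from
weighted operations downstream).

Units of the momentum transfer ``s`` (nm^-1 vs. A^-1) are carried as
metadata and never converted silently: ``s = 4 pi sin(theta) / lambda`` so
real-space repeats follow ``d = 2 pi / s``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import DataError, FormatError, GridError

__all__ = [
    "Curve",
    "FrameSeries",
    "read_dat",
    "write_dat",
    "load_series",
    "export_csv",
]

#: Relative tolerance within which two frame grids are considered identical.
GRID_RTOL = 1e-9


@dataclass
class Curve:
    """One 1D scattering pattern: grid ``s``, intensities ``I``, uncertainties ``sigma``.

    ``sigma`` entries are NaN where the uncertainty is missing; such points
    are excluded from weighted fits. ``s`` must be strictly increasing and
    non-negative.
    """

    s: np.ndarray
    I: np.ndarray
    sigma: np.ndarray
    label: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.s = np.asarray(self.s, dtype=float)
        self.I = np.asarray(self.I, dtype=float)
        if self.sigma is None:
            self.sigma = np.full_like(self.I, np.nan)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if not (len(self.s) == len(self.I) == len(self.sigma)):
            raise DataError("s, I and sigma must have equal length")
        if len(self.s) and np.any(self.s < 0):
            raise DataError("momentum transfer s must be non-negative")
        if len(self.s) > 1 and np.any(np.diff(self.s) <= 0):
            raise DataError("momentum transfer grid must be strictly increasing")

    def __len__(self) -> int:
        return len(self.s)

    @property
    def has_sigma(self) -> np.ndarray:
        """Boolean mask of points with a finite, positive uncertainty."""
        return np.isfinite(self.sigma) & (self.sigma > 0)

    def copy(self) -> "Curve":
        return Curve(self.s.copy(), self.I.copy(), self.sigma.copy(),
                     label=self.label, metadata=dict(self.metadata))


@dataclass
class FrameSeries:
    """Ordered stack of curves on one common ``s`` grid (the SEC-SAXS data matrix).

    ``frames`` is the matrix ``D`` of shape (m frames, n s-points); ``sigma``
    holds the matching uncertainties. ``frame_ids`` are ordered integer
    labels, by default ``0..m-1``.
    """

    s: np.ndarray
    frames: np.ndarray
    sigma: np.ndarray
    frame_ids: np.ndarray = None

    def __post_init__(self):
        self.s = np.asarray(self.s, dtype=float)
        self.frames = np.atleast_2d(np.asarray(self.frames, dtype=float))
        if self.sigma is None:
            self.sigma = np.full_like(self.frames, np.nan)
        self.sigma = np.atleast_2d(np.asarray(self.sigma, dtype=float))
        if self.frame_ids is None:
            self.frame_ids = np.arange(self.frames.shape[0])
        self.frame_ids = np.asarray(self.frame_ids, dtype=int)
        m, n = self.frames.shape
        if m < 1 or n < 2:
            raise DataError("a frame series needs m >= 1 frames and n >= 2 points")
        if self.sigma.shape != self.frames.shape:
            raise DataError("sigma matrix must match the frame matrix shape")
        if len(self.s) != n:
            raise DataError("s grid length must match the number of columns of D")
        if len(self.frame_ids) != m:
            raise DataError("frame_ids length must match the number of frames")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def curve(self, index: int, label: str = "") -> Curve:
        """Extract frame ``index`` (positional) as a Curve."""
        return Curve(self.s.copy(), self.frames[index].copy(),
                     self.sigma[index].copy(), label=label)

    def index_of(self, frame_id: int) -> int:
        hits = np.flatnonzero(self.frame_ids == frame_id)
        if len(hits) == 0:
            raise DataError(f"frame id {frame_id} not present in series")
        return int(hits[0])


def _is_numeric(token: str) -> bool:
    try:
        float(token)
    except ValueError:
        return False
    return True


def _numeric_majority(tokens: Sequence[str]) -> bool:
    if not tokens:
        return False
    numeric = sum(_is_numeric(t) for t in tokens)
    return numeric > len(tokens) / 2


def read_dat(path) -> Curve:
    """Read an ASCII ``.dat`` curve.

    Leading non-numeric lines are preserved in ``metadata['header']``.
    Rows with only two columns get ``sigma = NaN`` (missing). Raises
    :class:`FormatError` naming the first offending line if no data row
    parses, and :class:`OSError` for unreadable files.
    """
    path = Path(path)
    text = path.read_text()

    header: list[str] = []
    rows: list[tuple[float, float, float]] = []
    first_bad: int | None = None
    in_data = False
    for lineno, line in enumerate(text.splitlines(), start=1):
        tokens = line.split()
        if not in_data:
            if _numeric_majority(tokens):
                in_data = True
            else:
                header.append(line)
                continue
        if not tokens:
            continue
        try:
            s = float(tokens[0])
            i = float(tokens[1])
            sig = float(tokens[2]) if len(tokens) >= 3 else math.nan
        except (ValueError, IndexError):
            if first_bad is None:
                first_bad = lineno
            continue
        rows.append((s, i, sig))

    if not rows:
        where = first_bad if first_bad is not None else 1
        raise FormatError(f"{path}: no parsable data rows (first failure at line {where})")

    arr = np.array(rows, dtype=float)
    label = header[0].strip() if header else path.stem
    return Curve(arr[:, 0], arr[:, 1], arr[:, 2], label=label,
                 metadata={"header": header, "path": str(path)})


def write_dat(curve: Curve, path) -> None:
    """Write a curve in the 3-column ``.dat`` dialect.

    Numbers are printed with 14 significant digits so a write/read
    round-trip reproduces ``(s, I, sigma)`` to better than 1e-12 relative.
    Curves whose uncertainties are all missing are written with two columns.
    """
    path = Path(path)
    header = curve.metadata.get("header")
    if not header:
        header = [curve.label or "saskit curve"]
    two_col = not np.any(np.isfinite(curve.sigma))
    lines = list(header)
    for j in range(len(curve)):
        if two_col:
            lines.append(f" {curve.s[j]:.14e} {curve.I[j]:.14e}")
        else:
            sig = curve.sigma[j]
            sig_txt = f"{sig:.14e}" if np.isfinite(sig) else "nan"
            lines.append(f" {curve.s[j]:.14e} {curve.I[j]:.14e} {sig_txt}")
    path.write_text("\n".join(lines) + "\n")


def _load_matrix_file(path: Path) -> FrameSeries:
    # Matrix dialect: first column s, remaining columns one intensity per frame.
    # No per-point uncertainties are carried by this format.
    data = np.loadtxt(path, ndmin=2)
    if data.shape[1] < 2:
        raise FormatError(f"{path}: matrix file needs an s column plus >= 1 frame column")
    s = data[:, 0]
    frames = data[:, 1:].T
    return FrameSeries(s, frames, None)


def load_series(paths) -> FrameSeries:
    """Load a SEC-SAXS series from ordered ``.dat`` files or one matrix file.

    All frames must share the same grid to within ``GRID_RTOL`` relative;
    the first frame's grid becomes the canonical grid so downstream code may
    rely on bit-equality. The frame order is the given file order.
    """
    if isinstance(paths, (str, Path)):
        p = Path(paths)
        if p.is_dir():
            paths = sorted(p.glob("*.dat"))
        else:
            return _load_matrix_file(p)
    paths = [Path(p) for p in paths]
    if not paths:
        raise DataError("load_series needs at least one frame")

    curves = [read_dat(p) for p in paths]
    s0 = curves[0].s
    for p, c in zip(paths[1:], curves[1:]):
        if len(c.s) != len(s0) or not np.allclose(c.s, s0, rtol=GRID_RTOL, atol=0.0):
            raise GridError(f"{p}: s grid differs from first frame's grid")
    frames = np.vstack([c.I for c in curves])
    sigma = np.vstack([c.sigma for c in curves])
    return FrameSeries(s0.copy(), frames, sigma)


def export_csv(curves: Sequence[Curve], path) -> None:
    """Export curves to one CSV with per-curve ``s/I/sigma`` column triplets.

    Shorter curves are padded with empty cells. The decimal separator is
    always '.', independent of locale.
    """
    curves = list(curves)
    if not curves:
        raise DataError("export_csv needs at least one curve")
    columns = {}
    for idx, c in enumerate(curves):
        tag = c.label or f"curve{idx}"
        columns[f"s_{tag}"] = pd.Series(c.s)
        columns[f"I_{tag}"] = pd.Series(c.I)
        columns[f"sigma_{tag}"] = pd.Series(c.sigma)
    pd.DataFrame(columns).to_csv(path, index=False)
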