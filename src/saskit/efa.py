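"""Evolving factor analysis (EFA) of SEC-SAXS series with overlapping peaks.

The frame matrix D (m frames x n angles) of a k-component elution is, in
the ideal case, the product C S^T of non-negative concentration profiles
C (m x k) and component scattering curves S (n x k).  EFA locates each
component's concentration window by tracking how the singular values of
the growing sub-matrices D[0:j] (forward) and D[j:m] (backward) evolve:
a new singular value rising above the noise floor marks a component
entering (forward) or still present (backward).  Within those windows a
rotation of the truncated SVD basis recovers C and S themselves.

The rotation is algebraic — each column of the k x k rotation matrix is
the null vector of the rows of U_k S_k outside that component's window —
followed by alternating least squares under non-negativity and the window
masks, which makes the solution robust to noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .exceptions import DataError, DecompositionError
from .sas_io import Curve, FrameSeries

__all__ = [
    "EFAResult",
    "efa_curves",
    "predict_windows",
    "rotate",
    "rank_estimate",
]

#: Default multiple of the noise level a singular value must exceed.
NOISE_FACTOR = 5.0
#: ALS convergence: relative change of the residual norm.
ALS_TOL = 1e-10
ALS_MAX_ITER = 1000


@dataclass
class EFAResult:
    """Outcome of an EFA decomposition.

    ``C`` is m x k (arbitrary scale, each column normalised to max 1),
    ``S`` the k component curves, ``windows`` the per-component frame
    windows in elution order, ``residual_norm`` the relative Frobenius
    reconstruction residual ||D - C S^T|| / ||D||.
    """

    k: int
    forward_sv: list
    backward_sv: list
    windows: list
    C: np.ndarray
    S: list
    residual_norm: float


def efa_curves(series: FrameSeries, k: int):
    """Forward and backward evolving singular values.

    ``forward_sv[j]`` holds the leading ``min(k+1, j+1)`` singular values
    of the first j+1 frames (j = 0..m-1); ``backward_sv[j]`` those of the
    frames j..m-1.  Columns are in descending order.  Reversing the frame
    order swaps the roles of the two families.
    """
    m, n = series.frames.shape
    if k >= m:
        raise DataError("component count k must be smaller than the number of frames")
    if k < 1 or n < k:
        raise DataError("need 1 <= k <= n")

    D = series.frames
    forward = []
    for j in range(1, m + 1):
        sv = np.linalg.svd(D[:j], compute_uv=False)
        forward.append(sv[:min(k + 1, j)])
    backward = []
    for j in range(m):
        sv = np.linalg.svd(D[j:], compute_uv=False)
        backward.append(sv[:min(k + 1, m - j)])
    return forward, backward


def _noise_level(forward_sv, backward_sv, k: int) -> float:
    """Noise floor: median of the (k+1)-th singular values where defined."""
    vals = [sv[k] for sv in forward_sv if len(sv) > k]
    vals += [sv[k] for sv in backward_sv if len(sv) > k]
    if not vals:
        raise DecompositionError(
            "cannot estimate the noise floor; too few frames for k+1 singular values")
    return float(np.median(vals))


def predict_windows(forward_sv, backward_sv, k: int,
                    noise_factor: float = NOISE_FACTOR):
    """Predict the concentration window of every component.

    Component i (0-based, elution order) enters at the first frame where
    the (i+1)-th forward singular value exceeds ``noise_factor`` times the
    noise floor, and leaves at the last frame where the (i+1)-th singular
    value counted in the backward direction (i.e. the (k-i)-th backward
    one) still exceeds it.  Windows are forced into first-in/first-out
    order.  Raises :class:`DecompositionError` when some threshold is
    never crossed, which indicates k is too large for the data.
    """
    m = len(forward_sv)
    noise = _noise_level(forward_sv, backward_sv, k)
    thr = noise_factor * noise

    starts, ends = [], []
    for i in range(k):
        fwd = np.array([sv[i] if len(sv) > i else 0.0 for sv in forward_sv])
        above = np.flatnonzero(fwd > thr)
        if len(above) == 0:
            raise DecompositionError(
                f"forward singular value {i + 1} never exceeds the noise "
                f"threshold; try a smaller k")
        starts.append(int(above[0]))
        # component i ends where backward SV (k-1-i) falls below threshold
        bwd = np.array([sv[k - 1 - i] if len(sv) > k - 1 - i else 0.0
                        for sv in backward_sv])
        above_b = np.flatnonzero(bwd > thr)
        if len(above_b) == 0:
            raise DecompositionError(
                f"backward singular value {k - i} never exceeds the noise "
                f"threshold; try a smaller k")
        ends.append(int(above_b[-1]))

    # enforce FIFO: starts and ends each non-decreasing, start <= end
    starts = list(np.maximum.accumulate(starts))
    ends = list(np.minimum.accumulate(ends[::-1])[::-1])
    windows = []
    for i in range(k):
        lo, hi = starts[i], max(ends[i], starts[i] + 1)
        hi = min(hi, m - 1)
        windows.append((lo, hi))
    return windows


def rank_estimate(series: FrameSeries, max_k: int = 10) -> np.ndarray:
    """Advisory singular-value scree of the full matrix (never auto-applied)."""
    sv = np.linalg.svd(series.frames, compute_uv=False)
    return sv[:max_k]


def _initial_rotation(M: np.ndarray, windows) -> np.ndarray:
    """Column i of R = null vector of the rows of M outside window i."""
    m, k = M.shape
    R = np.empty((k, k))
    for i, (lo, hi) in enumerate(windows):
        outside = np.ones(m, dtype=bool)
        outside[lo:hi + 1] = False
        A = M[outside]
        if A.shape[0] < k - 1:
            raise DecompositionError(
                "window covers nearly all frames; rotation underdetermined")
        # least-squares null vector: right singular vector of smallest SV
        _, _, Vt = np.linalg.svd(A, full_matrices=True)
        R[:, i] = Vt[-1]
        # orient so the in-window concentration is mostly positive
        if np.sum(M[lo:hi + 1] @ R[:, i]) < 0:
            R[:, i] = -R[:, i]
    if np.linalg.matrix_rank(R, tol=1e-10) < k:
        raise DecompositionError(
            "rotation matrix is singular (identical or nested windows?)")
    return R


def rotate(series: FrameSeries, k: int, windows) -> EFAResult:
    """Rotate the truncated SVD into concentrations and component curves.

    Steps: truncated rank-k SVD of D; algebraic window rotation for the
    initial C; alternating least squares refinement with non-negativity
    and the window masks on C (at most ``ALS_MAX_ITER`` iterations,
    stopping when the relative residual change falls below ``ALS_TOL``);
    finally S^T = pinv(C) D and per-column normalisation max(C[:, i]) = 1.
    """
    m, n = series.frames.shape
    if len(windows) != k:
        raise DataError("need exactly one window per component")
    windows = [(int(lo), int(hi)) for lo, hi in windows]
    for i, (lo, hi) in enumerate(windows):
        if not (0 <= lo <= hi < m):
            raise DataError(f"window {i} out of range")
    for i in range(1, k):
        if windows[i][0] < windows[i - 1][0] or windows[i][1] < windows[i - 1][1]:
            raise DataError("windows must be in first-in/first-out elution order")
    if len(set(windows)) < k:
        raise DecompositionError("identical windows cannot be rotated apart")

    D = series.frames
    norm_D = np.linalg.norm(D)
    U, sv, Vt = np.linalg.svd(D, full_matrices=False)
    M = U[:, :k] * sv[:k]          # m x k score matrix

    R = _initial_rotation(M, windows)
    C = M @ R

    mask = np.zeros((m, k), dtype=bool)
    for i, (lo, hi) in enumerate(windows):
        mask[lo:hi + 1, i] = True

    C = np.where(mask, np.clip(C, 0.0, None), 0.0)
    if np.all(C == 0):
        raise DecompositionError("rotation produced an all-zero concentration matrix")

    prev_res = np.inf
    S = None
    for _ in range(ALS_MAX_ITER):
        # S given C (unconstrained least squares)
        S, *_ = np.linalg.lstsq(C, D, rcond=None)
        # C given S, then project onto masks and non-negativity
        Ct, *_ = np.linalg.lstsq(S.T, D.T, rcond=None)
        C = np.where(mask, np.clip(Ct.T, 0.0, None), 0.0)
        res = np.linalg.norm(D - C @ S) / norm_D
        if abs(prev_res - res) <= ALS_TOL * max(res, 1e-300):
            prev_res = res
            break
        prev_res = res

    S, *_ = np.linalg.lstsq(C, D, rcond=None)
    scale = C.max(axis=0)
    if np.any(scale <= 0):
        raise DecompositionError("a component's concentration vanished during ALS")
    C = C / scale
    S = S * scale[:, None]
    residual = float(np.linalg.norm(D - C @ S) / norm_D)

    curves = [Curve(series.s.copy(), S[i], np.full(n, np.nan),
                    label=f"component_{i}") for i in range(k)]
    fwd, bwd = efa_curves(series, k)
    return EFAResult(k=k, forward_sv=fwd, backward_sv=bwd, windows=windows,
                     C=C, S=curves, residual_norm=residual)
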