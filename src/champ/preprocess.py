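"""Flat-field correction and scan-trajectory estimation from raw frames.

Raw speckle-illuminated frames carry a smooth illumination envelope
(condenser vignetting) on top of the modulated signal; ``flatten_field``
removes it before reconstruction. ``estimate_shifts`` recovers the
raster trajectory by sub-pixel phase cross-correlation between frames,
so the solver never relies on nominal stage positions alone.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.registration import phase_cross_correlation

from .simulate import FrameStack

__all__ = ["ShiftTrajectory", "flatten_field", "estimate_shifts"]

log = logging.getLogger(__name__)


@dataclass
class ShiftTrajectory:
    """Estimated per-frame stage shifts, um, relative to a reference frame."""

    shifts: list[tuple[float, float]]  # (x, y) um
    reference_index: int = 0
    residual_to_nominal: np.ndarray | None = None  # um per frame
    flagged: list[int] | None = None  # frames that fell back to nominal

    def __post_init__(self) -> None:
        ref = self.shifts[self.reference_index]
        if abs(ref[0]) > 1e-9 or abs(ref[1]) > 1e-9:
            raise ValueError("shift at the reference index must be (0, 0)")

    def __len__(self) -> int:
        return len(self.shifts)


def _polynomial_envelope(mean_frame: np.ndarray, order: int = 2) -> np.ndarray:
    ny, nx = mean_frame.shape
    y = np.linspace(-1.0, 1.0, ny)
    x = np.linspace(-1.0, 1.0, nx)
    yy, xx = np.meshgrid(y, x, indexing="ij")
    cols = [
        (yy**i * xx**j).ravel()
        for i in range(order + 1)
        for j in range(order + 1 - i)
    ]
    basis = np.stack(cols, axis=1)
    coef, *_ = np.linalg.lstsq(basis, mean_frame.ravel(), rcond=None)
    return (basis @ coef).reshape(ny, nx)


def flatten_field(
    stack: FrameStack,
    method: str = "polynomial",
    smooth_px: float | None = None,
    epsilon: float = 1e-3,
) -> FrameStack:
    """Correct illumination non-uniformity across the stack.

    The illumination envelope is estimated from the log of the mean
    frame — fitted with a low-order 2D polynomial (``method="polynomial"``,
    the default: the fit is a linear projection, so the correction is
    idempotent) or heavily low-pass filtered (``method="mean-frame"``) —
    exponentiated, and divided out of every frame. The stack's global
    mean is preserved.

    Zero-valued pixels are floored at ``epsilon`` times the mean (a
    warning is logged) so the log and division stay finite.
    """
    frames = np.asarray(stack.frames, dtype=float)
    if method == "mean-frame" and len(frames) < 2:
        raise ValueError("mean-frame flattening needs at least two frames")
    mean_frame = frames.mean(axis=0)

    floor = epsilon * max(mean_frame.mean(), 1e-30)
    if np.any(mean_frame < floor):
        log.warning(
            "mean frame reaches zero; flooring %d pixels at %.3g before the "
            "envelope fit",
            int(np.sum(mean_frame < floor)),
            floor,
        )
    work = np.maximum(mean_frame, floor)
    if method == "mean-frame":
        if smooth_px is None:
            smooth_px = max(frames.shape[-1], frames.shape[-2]) / 8.0
        # smooth in the log domain: the envelope is multiplicative
        envelope = np.exp(gaussian_filter(np.log(work), smooth_px, mode="nearest"))
    elif method == "polynomial":
        # iterate the fit to its multiplicative fixed point so that a
        # second application of flatten_field is a no-op
        envelope = np.ones_like(work)
        for _ in range(3):
            envelope = envelope * np.maximum(
                _polynomial_envelope(work / envelope), floor
            )
    else:
        raise ValueError(f"unknown flattening method {method!r}")
    corrected = frames / envelope[None, :, :]
    corrected *= frames.mean() / corrected.mean()
    return replace(stack, frames=corrected)


def _window(shape: tuple[int, int]) -> np.ndarray:
    wy = np.hanning(shape[0])
    wx = np.hanning(shape[1])
    return wy[:, None] * wx[None, :]


def _peak_ratio(a: np.ndarray, b: np.ndarray, exclude: int = 5) -> float:
    """Dominant-to-secondary peak ratio of the phase correlogram."""
    fa, fb = np.fft.fft2(a), np.fft.fft2(b)
    cross = fa * np.conj(fb)
    mag = np.abs(cross)
    corr = np.abs(np.fft.ifft2(cross / np.maximum(mag, 1e-30)))
    peak_idx = np.unravel_index(np.argmax(corr), corr.shape)
    peak = corr[peak_idx]
    masked = corr.copy()
    ys = (np.arange(corr.shape[0]) - peak_idx[0] + corr.shape[0] // 2) % corr.shape[0] - corr.shape[0] // 2
    xs = (np.arange(corr.shape[1]) - peak_idx[1] + corr.shape[1] // 2) % corr.shape[1] - corr.shape[1] // 2
    near = (np.abs(ys)[:, None] <= exclude) & (np.abs(xs)[None, :] <= exclude)
    masked[near] = 0.0
    second = masked.max()
    return float(peak / max(second, 1e-30))


def estimate_shifts(
    stack: FrameStack,
    upsample_factor: int = 20,
    mode: str = "reference",
    moving: str = "specimen",
    subtract_mean: bool = False,
    window: bool = True,
    peak_ratio_threshold: float = 1.5,
) -> ShiftTrajectory:
    """Estimate the scan trajectory by sub-pixel phase cross-correlation.

    Parameters
    ----------
    stack:
        Raw (preferably flattened) frames.
    upsample_factor:
        Sub-pixel refinement; 20 resolves 0.05 camera pixel.
    mode:
        ``"reference"`` (default) correlates every frame against the
        reference frame directly; ``"chained"`` correlates successive
        frames and accumulates the drift. All-to-reference is the
        default because chaining accumulates the per-pair bias over the
        raster, while with a scan range far smaller than the field every
        frame overlaps the reference almost entirely.
    moving:
        What the correlation tracks. ``"specimen"``: frames are in the
        lab frame and the specimen translates by +s_j (real raw data).
        ``"pattern"``: frames are registered to the specimen and only
        the illumination pattern moves, by -s_j (the simulator's sample-
        frame convention); the measured displacement is negated.
    subtract_mean:
        Remove the across-stack mean frame before correlating, isolating
        the moving component when a static one dominates.
    window:
        Apply a raised-cosine window to suppress edge effects.
    peak_ratio_threshold:
        Frames whose normalized correlation peak falls below this ratio
        are flagged and fall back to their nominal shift.

    Returns
    -------
    ShiftTrajectory
        Shifts in um ((0, 0) at the reference frame), residuals to the
        nominal trajectory when one is available, and flagged frames.
    """
    frames = np.asarray(stack.frames, dtype=float)
    n = len(frames)
    if n < 2:
        raise ValueError("need at least two frames to estimate a trajectory")
    pitch = stack.pixel_size
    work = frames - frames.mean(axis=0, keepdims=True) if subtract_mean else frames
    if window:
        work = work * _window(frames.shape[1:])[None, :, :]

    def _pair(ref: np.ndarray, mov: np.ndarray) -> tuple[float, float, float]:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            shift_rc, _, _ = phase_cross_correlation(
                ref, mov, upsample_factor=upsample_factor, normalization="phase"
            )
        # skimage returns the shift that registers mov onto ref; negate to
        # get the (row, col) content displacement of mov relative to ref
        return -float(shift_rc[0]), -float(shift_rc[1]), _peak_ratio(ref, mov)

    disp_px = np.zeros((n, 2))  # (row, col) content displacement vs reference
    flagged: list[int] = []
    ref_idx = 0
    if mode == "chained":
        acc = np.zeros(2)
        for j in range(1, n):
            dy, dx, peak = _pair(work[j - 1], work[j])
            if peak < peak_ratio_threshold:
                flagged.append(j)
            acc = acc + (dy, dx)
            disp_px[j] = acc
    elif mode == "reference":
        for j in range(1, n):
            dy, dx, peak = _pair(work[ref_idx], work[j])
            if peak < peak_ratio_threshold:
                flagged.append(j)
            disp_px[j] = (dy, dx)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    sign = 1.0 if moving == "specimen" else -1.0
    if moving not in ("specimen", "pattern"):
        raise ValueError("moving must be 'specimen' or 'pattern'")
    shifts = [
        (sign * disp_px[j, 1] * pitch, sign * disp_px[j, 0] * pitch)
        for j in range(n)
    ]

    residual = None
    if stack.nominal_shifts is not None and len(stack.nominal_shifts) == n:
        nom = np.asarray(stack.nominal_shifts, dtype=float)
        nom = nom - nom[ref_idx]
        est = np.asarray(shifts)
        residual = np.hypot(*(est - nom).T)
        for j in flagged:
            log.warning(
                "frame %d: ambiguous correlation peak; using nominal shift", j
            )
            shifts[j] = (float(nom[j, 0]), float(nom[j, 1]))
        if flagged:
            est = np.asarray(shifts)
            residual = np.hypot(*(est - nom).T)
    return ShiftTrajectory(
        shifts=shifts,
        reference_index=ref_idx,
        residual_to_nominal=residual,
        flagged=flagged or None,
    )
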