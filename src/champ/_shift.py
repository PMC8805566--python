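"""Fourier-domain sub-pixel translation shared by the simulator and solver."""

from __future__ import annotations

import numpy as np
from scipy import fft as sfft


def subpixel_shift(image: np.ndarray, shift_rc: tuple[float, float]) -> np.ndarray:
    """Translate a real 2D array by (row, col) pixels with periodic wrap.

    Positive shifts move content down / right. Exact for band-limited
    content; callers keep a guard margin so wrapped content never enters
    the region of interest.
    """
    dy, dx = shift_rc
    if dy == 0.0 and dx == 0.0:
        return image.copy()
    ny, nx = image.shape
    fy = sfft.fftfreq(ny)[:, None]
    fx = sfft.rfftfreq(nx)[None, :]
    ramp = np.exp(-2j * np.pi * (fy * dy + fx * dx))
    return sfft.irfft2(sfft.rfft2(image) * ramp, s=image.shape)


def box_average(image: np.ndarray, u: int) -> np.ndarray:
    """Average u-by-u pixel blocks (camera binning of the fine grid)."""
    if u == 1:
        return image
    ny, nx = image.shape
    if ny % u or nx % u:
        raise ValueError(f"shape {image.shape} not divisible by u={u}")
    return image.reshape(ny // u, u, nx // u, u).mean(axis=(1, 3))


def box_expand(image: np.ndarray, u: int) -> np.ndarray:
    """Right-inverse of :func:`box_average`: replicate each pixel u-by-u.

    Replication (rather than the strict adjoint, which carries a 1/u^2
    factor) keeps back-projected residuals on the same intensity scale
    as the fine grid, so relaxed update steps are well-scaled for any u.
    """
    if u == 1:
        return image
    return np.repeat(np.repeat(image, u, axis=0), u, axis=1)


def box_adjoint(image: np.ndarray, u: int) -> np.ndarray:
    """Strict adjoint of :func:`box_average` (replicate and divide by u^2)."""
    if u == 1:
        return image
    return np.repeat(np.repeat(image, u, axis=0), u, axis=1) / (u * u)
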