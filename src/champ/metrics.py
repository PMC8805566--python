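"""Resolution and fidelity metrics: Gaussian-fit FWHM, Pearson, SSIM, throughput."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from skimage.metrics import structural_similarity

__all__ = [
    "FwhmMeasurement",
    "fit_fwhm",
    "bead_fwhm",
    "pearson",
    "ssim",
    "throughput",
]

FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))  # 2.3548...


@dataclass
class FwhmMeasurement:
    """Result of a 1D Gaussian + offset least-squares fit."""

    fwhm: float  # um
    fit_params: tuple[float, float, float, float]  # amplitude, center, sigma, offset
    r_squared: float
    ok: bool = True  # False when the fit failed to converge or r^2 < 0.8


def _gaussian(x, amplitude, center, sigma, offset):
    return amplitude * np.exp(-0.5 * ((x - center) / sigma) ** 2) + offset


def fit_fwhm(profile: np.ndarray, pixel_size: float, r2_floor: float = 0.8) -> FwhmMeasurement:
    """Fit a Gaussian with constant offset to a 1D peak profile.

    ``profile`` should contain a single dominant peak sampled at
    ``pixel_size`` um spacing with at least ~5 samples across it. The
    FWHM is 2 sqrt(2 ln 2) sigma in um. A non-convergent fit or one with
    r^2 below ``r2_floor`` is returned flagged (``ok=False``) rather
    than silently.
    """
    y = np.asarray(profile, dtype=float)
    if y.ndim != 1 or len(y) < 5:
        raise ValueError("profile must be 1D with at least 5 samples")
    x = np.arange(len(y)) * pixel_size
    offset0 = float(y.min())
    amp0 = float(y.max() - offset0)
    if amp0 <= 0:
        return FwhmMeasurement(np.nan, (0.0, 0.0, np.nan, offset0), 0.0, ok=False)
    center0 = float(x[np.argmax(y)])
    weights = np.clip(y - offset0, 0, None)
    sigma0 = float(
        np.sqrt(np.sum(weights * (x - center0) ** 2) / max(weights.sum(), 1e-30))
    )
    sigma0 = max(sigma0, pixel_size / 2.0)
    try:
        import warnings
        from scipy.optimize import OptimizeWarning

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", OptimizeWarning)
            popt, _ = curve_fit(
                _gaussian,
                x,
                y,
                p0=(amp0, center0, sigma0, offset0),
                maxfev=10000,
            )
    except RuntimeError:
        return FwhmMeasurement(np.nan, (amp0, center0, sigma0, offset0), 0.0, ok=False)
    resid = y - _gaussian(x, *popt)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / max(ss_tot, 1e-30)
    sigma = abs(float(popt[2]))
    return FwhmMeasurement(
        fwhm=FWHM_PER_SIGMA * sigma,
        fit_params=(float(popt[0]), float(popt[1]), sigma, float(popt[3])),
        r_squared=max(0.0, min(1.0, r2)),
        ok=r2 >= r2_floor,
    )


def bead_fwhm(
    image: np.ndarray,
    center_xy_um: tuple[float, float],
    pixel_size: float,
    halfwidth_um: float = 6.0,
) -> FwhmMeasurement | None:
    """FWHM of an isolated bead: x and y line cuts through the refined centroid.

    The centre is refined by an intensity-weighted centroid in a local
    window; the x and y profiles through it are fitted independently and
    the two FWHM values averaged (as is the r^2, pessimistically taking
    the minimum). Returns ``None`` when the bead window leaves the image.
    """
    half = int(round(halfwidth_um / pixel_size))
    cx = int(round(center_xy_um[0] / pixel_size))
    cy = int(round(center_xy_um[1] / pixel_size))
    if (
        cy - half < 0
        or cx - half < 0
        or cy + half + 1 > image.shape[0]
        or cx + half + 1 > image.shape[1]
    ):
        return None
    win = image[cy - half : cy + half + 1, cx - half : cx + half + 1]
    w = np.clip(win - win.min(), 0, None)
    yy, xx = np.mgrid[0 : win.shape[0], 0 : win.shape[1]]
    total = max(w.sum(), 1e-30)
    ry = int(round(float((w * yy).sum() / total)))
    rx = int(round(float((w * xx).sum() / total)))
    ry = min(max(ry, 0), win.shape[0] - 1)
    rx = min(max(rx, 0), win.shape[1] - 1)
    fit_x = fit_fwhm(win[ry, :], pixel_size)
    fit_y = fit_fwhm(win[:, rx], pixel_size)
    if not (np.isfinite(fit_x.fwhm) and np.isfinite(fit_y.fwhm)):
        return None
    return FwhmMeasurement(
        fwhm=0.5 * (fit_x.fwhm + fit_y.fwhm),
        fit_params=fit_x.fit_params,
        r_squared=min(fit_x.r_squared, fit_y.r_squared),
        ok=fit_x.ok and fit_y.ok,
    )


def pearson(a: np.ndarray, b: np.ndarray, mask: np.ndarray | None = None) -> float:
    """Pearson product-moment correlation over (optionally masked) pixels."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("images must share a shape")
    if mask is not None:
        a, b = a[mask], b[mask]
    else:
        a, b = a.ravel(), b.ravel()
    if a.std() == 0 or b.std() == 0:
        raise ValueError("Pearson correlation undefined for a constant image")
    return float(np.corrcoef(a, b)[0, 1])


def ssim(
    a: np.ndarray,
    b: np.ndarray,
    data_range: float | None = None,
    win_size: int = 11,
    k1: float = 0.01,
    k2: float = 0.03,
) -> float:
    """Mean structural similarity with Gaussian 11-px window defaults.

    The dynamic range defaults to the joint min/max of the pair; images
    are compared in their native float scale, not re-quantized.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("images must share a shape")
    if data_range is None:
        lo = min(a.min(), b.min())
        hi = max(a.max(), b.max())
        data_range = float(hi - lo)
    if data_range <= 0:
        raise ValueError("zero dynamic range: SSIM undefined")
    win = min(win_size, min(a.shape) - (min(a.shape) + 1) % 2)
    if win % 2 == 0:
        win -= 1
    return float(
        structural_similarity(
            a,
            b,
            data_range=data_range,
            gaussian_weights=True,
            win_size=win,
            sigma=1.5,
            use_sample_covariance=False,
            K1=k1,
            K2=k2,
        )
    )


def throughput(fov_per_minute: float, half_pitch: float) -> float:
    """Imaging throughput: attainable FOV per minute over half-pitch squared.

    Units are the caller's; with mm^2/min and um the conventional usage
    is ``throughput(60, 0.55) ~ 2e8`` effective pixels per minute (both
    lengths converted to the same unit internally: the FOV is taken in
    mm^2 and the half pitch in um).
    """
    if fov_per_minute <= 0 or half_pitch <= 0:
        raise ValueError("arguments must be positive")
    return fov_per_minute * 1e6 / half_pitch**2
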