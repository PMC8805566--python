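"""Synthetic speckle patterns, fluorophore phantoms and raw frame stacks.

The forward model mirrors the acquisition geometry of a speckle-
illuminated wide-field system: a constant, fully developed speckle
pattern is projected onto the specimen; the stage raster-scans the
specimen so that, in the specimen's own frame of reference, the pattern
translates by the negated stage shift; the emitted fluorescence is
blurred by the incoherent detection PSF and sampled by a camera whose
pixel pitch undersamples that PSF. Shot noise and Gaussian read noise
model an sCMOS detector.

Conventions: 0-based pixel indices; shifts are (x, y) in micrometres
with +x rightwards (columns) and +y downwards (rows); the pattern moves
by -s_j in the sample frame.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import fft as sfft
from scipy.signal import fftconvolve
from scipy.special import erf

from ._shift import box_average, subpixel_shift
from .optics import AIRY_FWHM_FACTOR, OpticalSystem, psf

__all__ = [
    "SpeckleField",
    "Phantom",
    "FrameStack",
    "make_speckle",
    "make_phantom",
    "forward_image",
    "raster_shifts",
    "autocorrelation_fwhm",
]


@dataclass
class SpeckleField:
    """A fully developed speckle intensity pattern on the fine grid."""

    intensity: np.ndarray  # 2D, non-negative, mean-normalized to 1
    grain_size: float  # um, measured autocorrelation FWHM
    contrast: float  # std / mean
    pixel_size: float  # um per fine-grid pixel


@dataclass
class Phantom:
    """Fluorophore density map with optional ground-truth nucleus labels."""

    density: np.ndarray  # 2D, non-negative
    pixel_size: float  # um
    truth_labels: np.ndarray | None = None  # int mask, same shape
    centers: np.ndarray | None = None  # (n, 2) feature centres, (x, y) um

    def __post_init__(self) -> None:
        if np.any(self.density < 0):
            raise ValueError("phantom density must be non-negative")
        if self.truth_labels is not None and self.truth_labels.shape != self.density.shape:
            raise ValueError("truth_labels shape must match density")


@dataclass
class FrameStack:
    """Raw camera frames with the nominal scan trajectory and optics."""

    frames: np.ndarray  # (n_frames, h, w), non-negative
    nominal_shifts: list[tuple[float, float]]  # (x, y) um per frame
    meta: OpticalSystem
    noise_params: tuple[float, float] = (0.0, 0.0)  # (photon scale, read sd)
    pixel_size: float | None = None  # um per camera pixel at the sample

    def __post_init__(self) -> None:
        if len(self.frames) != len(self.nominal_shifts):
            raise ValueError("one nominal shift per frame is required")
        if self.pixel_size is None:
            self.pixel_size = self.meta.sample_pitch

    def __len__(self) -> int:
        return len(self.frames)


def raster_shifts(n_side: int, step_um: float) -> list[tuple[float, float]]:
    """Row-major raster trajectory of ``n_side**2`` positions, origin first."""
    return [
        (col * step_um, row * step_um)
        for row in range(n_side)
        for col in range(n_side)
    ]


def _centred_profile_fwhm(profile: np.ndarray, pixel_size: float) -> float:
    """FWHM of a symmetric peak centred in ``profile``, linear interpolation."""
    c = len(profile) // 2
    peak = profile[c]
    half = peak / 2.0
    right = profile[c:]
    below = np.nonzero(right < half)[0]
    if len(below) == 0:
        raise ValueError("profile never falls below half maximum")
    k = below[0]
    frac = (right[k - 1] - half) / (right[k - 1] - right[k])
    return 2.0 * (k - 1 + frac) * pixel_size


def autocorrelation_fwhm(intensity: np.ndarray, pixel_size: float) -> float:
    """Grain size: FWHM of the intensity autocovariance peak (um).

    Computed by FFT; the central row and column cuts through the peak are
    averaged (speckle grains are isotropic for a circular pupil).
    """
    fluct = intensity - intensity.mean()
    power = np.abs(sfft.fft2(fluct)) ** 2
    acov = np.real(sfft.ifft2(power))
    acov = sfft.fftshift(acov)
    acov = acov / acov.max()
    cy, cx = np.array(acov.shape) // 2
    w_row = _centred_profile_fwhm(acov[cy, :], pixel_size)
    w_col = _centred_profile_fwhm(acov[:, cx], pixel_size)
    return 0.5 * (w_row + w_col)


def _speckle_realization(
    shape: tuple[int, int], pixel_size: float, f_cut: float, seed: int
) -> np.ndarray:
    """One fully developed speckle intensity from a circular random-phase pupil."""
    rng = np.random.default_rng(seed)
    fy = sfft.fftfreq(shape[0], d=pixel_size)[:, None]
    fx = sfft.fftfreq(shape[1], d=pixel_size)[None, :]
    pupil = (fy**2 + fx**2) <= f_cut**2
    if pupil.sum() < 8:
        raise ValueError("grain size too large for this field: too few speckle modes")
    phases = rng.uniform(0.0, 2.0 * np.pi, size=shape)
    spectrum = pupil * np.exp(1j * phases)
    fld = sfft.ifft2(spectrum)
    intensity = np.abs(fld) ** 2
    return intensity / intensity.mean()


def make_speckle(
    shape: tuple[int, int],
    grain_size: float,
    pixel_size: float,
    seed: int = 0,
) -> SpeckleField:
    """Generate fully developed speckle with a target grain size.

    The grain size is the FWHM of the intensity autocorrelation peak. A
    circular pupil with uniformly random phases yields negative-
    exponential intensity statistics (contrast ~ 1). The pupil cut-off is
    set from the Airy relation FWHM ~ 0.514 / f_cut and refined once
    against the measured autocorrelation of a first realization.

    Parameters
    ----------
    shape:
        Field dimensions in fine-grid pixels.
    grain_size:
        Target autocorrelation FWHM in um; must be at least 2 pixels.
    pixel_size:
        Fine-grid pixel in um.
    seed:
        Phase-screen seed; fixed seed gives a bit-identical field.
    """
    if grain_size < 2.0 * pixel_size:
        raise ValueError(
            f"grain size {grain_size} um is below the grid resolution "
            f"(minimum {2.0 * pixel_size} um at {pixel_size} um/px)"
        )
    f_cut = AIRY_FWHM_FACTOR / grain_size
    intensity = _speckle_realization(shape, pixel_size, f_cut, seed)
    measured = autocorrelation_fwhm(intensity, pixel_size)
    # one calibration pass: FWHM scales as 1/f_cut
    f_cut *= measured / grain_size
    intensity = _speckle_realization(shape, pixel_size, f_cut, seed)
    measured = autocorrelation_fwhm(intensity, pixel_size)
    return SpeckleField(
        intensity=intensity,
        grain_size=measured,
        contrast=float(intensity.std() / intensity.mean()),
        pixel_size=pixel_size,
    )


def _soft_disk(
    shape: tuple[int, int], center_px: tuple[float, float], radius_px: float
) -> np.ndarray:
    """Anti-aliased disk indicator via an erf edge of ~half-pixel width."""
    yy = np.arange(shape[0])[:, None] - center_px[0]
    xx = np.arange(shape[1])[None, :] - center_px[1]
    r = np.hypot(yy, xx)
    return 0.5 * (1.0 + erf((radius_px - r) / 0.5))


def _place_centres(
    rng: np.random.Generator,
    n: int,
    shape: tuple[int, int],
    margin_px: float,
    min_sep_px: float,
    max_tries: int = 5000,
) -> np.ndarray:
    centres: list[tuple[float, float]] = []
    tries = 0
    while len(centres) < n:
        if tries > max_tries * max(n, 1):
            raise RuntimeError(
                f"could not place {n} non-overlapping features after "
                f"{tries} attempts; reduce the count or the separation"
            )
        tries += 1
        cy = rng.uniform(margin_px, shape[0] - 1 - margin_px)
        cx = rng.uniform(margin_px, shape[1] - 1 - margin_px)
        if all(math.hypot(cy - y, cx - x) >= min_sep_px for y, x in centres):
            centres.append((cy, cx))
    return np.asarray(centres)


def _beads_phantom(shape, pixel_size, rng, params) -> Phantom:
    diameter = params.get("diameter_um", 0.5)
    n = params.get("n_beads", 20)
    min_sep = params.get("min_separation_um", max(5.0, 4.0 * diameter))
    margin = params.get("margin_um", 5.0)
    radius_px = diameter / 2.0 / pixel_size
    if 2.0 * radius_px < 1.0:
        raise ValueError("bead diameter below one fine-grid pixel")
    centres = _place_centres(
        rng, n, shape, margin / pixel_size, min_sep / pixel_size
    )
    density = np.zeros(shape)
    labels = np.zeros(shape, dtype=np.int32)
    for i, (cy, cx) in enumerate(centres):
        disk = _soft_disk(shape, (cy, cx), radius_px)
        density += disk
        labels[_soft_disk(shape, (cy, cx), max(radius_px, 1.0)) > 0.5] = i + 1
    centers_um = np.stack([centres[:, 1], centres[:, 0]], axis=1) * pixel_size
    return Phantom(density, pixel_size, truth_labels=labels, centers=centers_um)


def _nuclei_phantom(shape, pixel_size, rng, params) -> Phantom:
    n = params.get("n_nuclei", 30)
    background = params.get("background", 1.0)
    level = params.get("nucleus_level", 0.25)
    r_lo, r_hi = params.get("radius_um", (2.0, 4.0))
    min_sep = params.get("min_separation_um", 2.5 * r_hi)
    margin = params.get("margin_um", r_hi + 1.0)
    n_stripes = params.get("n_stripes", 0)

    density = np.full(shape, background, dtype=float)
    labels = np.zeros(shape, dtype=np.int32)
    centres = (
        _place_centres(rng, n, shape, margin / pixel_size, min_sep / pixel_size)
        if n > 0
        else np.empty((0, 2))
    )
    yy = np.arange(shape[0])[:, None]
    xx = np.arange(shape[1])[None, :]
    for i, (cy, cx) in enumerate(centres):
        a = rng.uniform(r_lo, r_hi) / pixel_size
        b = a * rng.uniform(0.6, 1.0)
        theta = rng.uniform(0.0, np.pi)
        dy, dx = yy - cy, xx - cx
        rot_y = dy * np.cos(theta) - dx * np.sin(theta)
        rot_x = dy * np.sin(theta) + dx * np.cos(theta)
        r = np.sqrt((rot_y / b) ** 2 + (rot_x / a) ** 2)
        mask = 0.5 * (1.0 + erf((1.0 - r) * min(a, b) / 0.5))
        density -= (background - level) * mask
        labels[mask > 0.5] = i + 1
    for _ in range(n_stripes):
        # dark elongated band with internal texture (vessel-like feature)
        theta = rng.uniform(0.0, np.pi)
        offset = rng.uniform(0.3, 0.7) * shape[0]
        width_px = params.get("stripe_width_um", 3.0) / pixel_size
        dist = np.abs(
            (yy - offset) * np.cos(theta) - (xx - shape[1] / 2) * np.sin(theta)
        )
        band = 0.5 * (1.0 + erf((width_px - dist) / 0.5))
        texture = 1.0 + 0.35 * np.sin(2.0 * np.pi * (xx + yy) * pixel_size / 1.5)
        density = density * (1.0 - band) + band * level * texture
    density = np.clip(density, 0.0, None)
    centers_um = (
        np.stack([centres[:, 1], centres[:, 0]], axis=1) * pixel_size
        if len(centres)
        else None
    )
    return Phantom(density, pixel_size, truth_labels=labels, centers=centers_um)


def _siemens_phantom(shape, pixel_size, rng, params) -> Phantom:
    n_spokes = params.get("n_spokes", 16)
    cy, cx = (shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0
    yy = np.arange(shape[0])[:, None] - cy
    xx = np.arange(shape[1])[None, :] - cx
    r = np.hypot(yy, xx)
    theta = np.arctan2(yy, xx)
    r_outer = params.get("r_outer_frac", 0.45) * min(shape)
    r_inner = params.get("r_inner_px", 3.0)
    annulus = 0.5 * (1.0 + erf((r_outer - r) / 1.0))
    annulus *= 0.5 * (1.0 + erf((r - r_inner) / 1.0))
    density = 0.5 * (1.0 + np.cos(n_spokes * theta)) * annulus
    return Phantom(density, pixel_size, truth_labels=None)


_PHANTOM_MAKERS = {
    "beads": _beads_phantom,
    "nuclei": _nuclei_phantom,
    "siemens": _siemens_phantom,
}


def make_phantom(
    kind: str,
    shape: tuple[int, int],
    pixel_size: float,
    seed: int = 0,
    **params,
) -> Phantom:
    """Generate a fluorophore phantom on the fine grid.

    Kinds
    -----
    ``beads``
        Isolated sub-resolution disks at non-overlapping random positions
        (``diameter_um``, ``n_beads``, ``min_separation_um``).
    ``nuclei``
        Bright autofluorescent background with dark elliptical nuclei
        (negative nuclear contrast), truth labels filled; optional dark
        textured stripes emulate vessel-like confounders (``n_nuclei``,
        ``radius_um``, ``nucleus_level``, ``n_stripes``).
    ``siemens``
        Radial sinusoidal star target for frequency-support checks.
    """
    if min(shape) <= 0:
        raise ValueError("shape must be positive")
    try:
        maker = _PHANTOM_MAKERS[kind]
    except KeyError:
        raise ValueError(f"unknown phantom kind {kind!r}") from None
    return maker(tuple(shape), pixel_size, np.random.default_rng(seed), params)


def forward_image(
    phantom: Phantom,
    speckle: SpeckleField,
    system: OpticalSystem,
    shifts: Sequence[tuple[float, float]],
    noise_params: tuple[float, float] = (0.0, 0.0),
    upsample: int = 2,
    seed: int = 0,
    psf_mode: str = "airy",
    psf_fwhm: float | None = None,
    psf_kernel: np.ndarray | None = None,
) -> FrameStack:
    """Simulate the raw camera stack for a raster-scanned acquisition.

    For each stage shift ``s_j`` the emitted intensity is the phantom
    density times the speckle translated by ``-s_j`` (sample frame),
    blurred by the incoherent detection PSF, box-averaged ``upsample``-
    fold down to camera sampling, and corrupted by Poisson shot noise at
    ``noise_params[0]`` photons per unit intensity plus Gaussian read
    noise of sd ``noise_params[1]`` (both zero disables noise).

    The speckle field must be strictly larger than the phantom so that
    no periodic wrap from the Fourier-domain translation enters the
    cropped field of view; a shift too large for the available guard
    margin raises ``ValueError``.
    """
    if upsample < 1 or int(upsample) != upsample:
        raise ValueError("upsample must be a positive integer")
    u = int(upsample)
    fine = phantom.density
    if not np.isclose(speckle.pixel_size, phantom.pixel_size):
        raise ValueError("speckle and phantom pixel sizes differ")
    px = phantom.pixel_size
    big = speckle.intensity
    pad_y = (big.shape[0] - fine.shape[0]) // 2
    pad_x = (big.shape[1] - fine.shape[1]) // 2
    if pad_y < 0 or pad_x < 0:
        raise ValueError("speckle field must be at least as large as the phantom")
    max_sx = max(abs(s[0]) for s in shifts) / px
    max_sy = max(abs(s[1]) for s in shifts) / px
    if max_sx > pad_x - 1 or max_sy > pad_y - 1:
        raise ValueError(
            "shift moves the pattern support off the speckle field; "
            "generate the speckle on a larger guard field"
        )
    if fine.shape[0] % u or fine.shape[1] % u:
        raise ValueError("phantom shape must be divisible by upsample")

    if psf_kernel is None:
        if psf_mode == "gaussian":
            width = psf_fwhm if psf_fwhm is not None else 0.0
        else:
            width = system.psf_fwhm
        half = int(np.ceil(3.0 * max(width, 4 * px) / px))
        ksize = 2 * half + 1
        psf_kernel = psf(system, (ksize, ksize), px, mode=psf_mode, fwhm=psf_fwhm)

    rng = np.random.default_rng(seed)
    photon_scale, read_sd = noise_params
    frames = []
    sl = (slice(pad_y, pad_y + fine.shape[0]), slice(pad_x, pad_x + fine.shape[1]))
    for sx, sy in shifts:
        shifted = subpixel_shift(big, (-sy / px, -sx / px))
        psi = fine * shifted[sl]
        blurred = fftconvolve(psi, psf_kernel, mode="same")
        frame = box_average(blurred, u)
        if photon_scale > 0:
            frame = rng.poisson(np.clip(frame, 0, None) * photon_scale) / photon_scale
        if read_sd > 0:
            frame = frame + rng.normal(0.0, read_sd, size=frame.shape)
        frames.append(np.clip(frame, 0.0, None))
    return FrameStack(
        frames=np.asarray(frames),
        nominal_shifts=[tuple(map(float, s)) for s in shifts],
        meta=system,
        noise_params=(float(photon_scale), float(read_sd)),
        pixel_size=u * px,
    )
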