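"""Optical system description, detection PSFs and resolution limits.

All lengths in metadata are micrometres unless a name says otherwise
(wavelengths are nanometres, following vendor convention). The detection
path is an incoherent fluorescence system: a low-NA objective whose PSF
is the squared modulus of the pupil's Fourier transform (Airy pattern),
or, when calibrating against a measured bead profile, a Gaussian of the
stated full width at half maximum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import j1

__all__ = [
    "OpticalSystem",
    "psf",
    "resolution_limit",
    "synthetic_aperture_cutoff",
    "grain_to_na",
]

#: FWHM of an Airy intensity pattern in units of lambda/NA.
AIRY_FWHM_FACTOR = 0.5145
#: First zero of the Airy pattern in units of lambda/NA.
AIRY_FIRST_ZERO_FACTOR = 0.6098


def grain_to_na(grain_size_um: float, wavelength_nm: float) -> float:
    """Illumination NA implied by a fully developed speckle grain size.

    The intensity autocorrelation FWHM (the grain) of speckle produced
    through a circular pupil of numerical aperture NA at wavelength
    lambda is approximately lambda / (2 NA), the same scaling as the
    structured-illumination half period.
    """
    if grain_size_um <= 0:
        raise ValueError("grain size must be positive")
    return (wavelength_nm * 1e-3) / (2.0 * grain_size_um)


@dataclass(frozen=True)
class OpticalSystem:
    """Geometry and apertures of the acquisition system.

    Defaults describe a deep-UV excited, visible-emission system with a
    4x/0.1-NA detection objective and a 6.5-um camera pixel pitch; the
    illumination NA defaults to the value implied by a 1.3-um speckle
    grain at 266-nm excitation.
    """

    wavelength_ex: float = 266.0  # nm
    wavelength_em: float = 445.0  # nm
    na_obj: float = 0.1
    na_illu: float = field(default=grain_to_na(1.3, 266.0))
    magnification: float = 4.0
    camera_pitch: float = 6.5  # um, at the sensor

    def __post_init__(self) -> None:
        for name in ("wavelength_ex", "wavelength_em", "magnification", "camera_pitch"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.na_obj < 1:
            raise ValueError("na_obj must lie in (0, 1)")
        if not 0 < self.na_illu < 1:
            raise ValueError("na_illu must lie in (0, 1)")

    @property
    def sample_pitch(self) -> float:
        """Camera pixel pitch referred to the sample plane (um)."""
        return self.camera_pitch / self.magnification

    @property
    def psf_fwhm(self) -> float:
        """Diffraction-limited detection FWHM (um), Airy intensity."""
        return AIRY_FWHM_FACTOR * self.wavelength_em * 1e-3 / self.na_obj


def resolution_limit(system: OpticalSystem) -> float:
    """Structured-illumination resolution limit lambda / 2(NA_obj + NA_illu), um.

    With ``na_illu = 0`` this reduces to the incoherent wide-field limit
    lambda / (2 NA_obj).
    """
    return system.wavelength_em * 1e-3 / (2.0 * (system.na_obj + system.na_illu))


def synthetic_aperture_cutoff(f_obj: float, f_pmax: float) -> float:
    """Cut-off frequency of the synthetic aperture: f_obj + f_pmax.

    ``f_obj`` is the detection passband cut-off and ``f_pmax`` the highest
    spatial frequency present in the illumination intensity pattern; units
    are whatever the caller uses (typically cycles/um).
    """
    if f_obj < 0 or f_pmax < 0:
        raise ValueError("spatial frequencies must be non-negative")
    return f_obj + f_pmax


def _radius_grid(shape: tuple[int, int], pixel_size: float) -> np.ndarray:
    cy, cx = (shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0
    y = (np.arange(shape[0]) - cy) * pixel_size
    x = (np.arange(shape[1]) - cx) * pixel_size
    return np.hypot(y[:, None], x[None, :])


def psf(
    system: OpticalSystem,
    shape: tuple[int, int],
    pixel_size: float,
    mode: str = "airy",
    fwhm: float | None = None,
    min_samples_per_fwhm: float = 4.0,
) -> np.ndarray:
    """Normalized incoherent detection PSF sampled on a centred grid.

    Parameters
    ----------
    system:
        Supplies emission wavelength and detection NA for ``mode="airy"``.
    shape:
        Kernel shape (rows, cols); the peak sits at the geometric centre.
    pixel_size:
        Grid spacing in um. Must resolve the PSF with at least four
        samples across its FWHM.
    mode:
        ``"airy"`` for the diffraction-limited Airy intensity pattern, or
        ``"gaussian"`` for an isotropic Gaussian calibrated to a measured
        ``fwhm`` (um) — used when matching a bead-derived instrument PSF.

    Returns
    -------
    Kernel summing to 1.
    """
    if mode == "gaussian":
        if fwhm is None or fwhm <= 0:
            raise ValueError("gaussian mode requires a positive fwhm (um)")
        width = fwhm
    elif mode == "airy":
        width = AIRY_FWHM_FACTOR * system.wavelength_em * 1e-3 / system.na_obj
    else:
        raise ValueError(f"unknown PSF mode {mode!r}")
    if width / pixel_size < min_samples_per_fwhm:
        raise ValueError(
            f"grid does not resolve the PSF: {width / pixel_size:.2f} samples "
            f"across the FWHM, need at least {min_samples_per_fwhm:g} "
            "(use a finer pixel_size)"
        )

    r = _radius_grid(shape, pixel_size)
    if mode == "gaussian":
        sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        kernel = np.exp(-0.5 * (r / sigma) ** 2)
    else:
        # v = 2 pi NA r / lambda; intensity = (2 J1(v)/v)^2 with limit 1 at v=0
        v = 2.0 * np.pi * system.na_obj * r / (system.wavelength_em * 1e-3)
        with np.errstate(invalid="ignore", divide="ignore"):
            amp = np.where(v == 0, 1.0, 2.0 * j1(v) / np.where(v == 0, 1.0, v))
        kernel = amp**2
    return kernel / kernel.sum()
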