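"""Blind joint recovery of object and speckle pattern from a scanned stack.

The solver is a momentum-assisted, regularized ptychographic iterative
engine adapted to incoherent fluorescence: both the super-resolved
fluorophore map ``O`` and the unknown illumination intensity pattern
``P`` are real and non-negative, and each raw frame is modelled as

    I_j  =  D_u[ h * ( O . T_{-s_j} P ) ]

where ``T_{-s_j}`` translates the pattern opposite to the stage shift
``s_j``, ``h`` is the incoherent detection PSF, ``*`` denotes
convolution and ``D_u`` box-averages the fine reconstruction grid down
to the undersampled camera grid (the sub-sampling operator). Frames are
visited sequentially; after the model residual is back-projected through
the adjoint operators, object and pattern receive relaxed (rPIE-style)
updates, with a heavy-ball momentum step applied across iterations.

Resolution extends to the synthetic aperture ``f_obj + f_pmax``: object
frequencies mixed down into the detection passband by the pattern's
spatial frequencies become recoverable once the pattern is jointly
estimated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import fft as sfft

from ._shift import box_average, box_expand
from .optics import OpticalSystem, psf, resolution_limit, synthetic_aperture_cutoff
from .preprocess import ShiftTrajectory
from .simulate import FrameStack

__all__ = [
    "ReconConfig",
    "ReconResult",
    "ReconDivergenceError",
    "reconstruct",
    "resolution_limit",
    "synthetic_aperture_cutoff",
]


class ReconDivergenceError(RuntimeError):
    """Raised when the iteration produces non-finite estimates."""

    def __init__(self, iteration: int, last_object: np.ndarray, last_pattern: np.ndarray):
        super().__init__(f"reconstruction diverged at iteration {iteration}")
        self.iteration = iteration
        self.last_object = last_object
        self.last_pattern = last_pattern


@dataclass(frozen=True)
class ReconConfig:
    """Solver settings.

    ``alpha_obj`` / ``alpha_pat`` are the rPIE relaxation weights in the
    update denominators (1 recovers the conservative PIE step, small
    values take near-Newton steps where the partner estimate is strong);
    ``momentum_eta`` is the heavy-ball friction applied every
    ``momentum_interval`` iterations.
    """

    iterations: int = 10
    upsample: int = 2
    alpha_obj: float = 0.1
    alpha_pat: float = 0.25
    momentum_eta: float = 0.9
    momentum_interval: int = 1
    nonneg: bool = True
    seed: int = 0
    frame_order: str = "raster"  # or "random-per-iteration"
    update_pattern: bool = True
    psf_mode: str = "airy"
    psf_fwhm: float | None = None
    pad_px: int | None = None  # guard margin on the fine grid; auto if None
    pattern_band_cutoff: float | None = None  # cycles/um; None disables
    object_band_cutoff: float | None = None  # cycles/um; None disables
    relax: float = 1.0  # global damping of both updates, in (0, 1]

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.upsample < 1 or int(self.upsample) != self.upsample:
            raise ValueError("upsample must be a positive integer")
        for name in ("alpha_obj", "alpha_pat"):
            a = getattr(self, name)
            if not 0.0 < a <= 1.0:
                raise ValueError(f"{name} must lie in (0, 1]")
        if not 0.0 <= self.momentum_eta < 1.0:
            raise ValueError("momentum_eta must lie in [0, 1)")
        if self.frame_order not in ("raster", "random-per-iteration"):
            raise ValueError("frame_order must be 'raster' or 'random-per-iteration'")
        if not 0.0 < self.relax <= 1.0:
            raise ValueError("relax must lie in (0, 1]")


@dataclass
class ReconResult:
    """Converged estimates and the per-iteration relative data misfit."""

    object: np.ndarray  # fine grid, field of view only
    pattern: np.ndarray  # fine grid, padded reconstruction frame
    error_history: np.ndarray  # sum_j ||I_j - m_j||^2 / sum_j ||I_j||^2
    config: ReconConfig
    pixel_size: float  # um per fine-grid pixel
    fov_slice: tuple[slice, slice] | None = None  # FOV inside the padded frame
    object_padded: np.ndarray | None = None  # full reconstruction frame

    @property
    def pattern_fov(self) -> np.ndarray:
        """Pattern estimate cropped to the imaged field of view."""
        if self.fov_slice is None:
            return self.pattern
        return self.pattern[self.fov_slice]


def _shift_ramp(shape: tuple[int, int], dy: float, dx: float) -> np.ndarray:
    fy = sfft.fftfreq(shape[0])[:, None]
    fx = sfft.rfftfreq(shape[1])[None, :]
    return np.exp(-2j * np.pi * (fy * dy + fx * dx))


def reconstruct(
    stack: FrameStack,
    trajectory: ShiftTrajectory | None = None,
    config: ReconConfig = ReconConfig(),
    init_pattern: np.ndarray | None = None,
) -> ReconResult:
    """Jointly estimate object and illumination pattern from a frame stack.

    Parameters
    ----------
    stack:
        Flattened raw frames at camera sampling with optics metadata.
    trajectory:
        Per-frame stage shifts in um. ``None`` falls back to the stack's
        nominal shifts.
    config:
        Solver settings; ``config.update_pattern=False`` keeps the
        pattern fixed at its initialization (known-pattern deconvolution
        mode, used with ``init_pattern``).
    init_pattern:
        Optional pattern initialization on the padded fine grid or on the
        field-of-view grid (then embedded). Default: all ones.

    Returns
    -------
    ReconResult
        Non-negative object (FOV grid) and pattern (padded grid), with
        the relative data-misfit history.
    """
    frames = np.asarray(stack.frames, dtype=float)
    if trajectory is not None:
        shifts = list(trajectory.shifts)
    else:
        shifts = list(stack.nominal_shifts)
    if len(shifts) != len(frames):
        raise ValueError(
            f"stack has {len(frames)} frames but trajectory has {len(shifts)} shifts"
        )
    u = int(config.upsample)
    cam_ny, cam_nx = frames.shape[1:]
    fine_px = stack.pixel_size / u
    ny, nx = cam_ny * u, cam_nx * u

    _check_scan_guidance(stack.meta, shifts)

    # guard margin: maximum shift plus one PSF support
    if config.psf_mode == "gaussian" and config.psf_fwhm is not None:
        psf_width = config.psf_fwhm
    else:
        psf_width = stack.meta.psf_fwhm
    max_shift_px = max(max(abs(s[0]), abs(s[1])) for s in shifts) / fine_px
    pad = config.pad_px
    if pad is None:
        pad = int(np.ceil(max_shift_px + 2.0 * psf_width / fine_px)) + 4
        pad += (-(ny + 2 * pad)) % 16  # keep an FFT-friendly length
    gy, gx = ny + 2 * pad, nx + 2 * pad
    fov = (slice(pad, pad + ny), slice(pad, pad + nx))

    half = int(np.ceil(3.0 * max(psf_width, 4 * fine_px) / fine_px))
    kernel = psf(
        stack.meta,
        (2 * half + 1, 2 * half + 1),
        fine_px,
        mode=config.psf_mode,
        fwhm=config.psf_fwhm,
        # the reconstruction grid deliberately undersamples the PSF when the
        # camera does (that is what the sub-sampling operator handles)
        min_samples_per_fwhm=2.0,
    )
    kpad = np.zeros((gy, gx))
    kpad[:kernel.shape[0], :kernel.shape[1]] = kernel
    kpad = np.roll(kpad, (-half, -half), axis=(0, 1))
    otf = sfft.rfft2(kpad)
    otf_conj = np.conj(otf)

    # initialization: pattern flat; object = mean frame, replicated to the
    # fine grid, extended by its mean into the guard margin
    if init_pattern is None:
        pattern = np.ones((gy, gx))
    else:
        pattern = np.asarray(init_pattern, dtype=float)
        if pattern.shape == (ny, nx):
            embedded = np.full((gy, gx), float(pattern.mean()))
            embedded[fov] = pattern
            pattern = embedded
        elif pattern.shape != (gy, gx):
            raise ValueError(
                f"init_pattern shape {pattern.shape} matches neither the FOV "
                f"fine grid {(ny, nx)} nor the padded grid {(gy, gx)}"
            )
        pattern = pattern.copy()
    mean_frame = frames.mean(axis=0)
    obj = np.full((gy, gx), float(mean_frame.mean()))
    obj[fov] = np.repeat(np.repeat(mean_frame, u, axis=0), u, axis=1)
    obj /= max(pattern[fov].mean(), 1e-12)

    ramps = [
        _shift_ramp((gy, gx), -s[1] / fine_px, -s[0] / fine_px) for s in shifts
    ]
    data_norm = float(np.sum(frames**2))
    if data_norm == 0.0:
        raise ValueError("all-zero frame stack cannot be reconstructed")

    def _band_projector(cutoff: float | None):
        if cutoff is None:
            return None
        fy = sfft.fftfreq(gy, d=fine_px)[:, None]
        fx = sfft.rfftfreq(gx, d=fine_px)[None, :]
        return (fy**2 + fx**2) <= cutoff**2

    pat_band = _band_projector(config.pattern_band_cutoff)
    obj_band = _band_projector(config.object_band_cutoff)

    rng = np.random.default_rng(config.seed)
    vel_obj = np.zeros_like(obj)
    vel_pat = np.zeros_like(pattern)
    ckpt_obj = obj.copy()
    ckpt_pat = pattern.copy()
    errors = np.empty(config.iterations)

    for it in range(config.iterations):
        order = np.arange(len(frames))
        if config.frame_order == "random-per-iteration":
            rng.shuffle(order)
        misfit = 0.0
        for j in order:
            ramp = ramps[j]
            p_j = sfft.irfft2(sfft.rfft2(pattern) * ramp, s=(gy, gx))
            psi = obj * p_j
            blurred = sfft.irfft2(sfft.rfft2(psi) * otf, s=(gy, gx))
            model = box_average(blurred[fov], u)
            resid = frames[j] - model
            misfit += float(np.sum(resid**2))
            r_fine = np.zeros((gy, gx))
            r_fine[fov] = box_expand(resid, u)
            corr = sfft.irfft2(sfft.rfft2(r_fine) * otf_conj, s=(gy, gx))

            p_sq = p_j * p_j
            denom_o = (1.0 - config.alpha_obj) * p_sq + config.alpha_obj * p_sq.max()
            obj = obj + config.relax * p_j * corr / np.maximum(denom_o, 1e-30)
            if config.update_pattern:
                o_sq = obj * obj
                denom_p = (
                    (1.0 - config.alpha_pat) * o_sq + config.alpha_pat * o_sq.max()
                )
                dp = config.relax * obj * corr / np.maximum(denom_p, 1e-30)
                # shift the update back into the pattern's reference frame
                pattern = pattern + sfft.irfft2(
                    sfft.rfft2(dp) * np.conj(ramp), s=(gy, gx)
                )

        if not (np.isfinite(obj).all() and np.isfinite(pattern).all()):
            raise ReconDivergenceError(it, ckpt_obj, ckpt_pat)

        if pat_band is not None and config.update_pattern:
            pattern = sfft.irfft2(sfft.rfft2(pattern) * pat_band, s=(gy, gx))
        if obj_band is not None:
            obj = sfft.irfft2(sfft.rfft2(obj) * obj_band, s=(gy, gx))
        if config.nonneg:
            np.clip(obj, 0.0, None, out=obj)
            np.clip(pattern, 0.0, None, out=pattern)
        if config.update_pattern:
            # fix the O.P scale ambiguity: pattern has unit mean in the FOV
            scale = pattern[fov].mean()
            if scale > 1e-12:
                pattern /= scale
                obj *= scale

        if (
            config.momentum_eta > 0.0
            and (it + 1) % max(config.momentum_interval, 1) == 0
        ):
            vel_obj = config.momentum_eta * vel_obj + (obj - ckpt_obj)
            obj = obj + config.momentum_eta * vel_obj
            if config.update_pattern:
                vel_pat = config.momentum_eta * vel_pat + (pattern - ckpt_pat)
                pattern = pattern + config.momentum_eta * vel_pat
            if config.nonneg:
                np.clip(obj, 0.0, None, out=obj)
                np.clip(pattern, 0.0, None, out=pattern)
            ckpt_obj = obj.copy()
            ckpt_pat = pattern.copy()

        errors[it] = misfit / data_norm

    return ReconResult(
        object=obj[fov].copy(),
        pattern=pattern,
        error_history=errors,
        config=replace(config),
        pixel_size=fine_px,
        fov_slice=fov,
        object_padded=obj,
    )


def _check_scan_guidance(system: OpticalSystem, shifts) -> None:
    """Warn when the trajectory violates the stated acquisition guidance:
    scan range should exceed twice the diffraction-limited spot and steps
    should stay below the targeted resolution."""
    xs = [s[0] for s in shifts]
    ys = [s[1] for s in shifts]
    scan_range = max(max(xs) - min(xs), max(ys) - min(ys))
    spot = system.psf_fwhm
    if scan_range < 2.0 * spot:
        warnings.warn(
            f"scan range {scan_range:.2f} um is below twice the detection "
            f"spot size ({2 * spot:.2f} um); reconstruction may be distorted",
            stacklevel=3,
        )
    if len(shifts) > 1:
        steps = [
            np.hypot(xs[j + 1] - xs[j], ys[j + 1] - ys[j])
            for j in range(len(shifts) - 1)
        ]
        typical_step = float(np.median([s for s in steps if s > 0] or [0.0]))
        target = resolution_limit(system)
        if typical_step > target:
            warnings.warn(
                f"scan step {typical_step:.2f} um exceeds the targeted "
                f"resolution {target:.2f} um; reconstruction may be distorted",
                stacklevel=3,
            )
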