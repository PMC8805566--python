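"""Blind solver invariants: consistency, convergence, degeneracies, oracle."""

import numpy as np
import pytest
from scipy import fft as sfft

import champ
from champ._shift import box_average, box_adjoint, box_expand, subpixel_shift
from champ.optics import psf as make_psf
from champ.recon import ReconConfig, ReconDivergenceError, reconstruct
from tests.conftest import FINE_PX


@pytest.fixture(scope="module")
def small_recon(noise_free_stack):
    """Ten blind iterations on the shared small noise-free stack."""
    config = ReconConfig(
        iterations=10, upsample=2, psf_mode="gaussian", psf_fwhm=2.9,
        momentum_eta=0.9, seed=1,
    )
    return reconstruct(noise_free_stack, config=config)


class TestBasics:
    def test_shapes_and_nonnegativity(self, small_recon, noise_free_stack):
        u = small_recon.config.upsample
        expected = tuple(u * s for s in noise_free_stack.frames.shape[1:])
        assert small_recon.object.shape == expected
        assert np.all(small_recon.object >= 0)
        assert np.all(small_recon.pattern >= 0)
        assert len(small_recon.error_history) == 10

    def test_misfit_non_increasing_within_tolerance(self, small_recon):
        h = small_recon.error_history
        # momentum may overshoot by a few percent, never more
        assert np.all(h[2:] <= h[1:-1] * 1.05)

    def test_mismatched_trajectory_rejected(self, noise_free_stack):
        from champ.preprocess import ShiftTrajectory

        traj = ShiftTrajectory(shifts=[(0.0, 0.0)] * 3)
        with pytest.raises(ValueError, match="shifts"):
            reconstruct(noise_free_stack, traj)

    def test_all_zero_stack_rejected(self, noise_free_stack, system):
        from champ.simulate import FrameStack

        zeros = FrameStack(
            np.zeros_like(noise_free_stack.frames),
            noise_free_stack.nominal_shifts, system,
        )
        with pytest.raises(ValueError, match="all-zero"):
            reconstruct(zeros, config=ReconConfig(iterations=1))

    def test_non_finite_input_raises_divergence_error(self, noise_free_stack, system):
        from champ.simulate import FrameStack

        bad = noise_free_stack.frames.copy()
        bad[0, 0, 0] = np.nan
        stack = FrameStack(bad, noise_free_stack.nominal_shifts, system)
        config = ReconConfig(iterations=3, upsample=2, psf_mode="gaussian", psf_fwhm=2.9)
        with pytest.raises(ReconDivergenceError) as err:
            reconstruct(stack, config=config)
        assert err.value.iteration == 0
        assert err.value.last_object is not None

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"iterations": 0},
            {"alpha_obj": 0.0},
            {"alpha_pat": 1.5},
            {"momentum_eta": 1.0},
            {"frame_order": "spiral"},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ReconConfig(**kwargs)


class TestModelConsistency:
    def test_resimulation_reproduces_frames_within_two_percent(self, noise_free_stack):
        """Data consistency: pushing the converged (object, pattern) back
        through the solver's forward model reproduces the measurements."""
        config = ReconConfig(
            iterations=30, upsample=2, psf_mode="gaussian", psf_fwhm=2.9,
            momentum_eta=0.9, seed=1,
        )
        res = reconstruct(noise_free_stack, config=config)
        u = config.upsample
        fine_px = noise_free_stack.pixel_size / u
        gy, gx = res.pattern.shape
        fov = res.fov_slice
        half = int(np.ceil(3.0 * 2.9 / fine_px))
        kernel = make_psf(
            noise_free_stack.meta, (2 * half + 1,) * 2, fine_px,
            mode="gaussian", fwhm=2.9, min_samples_per_fwhm=2,
        )
        kpad = np.zeros((gy, gx))
        kpad[: kernel.shape[0], : kernel.shape[1]] = kernel
        kpad = np.roll(kpad, (-half, -half), axis=(0, 1))
        otf = sfft.rfft2(kpad)

        total_err = 0.0
        total = 0.0
        for frame, (sx, sy) in zip(noise_free_stack.frames, noise_free_stack.nominal_shifts):
            p_j = subpixel_shift(res.pattern, (-sy / fine_px, -sx / fine_px))
            psi = res.object_padded * p_j
            model = box_average(
                sfft.irfft2(sfft.rfft2(psi) * otf, s=(gy, gx))[fov], u
            )
            total_err += np.sum((model - frame) ** 2)
            total += np.sum(frame**2)
        assert np.sqrt(total_err / total) < 0.02

    def test_constant_trajectory_offset_shifts_pattern_not_object(self, noise_free_stack):
        """With the object fixed in the specimen frame, adding a constant
        offset to every stage shift re-expresses the same data with the
        pattern translated by that offset; the object is unchanged."""
        from dataclasses import replace as dc_replace

        config = ReconConfig(
            iterations=10, upsample=2, psf_mode="gaussian", psf_fwhm=2.9,
            momentum_eta=0.9, seed=1, pad_px=24,
        )
        base = reconstruct(noise_free_stack, config=config)
        offset = (1.625, 0.0)  # one camera pixel in +x
        shifted_stack = dc_replace(
            noise_free_stack,
            nominal_shifts=[
                (sx + offset[0], sy + offset[1])
                for sx, sy in noise_free_stack.nominal_shifts
            ],
        )
        moved = reconstruct(shifted_stack, config=config)
        n = base.object.shape[0]
        m = n // 4
        sl = (slice(m, n - m), slice(m, n - m))
        assert champ.pearson(base.object[sl], moved.object[sl]) > 0.95
        # the recovered pattern carries the offset: un-shifting it restores
        # agreement with the baseline pattern
        fine_px = base.pixel_size
        back = subpixel_shift(moved.pattern, (0.0, -offset[0] / fine_px))
        r_aligned = champ.pearson(back[base.fov_slice][sl], base.pattern[base.fov_slice][sl])
        r_raw = champ.pearson(moved.pattern[base.fov_slice][sl], base.pattern[base.fov_slice][sl])
        assert r_aligned > r_raw


class TestDegenerateDiversity:
    def test_uniform_pattern_reduces_to_deconvolution(self, nuclei_phantom, system):
        """Pattern fixed at 1 with no translation diversity: the solver is a
        plain multiframe deconvolution of the wide-field image."""
        flat = champ.SpeckleField(
            np.ones((192, 192)), 1.3, 0.0, FINE_PX
        )
        stack = champ.forward_image(
            nuclei_phantom, flat, system, [(0.0, 0.0)] * 4, upsample=4,
            psf_mode="gaussian", psf_fwhm=2.9,
        )
        config = ReconConfig(
            iterations=20, upsample=2, psf_mode="gaussian", psf_fwhm=2.9,
            momentum_eta=0.9, update_pattern=False, seed=0,
        )
        res = reconstruct(stack, config=config)
        truth = box_average(nuclei_phantom.density, 2)
        n = truth.shape[0]
        m = n // 8
        sl = (slice(m, n - m), slice(m, n - m))
        widefield = np.repeat(np.repeat(stack.frames.mean(0), 2, 0), 2, 1)
        r_wf = champ.pearson(widefield[sl], truth[sl])
        r_dec = champ.pearson(res.object[sl], truth[sl])
        assert r_dec > r_wf  # deconvolution sharpens toward the truth
        assert res.error_history[-1] < 1e-3


class TestKnownPatternOracle:
    def test_fixed_point_satisfies_normal_equations(self, system):
        """Known-pattern limit on a 64-square instance: the solver's fixed
        point solves the least-squares normal equations of the linear
        forward model, cross-checked against scipy's LSQR."""
        from scipy.sparse.linalg import LinearOperator, lsqr

        u, cam, pad = 1, 64, 16
        ny = cam * u  # 64-square fine instance
        gy = ny + 2 * pad
        fine_px = 0.8125
        shifts = champ.raster_shifts(3, 1.0)
        # periodic speckle on the padded grid = the solver's pattern space
        pattern = champ.make_speckle((gy, gy), 2.0, fine_px, seed=3).intensity
        obj_true = np.ones((gy, gy))
        fov = (slice(pad, pad + ny), slice(pad, pad + ny))
        phantom = champ.make_phantom(
            "nuclei", (ny, ny), fine_px, seed=2, n_nuclei=3,
            radius_um=(2.0, 3.0), min_separation_um=7.0,
        )
        obj_true[fov] = phantom.density

        # replicate the solver's kernel support exactly
        half = int(np.ceil(3.0 * max(2.9, 4 * fine_px) / fine_px))
        kernel = make_psf(
            system, (2 * half + 1,) * 2, fine_px,
            mode="gaussian", fwhm=2.9, min_samples_per_fwhm=2,
        )
        kpad = np.zeros((gy, gy))
        kpad[: kernel.shape[0], : kernel.shape[1]] = kernel
        kpad = np.roll(kpad, (-half, -half), axis=(0, 1))
        otf = sfft.rfft2(kpad)

        def forward(ovec):
            o = ovec.reshape(gy, gy)
            frames = []
            for sx, sy in shifts:
                p_j = subpixel_shift(pattern, (-sy / fine_px, -sx / fine_px))
                blurred = sfft.irfft2(sfft.rfft2(o * p_j) * otf, s=(gy, gy))
                frames.append(box_average(blurred[fov], u))
            return np.stack(frames).ravel()

        def adjoint(dvec):
            d = dvec.reshape(len(shifts), cam, cam)
            acc = np.zeros((gy, gy))
            for frame, (sx, sy) in zip(d, shifts):
                r = np.zeros((gy, gy))
                r[fov] = box_adjoint(frame, u)
                c = sfft.irfft2(sfft.rfft2(r) * np.conj(otf), s=(gy, gy))
                p_j = subpixel_shift(pattern, (-sy / fine_px, -sx / fine_px))
                acc += p_j * c
            return acc.ravel()

        b = forward(obj_true.ravel())
        from champ.simulate import FrameStack

        stack = FrameStack(
            b.reshape(len(shifts), cam, cam), shifts, system, pixel_size=u * fine_px
        )
        config = ReconConfig(
            iterations=200, upsample=u, psf_mode="gaussian", psf_fwhm=2.9,
            momentum_eta=0.0, update_pattern=False, nonneg=False, pad_px=pad,
            relax=0.5,
        )
        res = reconstruct(stack, config=config, init_pattern=pattern)

        x = res.object_padded.ravel()
        grad = adjoint(forward(x) - b)
        rel = np.linalg.norm(grad) / np.linalg.norm(adjoint(b))
        assert rel < 1e-3

        # brute-force least squares: the engine fits the data to within an
        # order of magnitude of the LSQR oracle, both below 1% relative
        A = LinearOperator((len(b), gy * gy), matvec=forward, rmatvec=adjoint)
        ref = lsqr(A, b, iter_lim=200, atol=1e-12, btol=1e-12)
        misfit_pie = np.linalg.norm(forward(x) - b) / np.linalg.norm(b)
        misfit_lsqr = np.linalg.norm(forward(ref[0]) - b) / np.linalg.norm(b)
        assert misfit_lsqr < 0.01
        assert misfit_pie < 0.01
        assert misfit_pie < 10 * misfit_lsqr


class TestResolutionGain:
    def test_bead_fwhm_improves_at_least_twofold(self, bead_experiment):
        """Blind reconstruction sharpens sub-resolution beads by >= 2x over
        the wide-field image on the default synthetic configuration."""
        assert bead_experiment["n_beads_measured"] >= 10
        assert bead_experiment["improvement"] >= 2.0
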