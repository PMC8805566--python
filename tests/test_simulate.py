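"""Forward-model tests: speckle statistics, phantoms, image formation."""

import numpy as np
import pytest

import champ
from champ.simulate import autocorrelation_fwhm, raster_shifts
from tests.conftest import FINE_PX


class TestSpeckle:
    def test_grain_size_matches_request_within_15_percent(self, small_speckle):
        measured = autocorrelation_fwhm(small_speckle.intensity, FINE_PX)
        assert measured == pytest.approx(1.3, rel=0.15)

    def test_fully_developed_contrast_near_unity(self, small_speckle):
        assert small_speckle.contrast == pytest.approx(1.0, abs=0.15)

    def test_intensity_non_negative_unit_mean(self, small_speckle):
        assert np.all(small_speckle.intensity >= 0)
        assert small_speckle.intensity.mean() == pytest.approx(1.0)

    def test_same_seed_bit_identical(self):
        a = champ.make_speckle((96, 96), 1.3, FINE_PX, seed=7)
        b = champ.make_speckle((96, 96), 1.3, FINE_PX, seed=7)
        np.testing.assert_array_equal(a.intensity, b.intensity)

    def test_different_seed_differs(self):
        a = champ.make_speckle((96, 96), 1.3, FINE_PX, seed=7)
        b = champ.make_speckle((96, 96), 1.3, FINE_PX, seed=8)
        assert not np.array_equal(a.intensity, b.intensity)

    def test_grain_below_grid_resolution_rejected(self):
        with pytest.raises(ValueError, match="grid resolution"):
            champ.make_speckle((96, 96), 0.1, 0.25, seed=1)


class TestPhantoms:
    def test_beads_are_disjoint_and_counted(self):
        ph = champ.make_phantom(
            "beads", (256, 256), 0.25, seed=1, n_beads=20,
            diameter_um=0.5, min_separation_um=4.0, margin_um=3.0,
        )
        n_components = len(np.unique(ph.truth_labels)) - 1
        assert n_components == 20
        assert np.all(ph.density >= 0)
        assert ph.centers.shape == (20, 2)

    def test_nuclei_have_negative_contrast_and_labels(self):
        ph = champ.make_phantom("nuclei", (128, 128), FINE_PX, seed=2, n_nuclei=4)
        inside = ph.density[ph.truth_labels > 0]
        outside = ph.density[ph.truth_labels == 0]
        assert inside.mean() < outside.mean()  # dark nuclei on bright background
        assert len(np.unique(ph.truth_labels)) - 1 == 4

    def test_zero_nuclei_gives_uniform_bright_field(self):
        ph = champ.make_phantom("nuclei", (64, 64), FINE_PX, seed=0, n_nuclei=0)
        assert np.allclose(ph.density, ph.density.flat[0])
        assert ph.truth_labels.max() == 0

    def test_fixed_seed_reproducible(self):
        a = champ.make_phantom("nuclei", (64, 64), FINE_PX, seed=5, n_nuclei=3)
        b = champ.make_phantom("nuclei", (64, 64), FINE_PX, seed=5, n_nuclei=3)
        np.testing.assert_array_equal(a.density, b.density)

    def test_overcrowded_beads_rejected(self):
        with pytest.raises(RuntimeError, match="could not place"):
            champ.make_phantom(
                "beads", (64, 64), 0.25, seed=1, n_beads=500,
                diameter_um=0.5, min_separation_um=5.0,
            )

    def test_siemens_star_is_bounded(self):
        ph = champ.make_phantom("siemens", (128, 128), 0.25, seed=0)
        assert ph.density.min() >= 0
        assert ph.density.max() <= 1.0 + 1e-9

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="unknown phantom kind"):
            champ.make_phantom("worms", (64, 64), 0.25)


class TestForwardModel:
    def test_frame_count_and_shapes_match_raster(self, system, small_speckle):
        ph = champ.make_phantom("nuclei", (128, 128), FINE_PX, seed=3, n_nuclei=2)
        shifts = raster_shifts(6, 1.0)
        stack = champ.forward_image(
            ph, small_speckle, system, shifts, upsample=4,
            psf_mode="gaussian", psf_fwhm=2.9,
        )
        assert len(stack) == 36
        assert stack.frames.shape == (36, 32, 32)
        assert stack.nominal_shifts == shifts
        assert stack.pixel_size == pytest.approx(4 * FINE_PX)

    def test_linearity_in_the_phantom(self, system, small_speckle, small_raster):
        ph1 = champ.make_phantom("nuclei", (128, 128), FINE_PX, seed=3, n_nuclei=2)
        ph2 = champ.make_phantom("nuclei", (128, 128), FINE_PX, seed=4, n_nuclei=3)
        combo = champ.Phantom(2.0 * ph1.density + 0.5 * ph2.density, FINE_PX)
        kw = dict(upsample=4, psf_mode="gaussian", psf_fwhm=2.9)
        f1 = champ.forward_image(ph1, small_speckle, system, small_raster, **kw).frames
        f2 = champ.forward_image(ph2, small_speckle, system, small_raster, **kw).frames
        fc = champ.forward_image(combo, small_speckle, system, small_raster, **kw).frames
        np.testing.assert_allclose(fc, 2.0 * f1 + 0.5 * f2, rtol=1e-10, atol=1e-13)

    def test_zero_phantom_gives_zero_frames(self, system, small_speckle, small_raster):
        ph = champ.Phantom(np.zeros((128, 128)), FINE_PX)
        stack = champ.forward_image(
            ph, small_speckle, system, small_raster, upsample=4,
            psf_mode="gaussian", psf_fwhm=2.9,
        )
        assert np.all(stack.frames == 0)

    def test_uniform_phantom_frames_follow_blurred_speckle(self, system, small_speckle):
        """Multiplicative model: density == c gives c x (blurred, binned speckle)."""
        from scipy.signal import fftconvolve

        from champ._shift import box_average
        from champ.optics import psf as make_psf

        c = 2.5
        ph = champ.Phantom(np.full((128, 128), c), FINE_PX)
        stack = champ.forward_image(
            ph, small_speckle, system, [(0.0, 0.0)], upsample=4,
            psf_mode="gaussian", psf_fwhm=2.9,
        )
        pad = (192 - 128) // 2
        crop = small_speckle.intensity[pad:-pad, pad:-pad]
        half = int(np.ceil(3.0 * 2.9 / FINE_PX))
        kernel = make_psf(system, (2 * half + 1,) * 2, FINE_PX, mode="gaussian", fwhm=2.9)
        expected = c * box_average(fftconvolve(crop, kernel, mode="same"), 4)
        np.testing.assert_allclose(stack.frames[0], expected, rtol=1e-9, atol=1e-12)

    def test_mean_preserved_by_camera_binning(self, noise_free_stack, nuclei_phantom,
                                              small_speckle, system):
        """Energy bookkeeping: binning to the camera grid preserves the mean."""
        from scipy.signal import fftconvolve

        from champ.optics import psf as make_psf

        pad = (192 - 128) // 2
        crop = small_speckle.intensity[pad:-pad, pad:-pad]
        psi = nuclei_phantom.density * crop
        half = int(np.ceil(3.0 * 2.9 / FINE_PX))
        kernel = make_psf(system, (2 * half + 1,) * 2, FINE_PX, mode="gaussian", fwhm=2.9)
        blurred = fftconvolve(psi, kernel, mode="same")
        assert noise_free_stack.frames[0].mean() == pytest.approx(
            blurred.mean(), rel=1e-9
        )

    def test_shift_consistency_with_preshifted_speckle(self, system, nuclei_phantom,
                                                       small_speckle):
        """A stage shift s equals imaging with the pattern pre-shifted by -s."""
        from champ._shift import subpixel_shift

        s = (1.0, -0.5)
        kw = dict(upsample=4, psf_mode="gaussian", psf_fwhm=2.9)
        shifted_frame = champ.forward_image(
            nuclei_phantom, small_speckle, system, [s], **kw
        ).frames[0]
        pre = champ.SpeckleField(
            subpixel_shift(small_speckle.intensity, (-s[1] / FINE_PX, -s[0] / FINE_PX)),
            small_speckle.grain_size, small_speckle.contrast, FINE_PX,
        )
        ref_frame = champ.forward_image(
            nuclei_phantom, pre, system, [(0.0, 0.0)], **kw
        ).frames[0]
        np.testing.assert_allclose(shifted_frame, ref_frame, rtol=0, atol=1e-10)

    def test_shift_off_field_rejected(self, system, nuclei_phantom, small_speckle):
        with pytest.raises(ValueError, match="off the speckle field"):
            champ.forward_image(
                nuclei_phantom, small_speckle, system, [(40.0, 0.0)], upsample=4,
                psf_mode="gaussian", psf_fwhm=2.9,
            )

    def test_noise_is_seeded_and_non_negative(self, system, nuclei_phantom, small_speckle):
        kw = dict(
            upsample=4, psf_mode="gaussian", psf_fwhm=2.9,
            noise_params=(1000.0, 5e-3),
        )
        a = champ.forward_image(nuclei_phantom, small_speckle, system, [(0, 0)], seed=9, **kw)
        b = champ.forward_image(nuclei_phantom, small_speckle, system, [(0, 0)], seed=9, **kw)
        c = champ.forward_image(nuclei_phantom, small_speckle, system, [(0, 0)], seed=10, **kw)
        np.testing.assert_array_equal(a.frames, b.frames)
        assert not np.array_equal(a.frames, c.frames)
        assert np.all(a.frames >= 0)


def test_raster_shifts_row_major_origin_first():
    shifts = raster_shifts(2, 1.5)
    assert shifts == [(0.0, 0.0), (1.5, 0.0), (0.0, 1.5), (1.5, 1.5)]
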