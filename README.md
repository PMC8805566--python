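# champ-microscopy

Blind super-resolution reconstruction for speckle-illuminated
wide-field fluorescence microscopy, with the synthetic forward model
needed to validate it and the downstream quantification used in
label-free computational histology: bead-FWHM resolution calibration,
nuclear morphometrics with rank-sum statistics, and the
cycle-consistent virtual-staining objective.

## The problem

A low-NA objective gives a huge field of view and depth of field —
ideal for rapid, slide-free imaging of thick tissue — but a poor
lateral resolution (here a 2.9-µm bead FWHM). Projecting a constant,
high-contrast laser speckle pattern onto the specimen and raster-
scanning the specimen beneath it mixes high object frequencies into
the detection passband: with detection cut-off `f_obj` and pattern band
`f_pmax`, content up to the synthetic aperture `f_obj + f_pmax`
becomes recoverable, i.e. a resolution of

    d = λ_em / 2 (NA_obj + NA_illu)

(1.11 µm for 445-nm emission with matched 0.1 apertures). Neither the
object `O` nor the exact pattern `P` is known; both are estimated
jointly from the frame stack

    I_j = D_u[ h ∗ ( O · T_{−s_j} P ) ]      j = 1 … 36

by a momentum-assisted, regularized ptychographic iterative engine
(`h` is the detection PSF, `T_{−s_j}` the pattern translation opposite
to the stage shift, and `D_u` the box-average onto the undersampled
camera grid). Ten iterations are the default operating point.

## Worked example

```python
import champ

fine_px = 6.5 / 4 / 4            # simulate at a quarter camera pixel (um)
system  = champ.OpticalSystem()  # 4x / 0.1 NA, 6.5-um camera pitch

phantom = champ.make_phantom("nuclei", (512, 512), fine_px, seed=3, n_nuclei=40)
speckle = champ.make_speckle((640, 640), grain_size=1.3, pixel_size=fine_px, seed=7)
stack   = champ.forward_image(phantom, speckle, system,
                              shifts=champ.raster_shifts(6, 1.0),
                              noise_params=(2e5, 1e-5), upsample=4,
                              psf_mode="gaussian", psf_fwhm=2.9)

flat   = champ.flatten_field(stack)
result = champ.reconstruct(flat, config=champ.ReconConfig(
    iterations=10, upsample=2, psf_mode="gaussian", psf_fwhm=2.9))

print(f"final relative misfit: {result.error_history[-1]:.3e}")
print(f"fine-grid pixel:       {result.pixel_size:.4f} um")
```

prints

```
final relative misfit: 4.780e-04
fine-grid pixel:       0.8125 um
```

— the blind solver explains all but ~0.05% of the frame energy after ten
iterations, and returns the object and the recovered speckle pattern on
a 0.8125-µm grid (twice the camera sampling). The same protocol on a
field of 500-nm beads, with the PSF calibrated so the measured
wide-field bead FWHM is 2.9 µm, gives a reconstructed bead FWHM of
≈1.1 µm — a ≈2.6× resolution improvement (see below).

A command-line interface mirrors the library:

```bash
champ simulate --phantom beads --grain-um 1.3 --grid 6x6 --seed 1 --out stack.tif
champ preprocess stack.tif --out flat.tif
champ reconstruct flat.tif --iters 10 --psf-fwhm-um 2.9 --out champ.tif
champ quantify champ.tif --polarity dark-on-bright --out features.csv
champ compare featA.csv featB.csv --column nn_distance_um
champ stain-smoke --steps 200 --seed 1
```

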