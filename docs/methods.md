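# Methods

## The imaging model

The package models a wide-field fluorescence microscope in which a
constant, fully developed speckle pattern is projected onto the
specimen and the specimen is raster-scanned beneath it. Working in the
specimen's frame of reference, the *j*-th raw frame is

    I_j = D_u[ h * ( O · T_{−s_j} P ) ] + noise

where `O` is the fluorophore density (the object), `P` the illumination
intensity pattern, `T_{−s_j}` translation opposite to the stage shift
`s_j`, `h` the incoherent detection PSF, `*` convolution, and `D_u` the
box-average from the fine reconstruction grid to the camera grid (the
camera pitch undersamples the PSF by design; `D_u` is the sub-sampling
operator that handles the resulting aliasing). Fluorescence is
incoherent, so everything is real and non-negative; no complex phase is
involved.

Mixing by the pattern translates object spatial frequencies into the
detection passband: with detection cut-off `f_obj` and pattern
intensity band `f_pmax`, content up to the synthetic aperture
`f_obj + f_pmax` is in principle recoverable. Equivalently, the
resolution limit is `λ_em / 2(NA_obj + NA_illu)`; with the default
optics (445-nm emission, 0.1-NA detection, illumination NA ≈ 0.102
implied by a 1.3-µm speckle grain) this is 1.11 µm, versus the 2.225-µm
wide-field limit.

## Conventions

Pixels are 0-based; shifts are `(x, y)` in micrometres, `+x` rightwards
(columns), `+y` downwards (rows). Lengths in metadata are µm, except
wavelengths (nm). Sub-pixel translations are exact Fourier-domain phase
ramps; every translated field carries a guard margin so periodic wrap
never reaches the region of interest.

## Synthetic data

`make_speckle` draws a random-phase screen over a circular pupil whose
cut-off is set from the Airy relation `FWHM ≈ 0.5145 / f_cut` and
refined once against the measured intensity-autocorrelation FWHM of a
first realization. The result is fully developed speckle: negative-
exponential intensities, contrast ≈ 1, grain size within a few percent
of the request.

Phantoms:

* `beads` — anti-aliased 0.5-µm disks at non-overlapping random
  positions; used for resolution calibration. The resolution
  experiment places 100 beads in the 208-µm field (≈2.3·10⁻³ µm⁻²,
  a typical calibration-slide density); averaging over ~60 accepted
  fits keeps the run-to-run spread of the mean FWHM small.
* `nuclei` — bright autofluorescent background with dark elliptical
  nuclei (negative nuclear contrast, as with deep-UV excitation where
  nucleotides fluoresce weakly against the cytoplasm), semi-axes 2–4 µm,
  truth labels kept; optional dark textured stripes emulate vessel-like
  confounders for the pre-segmentation stand-in.
* `siemens` — radial sinusoid for frequency-support checks.

The simulator renders on a grid at one quarter of the camera pixel
(0.40625 µm) so the speckle grain and the beads are resolved, then
box-averages 4× to the camera. Noise is Poisson shot noise at a
configurable photon scale plus Gaussian read noise, then clipping at
zero — the standard sCMOS model. What the generator does **not**
emulate: depth-dependent excitation, tissue scattering and
autofluorescence spectra, photobleaching, stage vibration, and hot
pixels; passing tests therefore validate the inversion machinery and
protocol, not robustness to every property of real tissue data.

## Pre-processing

*Flat-field.* The illumination envelope is fitted to the mean frame in
the log domain with an order-2 2D polynomial (default) or estimated by
heavy Gaussian low-pass. The polynomial fit is a linear projection, so
applying the correction twice is a no-op; the low-pass estimator is
kept for envelopes a low-order polynomial cannot describe. The stack's
global mean is preserved.

*Trajectory.* Per-frame shifts are estimated by windowed phase
cross-correlation with sub-pixel refinement (default 1/20 camera
pixel). Every frame is correlated directly against the reference frame:
the scan range (6 µm) is minute compared with the field, so overlap is
never a concern, while chaining successive frames accumulates the
per-pair bias (measured ≈3× worse on the protocol raster). For real
(lab-frame) data the specimen is the moving content; for sample-frame
simulated stacks only the pattern moves, and `moving="pattern"` negates
the measured displacement accordingly. A correlogram peak-ratio test
flags ambiguous frames, which fall back to their nominal shifts.

## Reconstruction

The solver is a momentum-assisted, regularized ptychographic iterative
engine on real intensities. Per frame: form `ψ = O · T_{−s_j}P`, blur,
box-average, compute the residual against the measured frame, expand it
back to the fine grid (replication — the right-inverse of the box
average, which keeps steps on the intensity scale for any `u`), and
back-project through the blur transpose. Object and pattern then
receive relaxed updates with rPIE-style denominators

    O ← O + P_j c / ((1−α_o) P_j² + α_o max P_j²)      α_o = 0.1
    P ← P + O c / ((1−α_p) O² + α_p max O²)            α_p = 0.25

the pattern update using the pre-update object and being translated
back into the pattern's reference frame. After each full pass: optional
non-negativity clamp (default on), pattern renormalization to unit mean
over the field of view (fixing the `O·P` scale ambiguity), and a
heavy-ball momentum step with friction η = 0.9. Initialization: object
= camera-replicated mean frame, pattern = 1. A fixed iteration count
(default 10) keeps runs deterministic; frames are visited in raster
order by default, with an optional random permutation per iteration
that suppresses raster-direction artifacts and measurably improves
long-run fidelity. The reconstruction grid is padded by the maximum
shift plus a PSF support; edges are excluded from all metrics. Optional
extras, off by default: spectral support projections for object and
pattern, and a global step damping `relax` used by the fixed-point
oracle tests.

Numerical notes. The relative data misfit `Σ‖I_j − m_j‖² / Σ‖I_j‖²` is
recorded per iteration. Non-finite iterates abort with the iteration
index and the last stable state. The sequential engine with unit steps
is marginally non-normal; in the unconstrained known-pattern setting it
can drift after deep convergence, which is why the oracle tests damp
the step. The defaults (non-negativity on) were stable in every
experiment up to 500 iterations.

### What the solver can and cannot recover

Two properties of the blind problem, established with an LSQR oracle on
the known-object linear subproblem under the protocol acquisition
(36 frames, 6×6 raster at 1 µm, 2.9-µm detection FWHM, 1.3-µm grain):

* The object is essentially fully identifiable once the pattern is
  known (r ≈ 0.995 to truth).
* The pattern is identifiable only to r ≈ 0.83–0.85 even with the true
  object supplied: its mid-band frequencies are observed only through
  products with the object's (weak) high frequencies, and deeper
  unregularized iteration semi-converges — the misfit stalls at the
  model-realism floor while the estimate wanders in near-null
  directions.

Blind reconstruction at the full protocol field reaches r ≈ 0.85–0.96
to the ground-truth object depending on the phantom and speckle
realization (typically ≈0.92; noise-free, 100 iterations, random frame
order), with the pattern at its ≈0.83 ceiling. Object quality
saturates around iteration 90–100 and then declines slightly. The
package treats pattern fidelity beyond the identifiability ceiling —
and the object error it induces in the mixing band — as properties of
the acquisition protocol rather than solver deficiencies.

On convergence speed: the data misfit keeps decreasing far beyond
iteration 10 — geometrically on noise-free data, and by slowly
absorbing part of the measurement noise otherwise (the unknowns number
roughly 40% of the measurements at `u = 2`). Reconstruction *quality*,
by contrast, is essentially reached within ~10 iterations and
eventually degrades on noisy data as the solver starts fitting noise —
supporting a fixed small iteration budget as the operating point even
though the misfit itself has not plateaued.

## Resolution measurement

Bead FWHMs are measured by least-squares Gaussian-plus-offset fits to
the x and y line profiles through each bead's intensity-weighted
centroid, averaged; fits with r² < 0.8 are flagged and excluded from
means. The wide-field reference is simulated under uniform
illumination; because the finite bead, camera binning and profile
discretization broaden the measured width beyond the raw PSF width, the
Gaussian detection PSF is calibrated in one step so the *measured*
wide-field bead FWHM equals 2.9 µm before the speckle acquisition is
simulated. The reported improvement factor is the ratio of mean
wide-field to mean reconstructed FWHM over all accepted beads.

## Morphometrics and statistics

Segmentation is a declared stand-in for a trained pixel classifier:
polarity-aware Otsu threshold, 8-connected labelling, minimum-area
filter; external label masks are accepted everywhere. Features follow
common practice: area = pixel count × pixel area; centroid = unweighted
member mean; intercellular distance = shortest centroid-to-centroid
distance to any other nucleus (undefined, flagged, for a single
nucleus). When groups of 50 nuclei are compared, the subsample is drawn
with a seeded generator, unmatched between groups.

The two-sided Wilcoxon rank-sum test uses mid-ranks for ties; exact
enumeration of the permutation distribution when both groups have fewer
than 10 observations, otherwise a normal approximation with
tie-corrected variance and a 0.5 continuity correction. Exact and
approximate p-values agree within 0.01 at n = 10 per group, and the
empirical type-I error at p ≤ 0.05 is within ±0.02 of nominal at
n = 50.

## Virtual-staining objective

The composite objective is the weighted sum of two adversarial value
functions, an L1 cycle-consistency term and an SSIM fidelity term, with
λ = 10 on the cycle term and γ = 2 on the SSIM term. The adversarial
expressions are the discriminators' value functions (to be maximized by
D); the trainer minimizes their negation for D and the non-saturating
form for the generators. The cycle norm is printed without a subscript
in the source material's notation; L1 — the standard choice for cycle
consistency — is assumed here. SSIM uses the 11-pixel Gaussian window
with K1 = 0.01, K2 = 0.03 and a joint-min/max dynamic range.

The smoke-scale trainer exists to exercise the objective end to end,
not to produce stained images: generators are single 3×3 linear
convolutions, discriminators one conv + pooled logistic readout, data
are smooth random 16×16 tiles (domain Y contrast-inverted from an
independent source), and optimization is Adam on finite-difference
gradients, fully deterministic under the seed. Two hundred steps
reduce the cycle loss by well over half across seeds.

The brightness pre-segmentation used before staining is likewise a
stand-in: Otsu darkness, then per-component smoothness (normalized
intensity spread) and compactness (axis ratio) separate nucleus
candidates from textured or elongated dark features.

## Desk-scale experiment sizes

The reference experiments run on a 512² simulation grid (208-µm field),
36 frames, reconstruction at `u = 2`: the bead resolution experiment
takes ~15 s, the 100-iteration convergence and blind-fidelity runs
~2 min each on one CPU. These sizes were chosen as the smallest fields
that hold enough beads/nuclei for stable statistics while preserving
the published acquisition geometry exactly.

## Known limitations

* The forward model is 2D; axial structure, depth-dependent excitation
  and surface irregularity are out of scope.
* Pattern recovery is protocol-limited (see above); quantitative claims
  about the recovered speckle should respect the ≈0.83 identifiability
  ceiling.
* The misfit-based convergence diagnostic keeps improving long after
  image quality has saturated; use the fixed iteration budget, not a
  misfit plateau, as the stopping rule.
* The segmentation and pre-segmentation stand-ins are intentionally
  simple; plug in a trained classifier for real tissue.
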