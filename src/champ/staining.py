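"""Composite objective of the cycle-consistent virtual-staining network.

The unpaired image-translation objective combines two adversarial value
functions (one per discriminator), an L1 cycle-consistency term, and an
SSIM fidelity term:

    l(G, F, D_X, D_Y) = L_GAN(G, D_Y) + L_GAN(F, D_X)
                        + lambda * L_cyc(G, F) + gamma * L_ssim(G, F)

with lambda = 10 and gamma = 2 by default. The adversarial terms are
written as the discriminators' value functions (to be maximized by D);
a trainer minimizes their negation for D and the non-saturating form
for the generators. The cycle norm is L1 (the standard choice for cycle
consistency).

The loss code is architecture-agnostic: it consumes arrays produced by
any generator/discriminator. The smoke-scale trainer included here uses
deliberately tiny linear convolutional generators and one-layer
discriminators, optimized with finite-difference gradients — enough to
exercise the full objective end to end, not to produce stained images.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import convolve, gaussian_filter
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops

from .metrics import ssim

__all__ = [
    "LossWeights",
    "LossBreakdown",
    "adversarial_loss",
    "cycle_loss",
    "ssim_loss",
    "total_objective",
    "smoke_train",
    "presegment_brightness",
]

_EPS = 1e-7


@dataclass(frozen=True)
class LossWeights:
    lambda_cyc: float = 10.0
    gamma_ssim: float = 2.0

    def __post_init__(self) -> None:
        if self.lambda_cyc < 0 or self.gamma_ssim < 0:
            raise ValueError("loss weights must be non-negative")


@dataclass
class LossBreakdown:
    l_gan_g: float
    l_gan_f: float
    l_cyc: float
    l_ssim: float
    total: float


def adversarial_loss(d_real: np.ndarray, d_fake: np.ndarray) -> float:
    """Discriminator value function: E[log D(real)] + E[log(1 - D(fake))].

    Outputs must lie in [0, 1] (they are clamped away from the endpoints
    by a small epsilon before the logs). The perfect-discriminator limit
    approaches 0 from below; D == 0.5 everywhere gives 2 log 0.5.
    """
    d_real = np.asarray(d_real, dtype=float)
    d_fake = np.asarray(d_fake, dtype=float)
    for name, d in (("d_real", d_real), ("d_fake", d_fake)):
        if np.any(d < 0) or np.any(d > 1):
            raise ValueError(f"{name} outputs must lie in [0, 1]")
    d_real = np.clip(d_real, _EPS, 1.0 - _EPS)
    d_fake = np.clip(d_fake, _EPS, 1.0 - _EPS)
    return float(np.mean(np.log(d_real)) + np.mean(np.log(1.0 - d_fake)))


def cycle_loss(x, x_cycled, y, y_cycled) -> float:
    """L1 cycle consistency: E|F(G(x)) - x| + E|G(F(y)) - y|."""
    x = np.asarray(x, dtype=float)
    x_cycled = np.asarray(x_cycled, dtype=float)
    y = np.asarray(y, dtype=float)
    y_cycled = np.asarray(y_cycled, dtype=float)
    if x.shape != x_cycled.shape or y.shape != y_cycled.shape:
        raise ValueError("cycled images must match their originals in shape")
    return float(np.mean(np.abs(x_cycled - x)) + np.mean(np.abs(y_cycled - y)))


def _batched(images: np.ndarray) -> np.ndarray:
    images = np.asarray(images, dtype=float)
    return images[None] if images.ndim == 2 else images


def ssim_loss(x, x_translated, y, y_translated) -> float:
    """(1 - E[SSIM(x, G(x))]) + (1 - E[SSIM(y, F(y))]).

    Each direction lies in [0, 2] given SSIM in [-1, 1], so the sum is
    bounded by 4; identical pairs give 0.
    """
    x, gx = _batched(x), _batched(x_translated)
    y, fy = _batched(y), _batched(y_translated)
    if x.shape != gx.shape or y.shape != fy.shape:
        raise ValueError("translated images must match their originals in shape")
    s_x = np.mean([ssim(a, b) for a, b in zip(x, gx)])
    s_y = np.mean([ssim(a, b) for a, b in zip(y, fy)])
    return float((1.0 - s_x) + (1.0 - s_y))


def total_objective(
    l_gan_g: float,
    l_gan_f: float,
    l_cyc: float,
    l_ssim: float,
    weights: LossWeights = LossWeights(),
) -> LossBreakdown:
    """Weighted sum of the four loss components, with the full breakdown."""
    total = (
        l_gan_g
        + l_gan_f
        + weights.lambda_cyc * l_cyc
        + weights.gamma_ssim * l_ssim
    )
    return LossBreakdown(
        l_gan_g=float(l_gan_g),
        l_gan_f=float(l_gan_f),
        l_cyc=float(l_cyc),
        l_ssim=float(l_ssim),
        total=float(total),
    )


# ---------------------------------------------------------------------------
# smoke-scale trainer: tiny linear conv generators, one-layer discriminators


class _ConvGen:
    """Linear 3x3 convolution + bias; 10 parameters."""

    n_params = 10

    @staticmethod
    def apply(params: np.ndarray, batch: np.ndarray) -> np.ndarray:
        kernel = params[:9].reshape(3, 3)
        bias = params[9]
        return np.stack(
            [convolve(img, kernel, mode="nearest") + bias for img in batch]
        )


class _ConvDisc:
    """sigmoid(a * mean(tanh(conv(x, k) + b)) + c); 12 parameters."""

    n_params = 12

    @staticmethod
    def apply(params: np.ndarray, batch: np.ndarray) -> np.ndarray:
        kernel = params[:9].reshape(3, 3)
        b, a, c = params[9], params[10], params[11]
        feats = np.array(
            [np.tanh(convolve(img, kernel, mode="nearest") + b).mean() for img in batch]
        )
        return 1.0 / (1.0 + np.exp(-(a * feats + c)))


def _smooth_tiles(rng: np.random.Generator, n: int, size: int) -> np.ndarray:
    tiles = rng.standard_normal((n, size, size))
    tiles = np.stack([gaussian_filter(t, 2.0) for t in tiles])
    lo = tiles.min(axis=(1, 2), keepdims=True)
    hi = tiles.max(axis=(1, 2), keepdims=True)
    return (tiles - lo) / np.maximum(hi - lo, 1e-12)


def _fd_grad(fun, params: np.ndarray, eps: float = 1e-4) -> np.ndarray:
    base = fun(params)
    grad = np.empty_like(params)
    for i in range(len(params)):
        shifted = params.copy()
        shifted[i] += eps
        grad[i] = (fun(shifted) - base) / eps
    return grad


class _Adam:
    """Minimal Adam optimizer (deterministic, no bias towards any library)."""

    def __init__(self, n: int, lr: float, beta1: float = 0.9, beta2: float = 0.999):
        self.lr, self.b1, self.b2 = lr, beta1, beta2
        self.m = np.zeros(n)
        self.v = np.zeros(n)
        self.t = 0

    def step(self, params: np.ndarray, grad: np.ndarray) -> np.ndarray:
        self.t += 1
        self.m = self.b1 * self.m + (1 - self.b1) * grad
        self.v = self.b2 * self.v + (1 - self.b2) * grad**2
        mhat = self.m / (1 - self.b1**self.t)
        vhat = self.v / (1 - self.b2**self.t)
        return params - self.lr * mhat / (np.sqrt(vhat) + 1e-8)


def smoke_train(
    steps: int = 200,
    seed: int = 0,
    tile: int = 16,
    n_tiles: int = 8,
    batch: int = 2,
    lr_gen: float = 0.02,
    lr_disc: float = 0.1,
    weights: LossWeights = LossWeights(),
) -> dict:
    """Train the toy translation models on synthetic tile pairs.

    Domain X holds smooth grayscale tiles; domain Y holds contrast-
    inverted tiles from an independent source, so the identity map is
    not a solution. Generators and discriminators are updated
    alternately by gradient descent on the composite objective
    (finite-difference gradients; everything is deterministic under the
    seed).

    Returns a dict with the initial and final :class:`LossBreakdown`
    (as dicts), the per-step ``l_cyc`` history, and the learned
    parameter vectors.
    """
    rng = np.random.default_rng(seed)
    x_data = _smooth_tiles(rng, n_tiles, tile)
    y_data = 1.0 - _smooth_tiles(rng, n_tiles, tile)

    pg = rng.normal(0.0, 0.25, _ConvGen.n_params)
    pf = rng.normal(0.0, 0.25, _ConvGen.n_params)
    pdy = rng.normal(0.0, 0.25, _ConvDisc.n_params)
    pdx = rng.normal(0.0, 0.25, _ConvDisc.n_params)

    def breakdown(xb: np.ndarray, yb: np.ndarray, pg, pf, pdy, pdx) -> LossBreakdown:
        gx = _ConvGen.apply(pg, xb)
        fy = _ConvGen.apply(pf, yb)
        x_cyc = _ConvGen.apply(pf, gx)
        y_cyc = _ConvGen.apply(pg, fy)
        l_gan_g = adversarial_loss(_ConvDisc.apply(pdy, yb), _ConvDisc.apply(pdy, gx))
        l_gan_f = adversarial_loss(_ConvDisc.apply(pdx, xb), _ConvDisc.apply(pdx, fy))
        l_cyc = cycle_loss(xb, x_cyc, yb, y_cyc)
        l_ssim = ssim_loss(xb, gx, yb, fy)
        return total_objective(l_gan_g, l_gan_f, l_cyc, l_ssim, weights)

    def gen_objective(pgf: np.ndarray, xb, yb) -> float:
        # non-saturating generator loss + weighted cycle and SSIM terms
        g, f = pgf[: _ConvGen.n_params], pgf[_ConvGen.n_params :]
        gx = _ConvGen.apply(g, xb)
        fy = _ConvGen.apply(f, yb)
        x_cyc = _ConvGen.apply(f, gx)
        y_cyc = _ConvGen.apply(g, fy)
        d_gx = np.clip(_ConvDisc.apply(pdy, gx), _EPS, 1 - _EPS)
        d_fy = np.clip(_ConvDisc.apply(pdx, fy), _EPS, 1 - _EPS)
        gan = -float(np.mean(np.log(d_gx)) + np.mean(np.log(d_fy)))
        return (
            gan
            + weights.lambda_cyc * cycle_loss(xb, x_cyc, yb, y_cyc)
            + weights.gamma_ssim * ssim_loss(xb, gx, yb, fy)
        )

    history = []
    init = breakdown(x_data, y_data, pg, pf, pdy, pdx)
    opt_gen = _Adam(2 * _ConvGen.n_params, lr_gen)
    opt_dy = _Adam(_ConvDisc.n_params, lr_disc)
    opt_dx = _Adam(_ConvDisc.n_params, lr_disc)
    for step in range(steps):
        idx = rng.choice(n_tiles, size=batch, replace=False)
        xb, yb = x_data[idx], y_data[idx]

        # discriminators: minimize the negated value function
        fake_y = _ConvGen.apply(pg, xb)
        fake_x = _ConvGen.apply(pf, yb)
        pdy = opt_dy.step(pdy, _fd_grad(
            lambda p: -adversarial_loss(_ConvDisc.apply(p, yb), _ConvDisc.apply(p, fake_y)),
            pdy,
        ))
        pdx = opt_dx.step(pdx, _fd_grad(
            lambda p: -adversarial_loss(_ConvDisc.apply(p, xb), _ConvDisc.apply(p, fake_x)),
            pdx,
        ))
        # generators: joint descent on the composite objective
        pgf = np.concatenate([pg, pf])
        pgf = opt_gen.step(pgf, _fd_grad(lambda p: gen_objective(p, xb, yb), pgf))
        pg, pf = pgf[: _ConvGen.n_params], pgf[_ConvGen.n_params :]

        x_cyc = _ConvGen.apply(pf, _ConvGen.apply(pg, x_data))
        y_cyc = _ConvGen.apply(pg, _ConvGen.apply(pf, y_data))
        history.append(cycle_loss(x_data, x_cyc, y_data, y_cyc))

    final = breakdown(x_data, y_data, pg, pf, pdy, pdx)
    return {
        "initial": vars(init),
        "final": vars(final),
        "l_cyc_history": history,
        "params": {"G": pg, "F": pf, "D_Y": pdy, "D_X": pdx},
    }


def presegment_brightness(
    image: np.ndarray,
    polarity: str = "dark-on-bright",
    texture_threshold: float = 0.12,
    elongation_threshold: float = 4.0,
) -> np.ndarray:
    """Brightness + local-texture pre-segmentation before virtual staining.

    Labels pixels 0 = background, 1 = nucleus candidate, 2 = dark
    non-nucleus feature. Dark regions (after polarity handling) are
    extracted by Otsu thresholding; each connected component is kept as
    a nucleus candidate only if its interior is smooth (normalized
    intensity spread below ``texture_threshold``) and its shape compact
    (major/minor axis ratio below ``elongation_threshold``); textured or
    elongated dark features — vessels, folds — are labelled separately.

    This is a stand-in for a trained pixel classifier; any external
    classifier producing the same three-way mask can replace it.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a single-channel 2D image")
    if polarity == "bright-on-dark":
        img = img.max() - img
    elif polarity != "dark-on-bright":
        raise ValueError(f"unknown polarity {polarity!r}")
    out = np.zeros(img.shape, dtype=np.int32)
    span = float(np.ptp(img))
    if span == 0:
        return out
    dark = img < threshold_otsu(img)
    labels = cc_label(dark, connectivity=2)
    for region in regionprops(labels):
        member = labels == region.label
        texture = float(img[member].std()) / span
        minor = max(region.axis_minor_length, 1.0)
        elongation = region.axis_major_length / minor
        is_nucleus = texture < texture_threshold and elongation < elongation_threshold
        out[member] = 1 if is_nucleus else 2
    return out
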