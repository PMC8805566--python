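"""Shared synthetic fixtures: small optical systems, speckles and stacks.

Everything is generated at test time from fixed seeds; module/session
scope is used for the expensive simulated acquisitions so several tests
can share one stack.
"""

from __future__ import annotations

import numpy as np
import pytest

import champ
from champ.simulate import FrameStack

# A scaled-down system used by most unit tests: same optics as the full
# instrument but a small field of view so simulations stay fast.
FINE_PX = 6.5 / 4 / 4  # um; simulation grid at a quarter camera pixel


@pytest.fixture(scope="session")
def system() -> champ.OpticalSystem:
    return champ.OpticalSystem()


@pytest.fixture(scope="session")
def small_speckle() -> champ.SpeckleField:
    return champ.make_speckle((192, 192), 1.3, FINE_PX, seed=7)


@pytest.fixture(scope="session")
def nuclei_phantom() -> champ.Phantom:
    return champ.make_phantom(
        "nuclei", (128, 128), FINE_PX, seed=3, n_nuclei=5,
        radius_um=(2.0, 3.5), min_separation_um=7.0,
    )


@pytest.fixture(scope="session")
def small_raster() -> list[tuple[float, float]]:
    return champ.raster_shifts(3, 1.0)


@pytest.fixture(scope="session")
def noise_free_stack(nuclei_phantom, small_speckle, system, small_raster) -> FrameStack:
    """9-frame noise-free acquisition of the small nuclei phantom."""
    return champ.forward_image(
        nuclei_phantom, small_speckle, system, small_raster,
        noise_params=(0.0, 0.0), upsample=4,
        psf_mode="gaussian", psf_fwhm=2.9,
    )


@pytest.fixture(scope="session")
def full_raster() -> list[tuple[float, float]]:
    return champ.raster_shifts(6, 1.0)


@pytest.fixture(scope="session")
def full_nuclei_acquisition(system, full_raster):
    """36-frame noise-free acquisition at the protocol's geometry.

    Returns (phantom, speckle, guard pad in px, stack); shared by the
    registration, reconstruction and acceptance tests.
    """
    n = 256
    pad = 48
    phantom = champ.make_phantom("nuclei", (n, n), FINE_PX, seed=3, n_nuclei=12)
    speckle = champ.make_speckle((n + 2 * pad, n + 2 * pad), 1.3, FINE_PX, seed=7)
    stack = champ.forward_image(
        phantom, speckle, system, full_raster,
        noise_params=(0.0, 0.0), upsample=4,
        psf_mode="gaussian", psf_fwhm=2.9, seed=5,
    )
    return phantom, speckle, pad, stack


@pytest.fixture(scope="session")
def bead_experiment() -> dict:
    """One full-protocol bead resolution run, shared by the resolution-gain
    invariant and the acceptance checks (it is the expensive part)."""
    from champ.experiments import bead_resolution_experiment

    return bead_resolution_experiment(seed=1)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
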