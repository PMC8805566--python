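"""Readers and writers: multi-page float TIFF stacks with YAML sidecars.

Raw and reconstructed images travel as 32-bit float grayscale TIFF;
acquisition metadata (scan shifts in um, optics, noise parameters) lives
in a YAML sidecar next to the stack so the TIFF tags stay untouched.
Estimated trajectories are written under a separate key, so nominal and
estimated shifts coexist.
"""

from __future__ import annotations

import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .optics import OpticalSystem
from .preprocess import ShiftTrajectory
from .simulate import FrameStack

__all__ = ["read_stack", "write_stack", "sidecar_path", "write_trajectory"]

log = logging.getLogger(__name__)


def sidecar_path(stack_path: str | Path) -> Path:
    return Path(stack_path).with_suffix(".yaml")


def write_stack(stack: FrameStack, path: str | Path, sidecar: str | Path | None = None) -> Path:
    """Write frames as a multi-page 32-bit float TIFF plus a YAML sidecar."""
    path = Path(path)
    # explicit photometric: 3/4-frame stacks must not be inferred as RGB(A)
    tifffile.imwrite(path, np.asarray(stack.frames, dtype=np.float32), photometric="minisblack")
    meta = {
        "shifts_um_nominal": [list(map(float, s)) for s in stack.nominal_shifts],
        "optics": asdict(stack.meta),
        "noise_params": list(map(float, stack.noise_params)),
        "pixel_size_um": float(stack.pixel_size),
    }
    side = Path(sidecar) if sidecar is not None else sidecar_path(path)
    side.write_text(yaml.safe_dump(meta, sort_keys=False))
    return side


def read_stack(path: str | Path, sidecar: str | Path | None = None) -> FrameStack:
    """Read a TIFF stack and its YAML sidecar back into a FrameStack.

    A missing sidecar loads the frames with default optics and zero
    nominal shifts (a warning is logged). RGB pages are rejected with a
    conversion hint; pages of inconsistent shape report the page index.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        pages = [p.asarray() for p in tif.pages]
    for idx, page in enumerate(pages):
        if page.ndim == 3:
            raise ValueError(
                f"page {idx} is multi-channel (shape {page.shape}); convert the "
                "stack to single-channel grayscale first"
            )
        if page.shape != pages[0].shape:
            raise ValueError(
                f"page {idx} shape {page.shape} differs from page 0 {pages[0].shape}"
            )
    frames = np.stack(pages)

    side = Path(sidecar) if sidecar is not None else sidecar_path(path)
    if not side.exists():
        log.warning("no sidecar at %s: using default optics and zero shifts", side)
        return FrameStack(
            frames=frames,
            nominal_shifts=[(0.0, 0.0)] * len(frames),
            meta=OpticalSystem(),
        )
    meta = yaml.safe_load(side.read_text())
    optics = OpticalSystem(**meta["optics"])
    noise = tuple(meta.get("noise_params", (0.0, 0.0)))
    stack = FrameStack(
        frames=frames,
        nominal_shifts=[tuple(s) for s in meta["shifts_um_nominal"]],
        meta=optics,
        noise_params=noise,  # type: ignore[arg-type]
        pixel_size=meta.get("pixel_size_um"),
    )
    return stack


def write_trajectory(trajectory: ShiftTrajectory, sidecar: str | Path) -> None:
    """Append the estimated trajectory to an existing sidecar."""
    side = Path(sidecar)
    meta = yaml.safe_load(side.read_text()) if side.exists() else {}
    meta["shifts_um_estimated"] = [list(map(float, s)) for s in trajectory.shifts]
    meta["trajectory_reference_index"] = trajectory.reference_index
    if trajectory.residual_to_nominal is not None:
        meta["trajectory_residual_um"] = [float(r) for r in trajectory.residual_to_nominal]
    side.write_text(yaml.safe_dump(meta, sort_keys=False))
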