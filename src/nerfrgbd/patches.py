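"""Multiresolution patch sampling over training frames.

Training draws random (M, N) pixel patches rather than independent rays so
that horizontal/vertical depth gradients — and hence surface normals — are
defined within every optimisation step.  Patches are drawn at ``p_levels``
resolutions; at level ``l`` the patch pixels are ``2**l`` apart, so coarse
levels supervise normals over larger spatial baselines.  Strided patches
index the target images at the strided pixel locations (no averaging).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .scene import CameraModel, RGBDFrame

__all__ = ["PatchSpec", "sample_patch", "patch_pixels", "patch_to_rays", "gather_patch_targets"]


@dataclass
class PatchSpec:
    """A strided patch anchored at ``(row, col)`` on one frame."""

    frame_index: int
    row: int
    col: int
    m: int = 8
    n: int = 8
    level: int = 0

    @property
    def stride(self) -> int:
        return 1 << self.level


def _max_anchor(size: int, count: int, stride: int) -> int:
    """Largest valid top-left coordinate along one axis (inclusive)."""
    return size - ((count - 1) * stride + 1)


def sample_patch(
    frame_index: int,
    height: int,
    width: int,
    m: int,
    n: int,
    p_levels: int,
    rng: np.random.Generator,
) -> PatchSpec:
    """Draw a level uniformly from {0..p_levels-1} and a uniform valid anchor."""
    feasible = [
        l
        for l in range(p_levels)
        if _max_anchor(height, m, 1 << l) >= 0 and _max_anchor(width, n, 1 << l) >= 0
    ]
    if len(feasible) < p_levels:
        raise ValueError(
            f"image {height}x{width} too small for a {m}x{n} patch at all "
            f"{p_levels} levels; feasible levels: {feasible}"
        )
    level = int(rng.integers(0, p_levels))
    stride = 1 << level
    row = int(rng.integers(0, _max_anchor(height, m, stride) + 1))
    col = int(rng.integers(0, _max_anchor(width, n, stride) + 1))
    return PatchSpec(frame_index=frame_index, row=row, col=col, m=m, n=n, level=level)


def patch_pixels(spec: PatchSpec) -> tuple[np.ndarray, np.ndarray]:
    """(rows, cols) integer grids of shape (M, N) for the strided patch."""
    rows = spec.row + np.arange(spec.m)[:, None] * spec.stride
    cols = spec.col + np.arange(spec.n)[None, :] * spec.stride
    return np.broadcast_to(rows, (spec.m, spec.n)), np.broadcast_to(cols, (spec.m, spec.n))


def patch_to_rays(spec: PatchSpec, cam: CameraModel) -> tuple[np.ndarray, np.ndarray]:
    """World-frame (origins, directions), each of shape (M, N, 3)."""
    rows, cols = patch_pixels(spec)
    if rows.max() >= cam.height or cols.max() >= cam.width:
        raise ValueError("patch extends outside the image")
    return cam.rays_for_pixels(rows, cols)


def gather_patch_targets(spec: PatchSpec, frame: RGBDFrame) -> dict:
    """Supervision targets at the strided patch pixels.

    Returns colour ``C``, metric sensor depth ``D_sensor`` with its validity
    mask (sensor value 0 means no measurement), and relative-scale dense
    depth ``D_dense``.
    """
    rows, cols = patch_pixels(spec)
    sensor = frame.sensor_depth[rows, cols]
    return {
        "C": frame.color[rows, cols],
        "D_sensor": sensor,
        "valid": sensor > 0,
        "D_dense": frame.dense_depth[rows, cols],
    }
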