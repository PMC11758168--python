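"""Supervision losses: colour, masked sensor-depth, and surface normals
derived from depth gradients.

The normal operator builds, per patch pixel, the vector ``(d D/dx, d D/dy, 1)``
from finite differences of the depth map and normalises it to unit length.
It is exactly invariant to additive depth offsets and only weakly sensitive
to multiplicative rescaling, which is what makes relative-scale dense depth
usable as a supervision signal next to metric rendered depth.  Losses are
sums over patch rays (squared errors), matching the weighting the default
loss weights were calibrated for; mean-reduced values are provided for
logging.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LossWeights",
    "color_loss",
    "color_loss_grad",
    "depth_loss",
    "depth_loss_grad",
    "normals_from_depth",
    "normal_loss",
    "normal_loss_grad_wrt_depth",
    "total_loss",
]


@dataclass
class LossWeights:
    """Weights of the depth (alpha) and normal (beta) terms."""

    alpha: float = 0.5
    beta: float = 0.5

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("loss weights must be non-negative")


def _check_same_shape(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")


def color_loss(C_hat: np.ndarray, C: np.ndarray) -> float:
    """Sum over rays of the squared colour error ||C_hat - C||^2."""
    C_hat = np.asarray(C_hat, dtype=np.float64)
    C = np.asarray(C, dtype=np.float64)
    _check_same_shape(C_hat, C)
    return float(((C_hat - C) ** 2).sum())


def color_loss_grad(C_hat: np.ndarray, C: np.ndarray) -> np.ndarray:
    return 2.0 * (np.asarray(C_hat, dtype=np.float64) - np.asarray(C, dtype=np.float64))


def depth_loss(D_hat: np.ndarray, D_sensor: np.ndarray, valid: np.ndarray | None = None) -> float:
    """Squared depth error summed over rays with a valid ToF measurement.

    Pixels where the sensor reported 0 (missing) carry no depth supervision;
    with no valid pixel at all the loss is 0.
    """
    D_hat = np.asarray(D_hat, dtype=np.float64)
    D_sensor = np.asarray(D_sensor, dtype=np.float64)
    _check_same_shape(D_hat, D_sensor)
    if np.any(D_sensor < 0):
        raise ValueError("sensor depth must be non-negative")
    if valid is None:
        valid = D_sensor > 0
    return float((valid * (D_hat - D_sensor) ** 2).sum())


def depth_loss_grad(D_hat: np.ndarray, D_sensor: np.ndarray, valid: np.ndarray | None = None) -> np.ndarray:
    D_hat = np.asarray(D_hat, dtype=np.float64)
    D_sensor = np.asarray(D_sensor, dtype=np.float64)
    if valid is None:
        valid = D_sensor > 0
    return 2.0 * valid * (D_hat - D_sensor)


# ---------------------------------------------------------------------------
# surface normals


def _depth_gradients(D: np.ndarray, pixel_spacing: float, stencil: str):
    """Finite-difference gradients on the patch grid.

    forward: defined on the (M-1, N-1) support (top-left corner of each cell);
    central: defined on the (M-2, N-2) interior.
    """
    D = np.asarray(D, dtype=np.float64)
    if D.ndim != 2 or D.shape[0] < 2 or D.shape[1] < 2:
        raise ValueError("need a depth patch of at least 2x2 pixels")
    h = float(pixel_spacing)
    if stencil == "forward":
        gx = (D[:-1, 1:] - D[:-1, :-1]) / h
        gy = (D[1:, :-1] - D[:-1, :-1]) / h
    elif stencil == "central":
        if D.shape[0] < 3 or D.shape[1] < 3:
            raise ValueError("central stencil needs at least a 3x3 patch")
        gx = (D[1:-1, 2:] - D[1:-1, :-2]) / (2.0 * h)
        gy = (D[2:, 1:-1] - D[:-2, 1:-1]) / (2.0 * h)
    else:
        raise ValueError(f"unknown stencil {stencil!r}")
    return gx, gy


def normals_from_depth(D: np.ndarray, pixel_spacing: float = 1.0, stencil: str = "forward") -> np.ndarray:
    """Per-pixel unit normals ``(dD/dx, dD/dy, 1) / ||.||`` from a depth patch.

    ``pixel_spacing`` is the physical spacing of adjacent patch pixels (the
    patch stride for strided patches), so multi-resolution patches probe the
    surface at different scales.  The third component is positive everywhere
    (front-facing convention).  Exactly invariant to ``D -> D + b``.
    """
    gx, gy = _depth_gradients(D, pixel_spacing, stencil)
    v = np.stack([gx, gy, np.ones_like(gx)], axis=-1)
    n = v / np.linalg.norm(v, axis=-1, keepdims=True)
    return n


def normal_loss(N_hat: np.ndarray, N: np.ndarray) -> float:
    """Sum of squared normal-vector differences over the patch support."""
    N_hat = np.asarray(N_hat, dtype=np.float64)
    N = np.asarray(N, dtype=np.float64)
    _check_same_shape(N_hat, N)
    return float(((N_hat - N) ** 2).sum())


def normal_loss_grad_wrt_depth(
    D_hat: np.ndarray,
    N_target: np.ndarray,
    pixel_spacing: float = 1.0,
    stencil: str = "forward",
) -> tuple[float, np.ndarray]:
    """Normal loss between normals-of-``D_hat`` and a target normal map,
    with its gradient w.r.t. the depth patch.

    Chain: depth -> finite-difference gradients -> normalisation -> loss.
    """
    D_hat = np.asarray(D_hat, dtype=np.float64)
    gx, gy = _depth_gradients(D_hat, pixel_spacing, stencil)
    v = np.stack([gx, gy, np.ones_like(gx)], axis=-1)
    inv_norm = 1.0 / np.linalg.norm(v, axis=-1, keepdims=True)
    n = v * inv_norm
    diff = n - np.asarray(N_target, dtype=np.float64)
    loss = float((diff**2).sum())
    # d loss / dn = 2 diff;  dn/dv = (I - n n^T) / ||v||
    dn = 2.0 * diff
    dv = (dn - n * (n * dn).sum(axis=-1, keepdims=True)) * inv_norm
    h = float(pixel_spacing)
    dD = np.zeros_like(D_hat)
    if stencil == "forward":
        dgx = dv[..., 0] / h
        dgy = dv[..., 1] / h
        dD[:-1, 1:] += dgx
        dD[:-1, :-1] -= dgx
        dD[1:, :-1] += dgy
        dD[:-1, :-1] -= dgy
    else:  # central
        dgx = dv[..., 0] / (2.0 * h)
        dgy = dv[..., 1] / (2.0 * h)
        dD[1:-1, 2:] += dgx
        dD[1:-1, :-2] -= dgx
        dD[2:, 1:-1] += dgy
        dD[:-2, 1:-1] -= dgy
    return loss, dD


def total_loss(L_color: float, L_depth: float, L_normal: float, w: LossWeights | None = None) -> float:
    """Weighted total ``L_color + alpha * L_depth + beta * L_normal``."""
    w = w or LossWeights()
    for L in (L_color, L_depth, L_normal):
        if L < 0:
            raise ValueError("losses must be non-negative")
    return float(L_color + w.alpha * L_depth + w.beta * L_normal)
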