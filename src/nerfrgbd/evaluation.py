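"""Image-quality evaluation: PSNR/SSIM, novel-view trajectories, and the
held-out-view and even-frames protocols.

PSNR uses peak 1.0 on float images in [0, 1].  SSIM follows the standard
formulation (11x11 Gaussian window, sigma 1.5, K1=0.01, K2=0.03) on the
luma channel, computed via scikit-image.  Depth errors are evaluated on
pixels with a valid (non-zero) sensor measurement, consistent with the
masking of the depth loss.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage.metrics import structural_similarity

from .scene import CameraModel, SceneManifest, load_frame
from .training import Checkpoint, render_image

__all__ = [
    "psnr",
    "ssim",
    "EvalReport",
    "circle_trajectory",
    "render_trajectory",
    "evaluate_protocol",
]

_LUMA = np.array([0.299, 0.587, 0.114])


def psnr(a: np.ndarray, b: np.ndarray, peak: float = 1.0) -> float:
    """Peak signal-to-noise ratio in dB; identical images give +inf."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    mse = float(((a - b) ** 2).mean())
    if mse == 0.0:
        return float("inf")
    return float(10.0 * np.log10(peak**2 / mse))


def _to_luma(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img, dtype=np.float64)
    if img.ndim == 3:
        return img @ _LUMA
    return img


def ssim(a: np.ndarray, b: np.ndarray) -> float:
    """Structural similarity on the luma channel, data range 1.0."""
    ga, gb = _to_luma(a), _to_luma(b)
    if ga.shape != gb.shape:
        raise ValueError(f"shape mismatch: {ga.shape} vs {gb.shape}")
    if min(ga.shape) < 11:
        raise ValueError("image smaller than the 11x11 SSIM window")
    return float(
        structural_similarity(
            ga, gb, data_range=1.0, gaussian_weights=True, sigma=1.5,
            use_sample_covariance=False, K1=0.01, K2=0.03,
        )
    )


@dataclass
class EvalReport:
    """Per-view metrics plus aggregates."""

    rows: list[dict] = field(default_factory=list)

    def add(self, **kw) -> None:
        self.rows.append(kw)

    def aggregate(self) -> dict:
        out = {}
        keys = [k for k in (self.rows[0] if self.rows else {}) if isinstance(self.rows[0][k], (int, float))]
        for k in keys:
            vals = np.array([r[k] for r in self.rows], dtype=np.float64)
            finite = vals[np.isfinite(vals)]
            if finite.size:
                out[f"{k}_mean"] = float(finite.mean())
                out[f"{k}_sd"] = float(finite.std(ddof=1)) if finite.size > 1 else 0.0
        return out

    def to_dict(self) -> dict:
        return {"views": self.rows, "aggregates": self.aggregate()}

    def save(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


# ---------------------------------------------------------------------------
# trajectories


def circle_trajectory(
    template: CameraModel,
    center: np.ndarray,
    radius: float,
    height: float,
    n_frames: int,
    theta_start: float = 0.0,
    sweep: float = 360.0,
) -> list[CameraModel]:
    """Cameras on a circular path around ``center``, all facing it.

    ``theta_start`` (degrees) positions the first pose — typically at a
    training camera's azimuth so the sweep starts from a seen view.
    """
    center = np.asarray(center, dtype=np.float64)
    cams = []
    for k in range(n_frames):
        theta = np.deg2rad(theta_start + sweep * k / max(n_frames, 1))
        eye = center + np.array([radius * np.cos(theta), radius * np.sin(theta), 0.0])
        eye[2] = height
        z = center - eye
        z /= np.linalg.norm(z)
        up = np.array([0.0, 0.0, 1.0])
        x = np.cross(-up, z)
        nx = np.linalg.norm(x)
        x = np.array([1.0, 0.0, 0.0]) if nx < 1e-9 else x / nx
        y = np.cross(z, x)
        cams.append(
            CameraModel(
                camera_id=f"traj{k}",
                fx=template.fx, fy=template.fy, cx=template.cx, cy=template.cy,
                width=template.width, height=template.height,
                rotation=np.stack([x, y, z], axis=1), translation=eye,
                near=template.near, far=template.far,
            )
        )
    return cams


def render_trajectory(ckpt: Checkpoint, trajectory: list[CameraModel], t: int = 1,
                      S: int | None = None) -> list[tuple[np.ndarray, np.ndarray]]:
    """One (color, depth) frame per trajectory pose."""
    S = S or int(ckpt.meta.get("samples_per_ray", 128))
    return [render_image(ckpt.model, cam, t=t, S=S) for cam in trajectory]


# ---------------------------------------------------------------------------
# protocols


def _view_metrics(render_c, render_d, frame, lpips_fn=None) -> dict:
    valid = frame.sensor_depth > 0
    out = {
        "psnr": psnr(render_c, frame.color),
        "ssim": ssim(render_c, frame.color),
    }
    if lpips_fn is not None:
        out["lpips"] = float(lpips_fn(render_c, frame.color))
    if valid.any():
        err = render_d[valid] - frame.sensor_depth[valid]
        out["depth_mae"] = float(np.abs(err).mean())
        out["depth_rmse"] = float(np.sqrt((err**2).mean()))
    return out


def evaluate_protocol(ckpt: Checkpoint, manifest: SceneManifest, protocol: str,
                      S: int | None = None, lpips_fn=None) -> EvalReport:
    """Run an evaluation protocol against ground-truth frames.

    ``holdout-view``: metrics on every frame not used in training (the
    excluded camera).  ``even-frames``: metrics at even time indices from the
    training camera poses, reported per t as a time series.  ``train-views``:
    metrics on the training frames themselves.

    ``lpips_fn(a, b) -> float`` is an optional hook for a learned perceptual
    metric; it needs pretrained network weights and is therefore not part of
    the core package.
    """
    S = S or int(ckpt.meta.get("samples_per_ray", 128))
    trained = set(ckpt.meta.get("train_frame_indices", []))
    report = EvalReport()
    for i, (rec, cam) in enumerate(manifest.iter_frames()):
        if protocol == "holdout-view":
            take = i not in trained
        elif protocol == "even-frames":
            take = rec.t % 2 == 0 and (ckpt.meta.get("holdout_camera") != rec.camera_id)
        elif protocol == "train-views":
            take = i in trained
        else:
            raise ValueError(f"unknown protocol {protocol!r}")
        if not take:
            continue
        frame = load_frame(manifest, rec)
        color, depth = render_image(ckpt.model, cam, t=rec.t, S=S)
        report.add(camera_id=rec.camera_id, t=rec.t,
                   **_view_metrics(color, depth, frame, lpips_fn=lpips_fn))
    if not report.rows:
        raise ValueError(f"protocol {protocol!r} selects no evaluation frames")
    return report
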