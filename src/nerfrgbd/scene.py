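"""Scene data model: cameras, RGB-D frames, rays, and the JSON manifest.

Conventions
-----------
* Right-handed coordinates; the camera looks down +z in its own frame.
* Pixels are 0-based ``(row, col)``; a ray passes through the pixel centre
  located at integer coordinates, i.e. pixel (r, c) maps to the camera-frame
  direction ``((c - cx)/fx, (r - cy)/fy, 1)``.
* All metric quantities are metres.  16-bit depth PNGs are millimetres
  (Azure-Kinect dialect); float TIFF depth maps are metres.  A sensor-depth
  value of exactly 0 means "no measurement".
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import imageio.v3 as iio
import numpy as np
import tifffile

__all__ = [
    "CameraModel",
    "Ray",
    "FrameRecord",
    "RGBDFrame",
    "SceneManifest",
    "load_manifest",
    "save_manifest",
    "load_frame",
    "write_rendered_frame",
    "read_color_png",
    "write_color_png",
    "read_depth",
    "write_depth_png",
]

_ROT_TOL = 1e-6


class ManifestError(ValueError):
    """Raised when a manifest or a referenced file fails validation."""


@dataclass
class CameraModel:
    """Pinhole camera with a rigid world-from-camera pose and ray bounds."""

    camera_id: str
    fx: float
    fy: float
    cx: float
    cy: float
    width: int
    height: int
    rotation: np.ndarray  # (3,3) world-from-camera
    translation: np.ndarray  # (3,) camera centre in world frame
    near: float
    far: float

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=np.float64).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=np.float64).reshape(3)
        if not (self.fx > 0 and self.fy > 0):
            raise ManifestError(f"camera {self.camera_id}: focal lengths must be positive")
        if not (0 < self.near < self.far):
            raise ManifestError(f"camera {self.camera_id}: need 0 < near < far")
        err = np.abs(self.rotation @ self.rotation.T - np.eye(3)).max()
        if err > _ROT_TOL or abs(np.linalg.det(self.rotation) - 1.0) > _ROT_TOL:
            raise ManifestError(
                f"camera {self.camera_id}: rotation is not a proper orthonormal matrix "
                f"(orthogonality error {err:.2e})"
            )

    # -- ray geometry -------------------------------------------------------

    def pixel_to_ray(self, row: int | np.ndarray, col: int | np.ndarray, t: int = 1) -> "Ray":
        """Cast the world-frame ray through pixel centre ``(row, col)``."""
        row_a = np.asarray(row)
        col_a = np.asarray(col)
        if np.any(row_a < 0) or np.any(row_a >= self.height) or np.any(col_a < 0) or np.any(col_a >= self.width):
            raise IndexError(
                f"pixel ({row}, {col}) outside image of size {self.height}x{self.width}"
            )
        origins, dirs = self.rays_for_pixels(row_a, col_a)
        return Ray(origin=origins, direction=dirs, pixel=(row_a, col_a), t=t)

    def rays_for_pixels(self, rows: np.ndarray, cols: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Vectorised origins/directions for arrays of pixel coordinates."""
        rows = np.asarray(rows, dtype=np.float64)
        cols = np.asarray(cols, dtype=np.float64)
        x = (cols - self.cx) / self.fx
        y = (rows - self.cy) / self.fy
        d_cam = np.stack([x, y, np.ones_like(x)], axis=-1)
        d_world = d_cam @ self.rotation.T
        d_world /= np.linalg.norm(d_world, axis=-1, keepdims=True)
        origin = np.broadcast_to(self.translation, d_world.shape).copy()
        return origin, d_world

    def project(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """World points -> pixel ``(rows, cols)`` (float, may be off-image)."""
        p = np.atleast_2d(np.asarray(points, dtype=np.float64))
        q = (p - self.translation) @ self.rotation
        rows = self.cy + self.fy * q[:, 1] / q[:, 2]
        cols = self.cx + self.fx * q[:, 0] / q[:, 2]
        return rows, cols

    def to_dict(self) -> dict:
        return {
            "id": self.camera_id,
            "fx": self.fx,
            "fy": self.fy,
            "cx": self.cx,
            "cy": self.cy,
            "width": self.width,
            "height": self.height,
            "rotation": self.rotation.tolist(),
            "translation": self.translation.tolist(),
            "near": self.near,
            "far": self.far,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CameraModel":
        return cls(
            camera_id=str(d["id"]),
            fx=float(d["fx"]),
            fy=float(d["fy"]),
            cx=float(d["cx"]),
            cy=float(d["cy"]),
            width=int(d["width"]),
            height=int(d["height"]),
            rotation=np.asarray(d["rotation"], dtype=np.float64),
            translation=np.asarray(d["translation"], dtype=np.float64),
            near=float(d["near"]),
            far=float(d["far"]),
        )


@dataclass
class Ray:
    """A world-frame ray (or an array of rays) with its pixel provenance."""

    origin: np.ndarray
    direction: np.ndarray
    pixel: tuple
    t: int = 1


@dataclass
class FrameRecord:
    """Manifest entry pointing at the image files of one RGB-D frame."""

    camera_id: str
    t: int
    color_path: str
    sensor_depth_path: str
    dense_depth_path: str
    true_depth_path: str | None = None

    def to_dict(self) -> dict:
        d = {
            "camera_id": self.camera_id,
            "t": self.t,
            "color": self.color_path,
            "sensor_depth": self.sensor_depth_path,
            "dense_depth": self.dense_depth_path,
        }
        if self.true_depth_path is not None:
            d["true_depth"] = self.true_depth_path
        return d


@dataclass
class RGBDFrame:
    """In-memory RGB-D training frame.

    ``sensor_depth`` is metric (metres) with 0 marking missing ToF
    measurements; ``dense_depth`` is a complete relative-scale map (typically
    in [0, 1]) as produced by a monocular depth estimator.
    """

    color: np.ndarray  # (H,W,3) float in [0,1]
    sensor_depth: np.ndarray  # (H,W) metres, 0 = missing
    dense_depth: np.ndarray  # (H,W) relative scale
    t: int
    camera_id: str
    true_depth: np.ndarray | None = None

    def validate(self, cam: CameraModel) -> None:
        h, w = cam.height, cam.width
        for name, img, ndim in (
            ("color", self.color, 3),
            ("sensor_depth", self.sensor_depth, 2),
            ("dense_depth", self.dense_depth, 2),
        ):
            if img.shape[:2] != (h, w) or img.ndim != ndim:
                raise ManifestError(
                    f"frame (cam={self.camera_id}, t={self.t}): {name} shape "
                    f"{img.shape} does not match camera {h}x{w}"
                )
        if np.any(self.sensor_depth < 0):
            raise ManifestError("sensor_depth must be non-negative")
        if not np.all(np.isfinite(self.dense_depth)):
            raise ManifestError("dense_depth must be finite everywhere")


@dataclass
class SceneManifest:
    """Scene description: camera table, frame records and global metadata."""

    cameras: list[CameraModel]
    frames: list[FrameRecord]
    t_video: int
    scene_bounds: tuple[np.ndarray, np.ndarray]  # (min_xyz, max_xyz) metres
    depth_unit: str = "mm"
    root: Path = field(default_factory=Path)

    def __post_init__(self) -> None:
        lo, hi = self.scene_bounds
        self.scene_bounds = (
            np.asarray(lo, dtype=np.float64).reshape(3),
            np.asarray(hi, dtype=np.float64).reshape(3),
        )
        ids = {c.camera_id for c in self.cameras}
        if len(ids) != len(self.cameras):
            raise ManifestError("duplicate camera ids")
        for fr in self.frames:
            if fr.camera_id not in ids:
                raise ManifestError(f"frame references unknown camera {fr.camera_id!r}")
            if not (1 <= fr.t <= self.t_video):
                raise ManifestError(
                    f"frame t={fr.t} outside 1..T_video={self.t_video}"
                )

    def camera(self, camera_id: str) -> CameraModel:
        for c in self.cameras:
            if c.camera_id == camera_id:
                return c
        raise KeyError(camera_id)

    def iter_frames(self) -> Iterator[tuple[FrameRecord, CameraModel]]:
        for fr in self.frames:
            yield fr, self.camera(fr.camera_id)

    def to_dict(self) -> dict:
        lo, hi = self.scene_bounds
        return {
            "t_video": self.t_video,
            "depth_unit": self.depth_unit,
            "scene_bounds": {"min": lo.tolist(), "max": hi.tolist()},
            "cameras": [c.to_dict() for c in self.cameras],
            "frames": [f.to_dict() for f in self.frames],
        }


# ---------------------------------------------------------------------------
# image I/O


def read_color_png(path: Path) -> np.ndarray:
    img = iio.imread(path)
    if img.ndim == 2:
        img = np.stack([img] * 3, axis=-1)
    return img[..., :3].astype(np.float64) / 255.0


def write_color_png(path: Path, color: np.ndarray) -> None:
    arr = np.clip(np.asarray(color, dtype=np.float64), 0.0, 1.0)
    iio.imwrite(path, np.round(arr * 255.0).astype(np.uint8))


def read_depth(path: Path, depth_unit: str = "mm") -> np.ndarray:
    """Read a depth map in metres.

    16-bit PNGs hold integer depth in the manifest's ``depth_unit``
    (millimetres by default); float TIFFs hold metres directly.
    """
    p = Path(path)
    if p.suffix.lower() in {".tif", ".tiff"}:
        return tifffile.imread(p).astype(np.float64)
    raw = iio.imread(p).astype(np.float64)
    scale = 1e-3 if depth_unit == "mm" else 1.0
    return raw * scale


def write_depth_png(path: Path, depth_m: np.ndarray) -> None:
    """Write depth (metres) as 16-bit millimetre PNG."""
    mm = np.round(np.asarray(depth_m, dtype=np.float64) * 1000.0)
    iio.imwrite(path, np.clip(mm, 0, 65535).astype(np.uint16))


def write_float_tiff(path: Path, arr: np.ndarray) -> None:
    tifffile.imwrite(path, np.asarray(arr, dtype=np.float32))


def write_rendered_frame(color: np.ndarray, depth: np.ndarray, path_prefix: Path) -> dict:
    """Write a rendered view: 8-bit colour PNG + 16-bit mm depth PNG + float TIFF.

    Returns the paths written.  Round-tripping recovers colour within 1/255
    and depth within 0.5 mm (PNG) / float32 precision (TIFF).
    """
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "color": prefix.with_name(prefix.name + "_color.png"),
        "depth_png": prefix.with_name(prefix.name + "_depth.png"),
        "depth_tiff": prefix.with_name(prefix.name + "_depth.tif"),
    }
    write_color_png(paths["color"], color)
    write_depth_png(paths["depth_png"], depth)
    write_float_tiff(paths["depth_tiff"], depth)
    return paths


# ---------------------------------------------------------------------------
# manifest I/O


def load_manifest(path: Path) -> SceneManifest:
    """Load and validate a scene manifest (JSON).

    Checks that every referenced image exists; does not load pixel data
    (use :func:`load_frame`).
    """
    path = Path(path)
    if not path.exists():
        raise ManifestError(f"manifest not found: {path}")
    with open(path) as fh:
        d = json.load(fh)
    root = path.parent
    cameras = [CameraModel.from_dict(c) for c in d["cameras"]]
    frames = [
        FrameRecord(
            camera_id=str(f["camera_id"]),
            t=int(f["t"]),
            color_path=f["color"],
            sensor_depth_path=f["sensor_depth"],
            dense_depth_path=f["dense_depth"],
            true_depth_path=f.get("true_depth"),
        )
        for f in d["frames"]
    ]
    bounds = (d["scene_bounds"]["min"], d["scene_bounds"]["max"])
    manifest = SceneManifest(
        cameras=cameras,
        frames=frames,
        t_video=int(d["t_video"]),
        scene_bounds=bounds,
        depth_unit=d.get("depth_unit", "mm"),
        root=root,
    )
    for fr in manifest.frames:
        for rel in (fr.color_path, fr.sensor_depth_path, fr.dense_depth_path):
            if not (root / rel).exists():
                raise ManifestError(f"referenced image missing: {root / rel}")
    return manifest


def save_manifest(manifest: SceneManifest, path: Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(manifest.to_dict(), fh, indent=1, sort_keys=True)
        fh.write("\n")


def load_frame(manifest: SceneManifest, record: FrameRecord) -> RGBDFrame:
    """Load one frame's images from disk and validate against its camera."""
    root = manifest.root
    frame = RGBDFrame(
        color=read_color_png(root / record.color_path),
        sensor_depth=read_depth(root / record.sensor_depth_path, manifest.depth_unit),
        dense_depth=read_depth(root / record.dense_depth_path, manifest.depth_unit),
        t=record.t,
        camera_id=record.camera_id,
        true_depth=(
            read_depth(root / record.true_depth_path, manifest.depth_unit)
            if record.true_depth_path
            else None
        ),
    )
    frame.validate(manifest.camera(record.camera_id))
    return frame


def load_all_frames(manifest: SceneManifest) -> list[RGBDFrame]:
    return [load_frame(manifest, fr) for fr in manifest.frames]
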