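"""Synthetic RGB-D scene generator.

Emulates the structure of multi-camera operating-room captures: a handful of
fixed RGB-D cameras on a ring around the scene centre with very different
vantage points, metric time-of-flight sensor depth with the three
characteristic missing-value mechanisms (zeroed sensor border, dropout on
reflective surfaces, "depth shadows" around object boundaries), and a
complete relative-scale dense depth map standing in for the output of a
monocular depth estimator.

Scenes are analytic (textured ground plane, spheres, axis-aligned boxes)
with flat shading, so ground-truth colour and depth are closed-form per
pixel; depth is the metric distance from the camera centre along the pixel
ray.  Primitives may carry a constant velocity to build dynamic scenes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .scene import (
    CameraModel,
    FrameRecord,
    SceneManifest,
    save_manifest,
    write_color_png,
    write_depth_png,
    write_float_tiff,
)

__all__ = [
    "Sphere",
    "Box",
    "GroundPlane",
    "AnalyticScene",
    "ToFArtifactConfig",
    "render_ground_truth",
    "corrupt_to_sensor_depth",
    "mock_dense_depth",
    "make_dataset",
    "default_scene",
    "moving_sphere_scene",
    "make_preset",
    "PRESETS",
]


# ---------------------------------------------------------------------------
# primitives


@dataclass
class Sphere:
    center: np.ndarray
    radius: float
    base_color: np.ndarray
    reflective: bool = False
    velocity: np.ndarray = field(default_factory=lambda: np.zeros(3))
    stripes: bool = True  # longitude stripes give the colour loss texture

    def center_at(self, t: int) -> np.ndarray:
        return np.asarray(self.center, float) + np.asarray(self.velocity, float) * (t - 1)

    def intersect(self, o: np.ndarray, d: np.ndarray, t: int):
        c = self.center_at(t)
        oc = o - c
        b = np.einsum("pk,pk->p", oc, d)
        disc = b * b - (np.einsum("pk,pk->p", oc, oc) - self.radius**2)
        hit = disc > 0
        sq = np.sqrt(np.where(hit, disc, 0.0))
        t0 = -b - sq
        t0 = np.where(hit & (t0 > 1e-6), t0, np.inf)
        return t0

    def shade(self, p: np.ndarray, t: int) -> np.ndarray:
        col = np.broadcast_to(np.asarray(self.base_color, float), p.shape).copy()
        if self.stripes:
            rel = p - self.center_at(t)
            phase = np.arctan2(rel[:, 1], rel[:, 0])
            stripe = 0.5 + 0.5 * np.sign(np.sin(4.0 * phase))
            col *= (0.6 + 0.4 * stripe)[:, None]
        return col


@dataclass
class Box:
    lo: np.ndarray
    hi: np.ndarray
    base_color: np.ndarray
    reflective: bool = False
    velocity: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def _bounds_at(self, t: int):
        off = np.asarray(self.velocity, float) * (t - 1)
        return np.asarray(self.lo, float) + off, np.asarray(self.hi, float) + off

    def intersect(self, o: np.ndarray, d: np.ndarray, t: int):
        lo, hi = self._bounds_at(t)
        with np.errstate(divide="ignore", invalid="ignore"):
            inv = 1.0 / d
            t1 = (lo - o) * inv
            t2 = (hi - o) * inv
        tmin = np.minimum(t1, t2).max(axis=1)
        tmax = np.maximum(t1, t2).min(axis=1)
        hit = (tmax > np.maximum(tmin, 1e-6))
        tval = np.where(tmin > 1e-6, tmin, tmax)  # inside the box: exit face
        return np.where(hit, tval, np.inf)

    def shade(self, p: np.ndarray, t: int) -> np.ndarray:
        check = (np.floor(p[:, 0] / 0.2) + np.floor(p[:, 1] / 0.2) + np.floor(p[:, 2] / 0.2)) % 2
        col = np.asarray(self.base_color, float)[None, :] * (0.65 + 0.35 * check)[:, None]
        return col


@dataclass
class Wall:
    """Vertical room wall: the plane ``p[axis] = coord`` for z in [0, z_max]."""

    axis: int  # 0 -> x = coord, 1 -> y = coord
    coord: float
    extent: float = 3.2  # half-width along the other horizontal axis
    z_max: float = 3.0
    color_a: np.ndarray = field(default_factory=lambda: np.array([0.75, 0.72, 0.65]))
    color_b: np.ndarray = field(default_factory=lambda: np.array([0.5, 0.55, 0.6]))
    square: float = 0.6
    reflective: bool = False
    velocity: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def intersect(self, o: np.ndarray, d: np.ndarray, t: int):
        with np.errstate(divide="ignore", invalid="ignore"):
            tval = (self.coord - o[:, self.axis]) / d[:, self.axis]
        p = o + tval[:, None] * d
        other = 1 - self.axis
        ok = (
            (tval > 1e-6)
            & (p[:, 2] >= 0.0)
            & (p[:, 2] <= self.z_max)
            & (np.abs(p[:, other]) <= self.extent)
        )
        return np.where(ok, tval, np.inf)

    def shade(self, p: np.ndarray, t: int) -> np.ndarray:
        other = 1 - self.axis
        check = (np.floor(p[:, other] / self.square) + np.floor(p[:, 2] / self.square)) % 2
        return np.where(check[:, None] > 0.5, self.color_a[None, :], self.color_b[None, :])


@dataclass
class GroundPlane:
    z: float = 0.0
    color_a: np.ndarray = field(default_factory=lambda: np.array([0.85, 0.85, 0.8]))
    color_b: np.ndarray = field(default_factory=lambda: np.array([0.35, 0.4, 0.45]))
    square: float = 0.4  # checker square size, metres
    reflective: bool = False
    velocity: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def intersect(self, o: np.ndarray, d: np.ndarray, t: int):
        with np.errstate(divide="ignore", invalid="ignore"):
            tval = (self.z - o[:, 2]) / d[:, 2]
        return np.where(tval > 1e-6, tval, np.inf)

    def shade(self, p: np.ndarray, t: int) -> np.ndarray:
        check = (np.floor(p[:, 0] / self.square) + np.floor(p[:, 1] / self.square)) % 2
        return np.where(check[:, None] > 0.5, self.color_a[None, :], self.color_b[None, :])


@dataclass
class AnalyticScene:
    primitives: list
    bounds_min: np.ndarray
    bounds_max: np.ndarray
    t_video: int = 1

    @property
    def diameter(self) -> float:
        return float(np.linalg.norm(np.asarray(self.bounds_max) - np.asarray(self.bounds_min)))


@dataclass
class ToFArtifactConfig:
    """Parameters of the simulated ToF missing-depth mechanisms."""

    border_margin: int = 1  # pixels zeroed at the sensor border (scaled to 48-px images)
    boundary_shadow_width: int = 1  # pixels zeroed around depth discontinuities
    jump_threshold: float = 0.15  # metres; discontinuity detection threshold
    reflective_dropout: float = 0.5  # Bernoulli zeroing prob on reflective surfaces

    def __post_init__(self) -> None:
        if self.border_margin < 0 or self.boundary_shadow_width < 0:
            raise ValueError("margins must be non-negative")
        if not 0.0 <= self.reflective_dropout <= 1.0:
            raise ValueError("reflective_dropout must be a probability")


# ---------------------------------------------------------------------------
# rendering


def render_ground_truth(scene: AnalyticScene, cam: CameraModel, t: int = 1):
    """Exact per-pixel nearest-hit colour and metric depth.

    Returns ``(color (H,W,3), depth (H,W), labels (H,W), reflective (H,W))``
    where depth is the distance along the unit pixel ray (``far`` where no
    primitive is hit), labels index the hit primitive (-1 for background)
    and ``reflective`` marks pixels on reflective-labelled surfaces.
    """
    H, W = cam.height, cam.width
    rows, cols = np.mgrid[0:H, 0:W]
    o, d = cam.rays_for_pixels(rows.ravel(), cols.ravel())
    P = H * W
    best_t = np.full(P, np.inf)
    best_i = np.full(P, -1, dtype=np.int64)
    for i, prim in enumerate(scene.primitives):
        ti = prim.intersect(o, d, t)
        closer = ti < best_t
        best_t = np.where(closer, ti, best_t)
        best_i = np.where(closer, i, best_i)
    beyond = best_t > cam.far
    best_t = np.where(beyond, np.inf, best_t)
    best_i = np.where(beyond, -1, best_i)

    color = np.zeros((P, 3))
    reflective = np.zeros(P, dtype=bool)
    for i, prim in enumerate(scene.primitives):
        sel = best_i == i
        if not np.any(sel):
            continue
        pts = o[sel] + best_t[sel, None] * d[sel]
        color[sel] = prim.shade(pts, t)
        if prim.reflective:
            reflective[sel] = True
    depth = np.where(np.isfinite(best_t), best_t, cam.far)
    return (
        np.clip(color, 0.0, 1.0).reshape(H, W, 3),
        depth.reshape(H, W),
        best_i.reshape(H, W),
        reflective.reshape(H, W),
    )


# ---------------------------------------------------------------------------
# sensor simulation


def corrupt_to_sensor_depth(
    true_depth: np.ndarray,
    labels: np.ndarray,
    reflective: np.ndarray,
    cfg: ToFArtifactConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Zero out depth pixels the way a ToF sensor loses them.

    Three mechanisms: (a) a frame of ``border_margin`` pixels at the sensor
    border, (b) "depth shadows": pixels within ``boundary_shadow_width`` of an
    object boundary (a change in the surface ``labels``) across which depth
    jumps by more than ``jump_threshold`` — a label change alone is a
    silhouette of two touching surfaces and casts no shadow, and a steep but
    continuous surface is not a boundary, (c) Bernoulli(``reflective_dropout``)
    pixels on reflective surfaces.
    """
    D = np.asarray(true_depth, dtype=np.float64)
    labels = np.asarray(labels)
    if labels.shape != D.shape or reflective.shape != D.shape:
        raise ValueError("labels/reflective mask shape mismatch")
    out = D.copy()
    m = cfg.border_margin
    if m > 0:
        keep = np.zeros_like(out, dtype=bool)
        keep[m:-m or None, m:-m or None] = True
        out[~keep] = 0.0
    w = cfg.boundary_shadow_width
    if w > 0:
        size = 2 * w + 1
        label_change = (
            ndimage.maximum_filter(labels, size=size)
            != ndimage.minimum_filter(labels, size=size)
        )
        depth_jump = (
            ndimage.maximum_filter(D, size=size) - ndimage.minimum_filter(D, size=size)
        ) > cfg.jump_threshold
        out[label_change & depth_jump] = 0.0
    if cfg.reflective_dropout > 0:
        drop = reflective & (rng.random(D.shape) < cfg.reflective_dropout)
        out[drop] = 0.0
    return out


def mock_dense_depth(
    true_depth: np.ndarray,
    rng: np.random.Generator,
    amplitude: float = 0.02,
) -> np.ndarray:
    """Relative-scale dense depth emulating a monocular estimator.

    Affine map of the true depth to [0, 1] (per-image min/max; a constant map
    goes to 0) plus a smooth low-frequency perturbation of amplitude at most
    ``amplitude`` standing in for estimator error.  Values exist for every
    pixel, as with real dense-depth estimators.
    """
    D = np.asarray(true_depth, dtype=np.float64)
    lo, hi = float(D.min()), float(D.max())
    base = np.zeros_like(D) if hi - lo < 1e-12 else (D - lo) / (hi - lo)
    H, W = D.shape
    yy, xx = np.mgrid[0:H, 0:W]
    u, v = xx / max(W - 1, 1), yy / max(H - 1, 1)
    pert = np.zeros_like(D)
    for _ in range(3):
        fx_, fy_ = rng.uniform(0.5, 2.5, size=2)
        ph = rng.uniform(0.0, 2.0 * np.pi)
        pert += np.sin(2.0 * np.pi * (fx_ * u + fy_ * v) + ph)
    mx = np.abs(pert).max()
    if mx > 0:
        pert = pert / mx
    return base + amplitude * pert


# ---------------------------------------------------------------------------
# scene presets


def default_scene(t_video: int = 1, sphere_velocity: np.ndarray | None = None) -> AnalyticScene:
    """Textured ground plane, two spheres (one reflective) and a box "table".

    The layout exercises all three ToF dropout mechanisms: the reflective
    sphere, depth shadows at the box and sphere silhouettes, and the border
    margin.  Procedural checker/stripe textures give the colour loss
    high-frequency content.
    """
    vel = np.zeros(3) if sphere_velocity is None else np.asarray(sphere_velocity, float)
    prims = [
        GroundPlane(z=0.0),
        Wall(axis=0, coord=3.0),
        Wall(axis=0, coord=-3.0),
        Wall(axis=1, coord=3.0),
        Wall(axis=1, coord=-3.0),
        Sphere(
            center=np.array([0.55, 0.35, 0.42]),
            radius=0.42,
            base_color=np.array([0.85, 0.3, 0.25]),
            reflective=True,
        ),
        Sphere(
            center=np.array([-0.55, -0.4, 0.32]),
            radius=0.32,
            base_color=np.array([0.25, 0.45, 0.85]),
            velocity=vel,
        ),
        Box(
            lo=np.array([-0.45, 0.25, 0.0]),
            hi=np.array([0.35, 0.85, 0.48]),
            base_color=np.array([0.4, 0.75, 0.35]),
        ),
    ]
    return AnalyticScene(
        primitives=prims,
        bounds_min=np.array([-3.2, -3.2, -0.2]),
        bounds_max=np.array([3.2, 3.2, 3.0]),
        t_video=t_video,
    )


def moving_sphere_scene(t_video: int = 4) -> AnalyticScene:
    """Dynamic preset: the blue sphere translates 0.15 m per time step."""
    return default_scene(t_video=t_video, sphere_velocity=np.array([0.15, 0.1, 0.0]))


def ring_cameras(
    n_cameras: int,
    image_size: int,
    radius: float = 2.4,
    target: np.ndarray | None = None,
    near: float = 0.5,
    far: float = 8.0,
) -> list[CameraModel]:
    """Cameras on a ring at varied heights, all facing the scene centre.

    Angular separation is 360/n degrees — few cameras with entirely
    different vantage points, as in a multi-camera OR rig.
    """
    target = np.array([0.0, 0.0, 0.4]) if target is None else np.asarray(target, float)
    heights = [1.3, 1.8, 1.5, 1.95, 1.4, 1.7]
    f = 0.5 * image_size / np.tan(np.deg2rad(30.0))  # 60 degree FOV
    cams = []
    for i in range(n_cameras):
        ang = 2.0 * np.pi * i / n_cameras
        eye = np.array([radius * np.cos(ang), radius * np.sin(ang), heights[i % len(heights)]])
        z = target - eye
        z = z / np.linalg.norm(z)
        up = np.array([0.0, 0.0, 1.0])
        x = np.cross(-up, z)
        x = x / np.linalg.norm(x)
        y = np.cross(z, x)
        R = np.stack([x, y, z], axis=1)
        cams.append(
            CameraModel(
                camera_id=f"cam{i}",
                fx=f,
                fy=f,
                cx=(image_size - 1) / 2.0,
                cy=(image_size - 1) / 2.0,
                width=image_size,
                height=image_size,
                rotation=R,
                translation=eye,
                near=near,
                far=far,
            )
        )
    return cams


# ---------------------------------------------------------------------------
# dataset writer


def make_dataset(
    scene: AnalyticScene,
    n_cameras: int,
    image_size: int,
    t_video: int,
    tof_cfg: ToFArtifactConfig,
    out_dir: Path,
    seed: int = 0,
) -> SceneManifest:
    """Render, corrupt and write a complete dataset + manifest.

    Fully reproducible: all stochastic components (ToF dropout, dense-depth
    perturbation) derive from ``seed`` via spawned generators, and the image
    writers are deterministic, so the same seed yields a byte-identical
    dataset.
    """
    if n_cameras < 2:
        raise ValueError("need at least 2 cameras")
    out_dir = Path(out_dir)
    img_dir = out_dir / "images"
    img_dir.mkdir(parents=True, exist_ok=True)
    cams = ring_cameras(n_cameras, image_size)
    seq = np.random.SeedSequence(seed)
    frames: list[FrameRecord] = []
    for t in range(1, t_video + 1):
        for cam in cams:
            child = np.random.default_rng(seq.spawn(1)[0])
            color, depth, labels, refl = render_ground_truth(scene, cam, t)
            sensor = corrupt_to_sensor_depth(depth, labels, refl, tof_cfg, child)
            sensor[labels < 0] = 0.0  # no surface within range: no ToF return
            dense = mock_dense_depth(depth, child)
            stem = f"{cam.camera_id}_t{t:03d}"
            rec = FrameRecord(
                camera_id=cam.camera_id,
                t=t,
                color_path=f"images/{stem}_color.png",
                sensor_depth_path=f"images/{stem}_sensor.png",
                dense_depth_path=f"images/{stem}_dense.tif",
                true_depth_path=f"images/{stem}_true.tif",
            )
            write_color_png(out_dir / rec.color_path, color)
            write_depth_png(out_dir / rec.sensor_depth_path, sensor)
            write_float_tiff(out_dir / rec.dense_depth_path, dense)
            write_float_tiff(out_dir / rec.true_depth_path, depth)
            frames.append(rec)
    manifest = SceneManifest(
        cameras=cams,
        frames=frames,
        t_video=t_video,
        scene_bounds=(scene.bounds_min, scene.bounds_max),
        depth_unit="mm",
        root=out_dir,
    )
    save_manifest(manifest, out_dir / "manifest.json")
    return manifest


def make_preset(name: str, out_dir: Path, seed: int = 0, image_size: int = 48,
                n_cameras: int = 6) -> SceneManifest:
    """Generate one of the named dataset presets into ``out_dir``."""
    if name == "static":
        return make_dataset(default_scene(), n_cameras, image_size, 1,
                            ToFArtifactConfig(), out_dir, seed=seed)
    if name == "holes-heavy":
        cfg = ToFArtifactConfig(border_margin=4, boundary_shadow_width=2,
                                jump_threshold=0.1, reflective_dropout=0.9)
        return make_dataset(default_scene(), n_cameras, image_size, 1, cfg,
                            out_dir, seed=seed)
    if name == "dynamic":
        scene = moving_sphere_scene(t_video=4)
        return make_dataset(scene, n_cameras, image_size, 4,
                            ToFArtifactConfig(), out_dir, seed=seed)
    raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")


PRESETS = {"static", "dynamic", "holes-heavy"}
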