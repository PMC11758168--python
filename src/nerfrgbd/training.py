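"""Training loop: optimise the radiance field and hash tables against the
combined colour + sensor-depth + surface-normal loss over random patches.

One optimisation step draws one (or more) strided patches from a random
training frame, renders every patch ray by quadrature, evaluates

    L = L_color + alpha * L_depth + beta * L_normal,

and backpropagates through the renderer, the MLP and the (tri/quadri)linear
grid interpolation with hand-written gradients, updating all parameters with
Adam.  Dynamic scenes (T_video > 1) add a 4D grid whose embedding is summed
element-wise with the static 3D embedding.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np

from .encoding import SH_DIM, GridEncoder, HashEncodingConfig, sh_encode
from .field import FieldConfig, RadianceFieldMLP
from .losses import (
    LossWeights,
    color_loss,
    color_loss_grad,
    depth_loss,
    depth_loss_grad,
    normal_loss_grad_wrt_depth,
    normals_from_depth,
    total_loss,
)
from .patches import gather_patch_targets, patch_to_rays, sample_patch
from .rendering import render_rays, render_rays_backward, sample_along_ray
from .scene import CameraModel, SceneManifest, load_all_frames

__all__ = [
    "TrainConfig",
    "desk_train_config",
    "NeuralRadianceField",
    "Checkpoint",
    "train",
    "load_checkpoint",
    "render_image",
]


@dataclass
class TrainConfig:
    """All knobs of a training run.

    Defaults follow the reference configuration for static scenes
    (2K iterations, learning rate 0.01, 8x8 patches at 4 resolution levels,
    one 64-ray patch per step); ``samples_per_ray`` defaults to a
    desk-scale 128 (the full-scale configuration uses orders of magnitude
    more, which assumes GPU-class throughput).
    """

    iterations: int = 2000
    learning_rate: float = 0.01
    patches_per_step: int = 1
    samples_per_ray: int = 128
    patch_m: int = 8
    patch_n: int = 8
    p_levels: int = 4
    seed: int = 0
    loss: LossWeights = field(default_factory=LossWeights)
    stencil: str = "forward"
    spatial_encoding: HashEncodingConfig = field(default_factory=HashEncodingConfig)
    temporal_min_resolution: int = 1
    field_cfg: FieldConfig = field(default_factory=FieldConfig)
    use_dynamic: bool | None = None  # None: automatic (T_video > 1)
    frame_filter: str = "all"  # all | odd | even  (by time index t)
    holdout_camera: str | None = None
    deterministic: bool = False
    checkpoint_every: int = 250
    dtype: str = "float32"

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


def desk_train_config(**overrides) -> TrainConfig:
    """Desk-scale preset: CPU-friendly grid and MLP sizes.

    8 encoding levels up to N_max=512 with 2^16-entry tables and a width-64
    MLP — sized for the bundled 48x48 synthetic scenes; all knobs remain
    overridable.  ``p_levels`` drops to 3 because an 8x8 patch at stride 8
    spans 57 pixels and does not fit in a 48-pixel image.
    """
    cfg = TrainConfig(
        spatial_encoding=HashEncodingConfig(
            n_min=16, n_max=512, levels=8, features=2, table_size_log2=16
        ),
        field_cfg=FieldConfig(hidden_layers=3, hidden_width=64, color_hidden_width=64),
        p_levels=3,
    )
    return replace(cfg, **overrides)


class NeuralRadianceField:
    """Hash-encoded radiance field: 3D (+ optional 4D) grids + MLP."""

    def __init__(
        self,
        spatial_cfg: HashEncodingConfig,
        field_cfg: FieldConfig,
        bounds: tuple[np.ndarray, np.ndarray],
        t_video: int = 1,
        use_dynamic: bool | None = None,
        temporal_min_resolution: int = 1,
        seed: int = 0,
        dtype="float32",
    ) -> None:
        self.spatial_cfg = spatial_cfg
        self.field_cfg = field_cfg
        self.bounds_min = np.asarray(bounds[0], dtype=np.float64)
        self.bounds_max = np.asarray(bounds[1], dtype=np.float64)
        self.t_video = int(t_video)
        self.use_dynamic = (t_video > 1) if use_dynamic is None else bool(use_dynamic)
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        self.grid3 = GridEncoder(spatial_cfg, dim=3, rng=rng, dtype=dtype)
        self.grid4 = None
        if self.use_dynamic:
            cfg4 = replace(
                spatial_cfg,
                temporal_max_resolution=max(self.t_video, 1),
                temporal_min_resolution=temporal_min_resolution,
            )
            self.grid4 = GridEncoder(cfg4, dim=4, rng=rng, dtype=dtype)
        self.mlp = RadianceFieldMLP(
            spatial_cfg.output_dim, SH_DIM, field_cfg, rng=rng, dtype=dtype
        )

    # -- parameter plumbing -------------------------------------------------

    def parameters(self) -> dict[str, np.ndarray]:
        p = {f"mlp.{k}": v for k, v in self.mlp.params.items()}
        p["grid3.table"] = self.grid3.table
        if self.grid4 is not None:
            p["grid4.table"] = self.grid4.table
        return p

    def set_parameters(self, params: dict[str, np.ndarray]) -> None:
        for k, v in params.items():
            if k == "grid3.table":
                self.grid3.table = v
            elif k == "grid4.table":
                assert self.grid4 is not None
                self.grid4.table = v
            elif k.startswith("mlp."):
                self.mlp.params[k[4:]] = v
            else:
                raise KeyError(k)

    def t_to_norm(self, t: int) -> float:
        if self.t_video <= 1:
            return 0.0
        return (t - 1) / (self.t_video - 1)

    def normalize_positions(self, x: np.ndarray) -> np.ndarray:
        return (x - self.bounds_min) / (self.bounds_max - self.bounds_min)

    # -- evaluation ---------------------------------------------------------

    def embed(self, positions: np.ndarray, t_norm: float, with_cache: bool = False):
        xn = self.normalize_positions(positions)
        if self.grid4 is None:
            out = self.grid3.encode(xn, with_cache=with_cache)
            if with_cache:
                e3, c3 = out
                return e3, (c3, None)
            return out
        x4 = np.concatenate([xn, np.full((xn.shape[0], 1), t_norm)], axis=1)
        if with_cache:
            e3, c3 = self.grid3.encode(xn, with_cache=True)
            e4, c4 = self.grid4.encode(x4, with_cache=True)
            return e3 + e4, (c3, c4)
        return self.grid3.encode(xn) + self.grid4.encode(x4)

    def query(self, positions: np.ndarray, directions: np.ndarray, t_norm: float = 0.0):
        """Field evaluation: world positions + view directions -> (color, sigma)."""
        feat = self.embed(positions, t_norm)
        sh = sh_encode(directions)
        return self.mlp.query(feat, sh)

    def field_fn(self, positions, directions, t_norm):
        return self.query(positions, directions, t_norm)


# ---------------------------------------------------------------------------
# optimiser


class Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float, beta1: float = 0.9,
                 beta2: float = 0.99, eps: float = 1e-15) -> None:
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros(v.shape, dtype=v.dtype) for k, v in params.items()}
        self.v = {k: np.zeros(v.shape, dtype=v.dtype) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for k, p in params.items():
            g = grads[k]
            self.m[k] = self.beta1 * self.m[k] + (1.0 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1.0 - self.beta2) * g * g
            update = (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)
            p -= (self.lr * update).astype(p.dtype)


# ---------------------------------------------------------------------------
# checkpointing


@dataclass
class Checkpoint:
    model: NeuralRadianceField
    meta: dict
    path: Path | None = None


def _cfg_to_jsonable(cfg: TrainConfig) -> dict:
    return asdict(cfg)


def save_checkpoint(model: NeuralRadianceField, meta: dict, path: Path) -> None:
    """Single-archive checkpoint: named parameter tensors + a JSON header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    header = dict(meta)
    header["spatial_encoding"] = asdict(model.spatial_cfg)
    header["field_cfg"] = asdict(model.field_cfg)
    header["bounds_min"] = model.bounds_min.tolist()
    header["bounds_max"] = model.bounds_max.tolist()
    header["t_video"] = model.t_video
    header["use_dynamic"] = model.use_dynamic
    header["temporal_min_resolution"] = (
        model.grid4.cfg.temporal_min_resolution if model.grid4 is not None else 1
    )
    arrays = {k.replace(".", "__"): v for k, v in model.parameters().items()}
    np.savez(path, __header__=np.frombuffer(json.dumps(header).encode(), dtype=np.uint8),
             **arrays)


def load_checkpoint(path: Path) -> Checkpoint:
    path = Path(path)
    with np.load(path) as data:
        header = json.loads(bytes(data["__header__"]).decode())
        arrays = {
            k.replace("__", "."): data[k] for k in data.files if k != "__header__"
        }
    model = NeuralRadianceField(
        spatial_cfg=HashEncodingConfig(**header["spatial_encoding"]),
        field_cfg=FieldConfig(**header["field_cfg"]),
        bounds=(np.array(header["bounds_min"]), np.array(header["bounds_max"])),
        t_video=header["t_video"],
        use_dynamic=header["use_dynamic"],
        temporal_min_resolution=header.get("temporal_min_resolution", 1),
    )
    model.set_parameters(arrays)
    meta = {k: v for k, v in header.items()
            if k not in {"spatial_encoding", "field_cfg", "bounds_min", "bounds_max",
                         "t_video", "use_dynamic", "temporal_min_resolution"}}
    return Checkpoint(model=model, meta=meta, path=path)


# ---------------------------------------------------------------------------
# training


def select_training_frames(manifest: SceneManifest, frame_filter: str,
                           holdout_camera: str | None) -> list[int]:
    """Indices of manifest frames used for training.

    ``frame_filter`` keeps all/odd/even time indices (the dynamic protocol
    trains on odd t and evaluates on even t); ``holdout_camera`` excludes one
    camera entirely (the held-out-view protocol).
    """
    keep = []
    for i, fr in enumerate(manifest.frames):
        if holdout_camera is not None and fr.camera_id == holdout_camera:
            continue
        if frame_filter == "odd" and fr.t % 2 == 0:
            continue
        if frame_filter == "even" and fr.t % 2 == 1:
            continue
        keep.append(i)
    return keep


def _train_step(model, frames, cams, train_idx, cfg, rng):
    """One optimisation step; returns (loss terms, parameter grads)."""
    w = cfg.loss
    grads_acc: dict[str, np.ndarray] | None = None
    Lc_tot = Ld_tot = Ln_tot = 0.0
    n_depth_unsupervised = 0
    for _ in range(cfg.patches_per_step):
        fi = train_idx[rng.integers(0, len(train_idx))]
        frame = frames[fi]
        cam = cams[frame.camera_id]
        spec = sample_patch(fi, cam.height, cam.width, cfg.patch_m, cfg.patch_n,
                            cfg.p_levels, rng)
        origins, dirs = patch_to_rays(spec, cam)
        M, N = spec.m, spec.n
        R = M * N
        o = origins.reshape(R, 3)
        d = dirs.reshape(R, 3)
        samples = sample_along_ray(o, d, cfg.samples_per_ray, cam.near, cam.far, rng=rng)
        S = cfg.samples_per_ray
        pos = samples.positions.reshape(R * S, 3)
        t_norm = model.t_to_norm(frame.t)
        feat, enc_caches = model.embed(pos, t_norm, with_cache=True)
        sh = np.repeat(sh_encode(d), S, axis=0)
        c, sigma, mlp_cache = model.mlp.query(feat, sh, with_cache=True)
        result, rcache = render_rays(
            sigma.reshape(R, S), c.reshape(R, S, 3), samples.a, samples.delta,
            with_cache=True,
        )
        targets = gather_patch_targets(spec, frame)
        C_hat = result.C.reshape(M, N, 3)
        D_hat = result.D.reshape(M, N)

        Lc = color_loss(C_hat, targets["C"])
        dC = color_loss_grad(C_hat, targets["C"])
        Ld = depth_loss(D_hat, targets["D_sensor"], targets["valid"])
        dDd = depth_loss_grad(D_hat, targets["D_sensor"], targets["valid"])
        if not targets["valid"].any():
            n_depth_unsupervised += 1
        if w.beta > 0 and M >= 2 and N >= 2:
            N_target = normals_from_depth(targets["D_dense"], pixel_spacing=spec.stride,
                                          stencil=cfg.stencil)
            Ln, dDn = normal_loss_grad_wrt_depth(D_hat, N_target,
                                                 pixel_spacing=spec.stride,
                                                 stencil=cfg.stencil)
        else:
            Ln, dDn = 0.0, np.zeros_like(D_hat)
        dD = w.alpha * dDd + w.beta * dDn

        dsigma, dcolor = render_rays_backward(rcache, dC.reshape(R, 3), dD.reshape(R))
        mlp_grads, dfeat = model.mlp.backward(
            mlp_cache, dcolor.reshape(R * S, 3), dsigma.reshape(R * S)
        )
        step_grads = {f"mlp.{k}": v for k, v in mlp_grads.items()}
        c3, c4 = enc_caches
        step_grads["grid3.table"] = model.grid3.backward(c3, dfeat)
        if model.grid4 is not None:
            step_grads["grid4.table"] = model.grid4.backward(c4, dfeat)
        if grads_acc is None:
            grads_acc = step_grads
        else:
            for k in grads_acc:
                grads_acc[k] = grads_acc[k] + step_grads[k]
        Lc_tot += Lc
        Ld_tot += Ld
        Ln_tot += Ln
    return Lc_tot, Ld_tot, Ln_tot, grads_acc, n_depth_unsupervised


def train(manifest: SceneManifest, cfg: TrainConfig, out_dir: Path | None = None,
          frames=None) -> Checkpoint:
    """Fit the field to a scene; returns the final checkpoint.

    ``frames`` may pass pre-loaded :class:`RGBDFrame` objects to skip disk
    I/O.  With ``out_dir`` set, writes ``checkpoint.npz``, ``config.json``
    and a line-oriented ``metrics.csv`` (iteration, losses, patch PSNR).
    """
    if not manifest.frames:
        raise ValueError("manifest contains no frames")
    frames = load_all_frames(manifest) if frames is None else frames
    cams = {c.camera_id: c for c in manifest.cameras}
    train_idx = select_training_frames(manifest, cfg.frame_filter, cfg.holdout_camera)
    if not train_idx:
        raise ValueError("frame filter leaves no training frames")
    model = NeuralRadianceField(
        spatial_cfg=cfg.spatial_encoding,
        field_cfg=cfg.field_cfg,
        bounds=manifest.scene_bounds,
        t_video=manifest.t_video,
        use_dynamic=cfg.use_dynamic,
        temporal_min_resolution=cfg.temporal_min_resolution,
        seed=cfg.seed,
        dtype=cfg.dtype,
    )
    params = model.parameters()
    opt = Adam(params, lr=cfg.learning_rate)
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 1)))
    metrics: list[dict] = []
    last_good: dict[str, np.ndarray] | None = None
    rays_per_patch = cfg.patch_m * cfg.patch_n * cfg.patches_per_step

    for it in range(1, cfg.iterations + 1):
        Lc, Ld, Ln, grads, n_nodepth = _train_step(model, frames, cams, train_idx, cfg, rng)
        L = total_loss(Lc, Ld, Ln, cfg.loss)
        if not np.isfinite(L):
            if out_dir is not None and last_good is not None:
                model.set_parameters(last_good)
                save_checkpoint(model, {"aborted_at": it}, Path(out_dir) / "checkpoint.npz")
            raise FloatingPointError(
                f"non-finite loss at iteration {it}: "
                f"L_color={Lc}, L_depth={Ld}, L_normal={Ln}"
            )
        opt.step(params, grads)
        patch_mse = Lc / (3.0 * rays_per_patch)
        metrics.append({
            "iteration": it,
            "L_color": Lc,
            "L_depth": Ld,
            "L_normal": Ln,
            "L": L,
            "patch_psnr": float(-10.0 * np.log10(max(patch_mse, 1e-12))),
            "no_depth_supervision": n_nodepth,
        })
        if cfg.checkpoint_every and it % cfg.checkpoint_every == 0:
            last_good = {k: v.copy() for k, v in params.items()}

    meta = {
        "train_frame_indices": train_idx,
        "frame_filter": cfg.frame_filter,
        "holdout_camera": cfg.holdout_camera,
        "iterations": cfg.iterations,
        "seed": cfg.seed,
        "samples_per_ray": cfg.samples_per_ray,
        "final_loss": metrics[-1]["L"],
    }
    ckpt = Checkpoint(model=model, meta=meta)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        ckpt.path = out_dir / "checkpoint.npz"
        save_checkpoint(model, meta, ckpt.path)
        with open(out_dir / "config.json", "w") as fh:
            json.dump(_cfg_to_jsonable(cfg), fh, indent=1, default=str)
        with open(out_dir / "metrics.csv", "w") as fh:
            cols = list(metrics[0])
            fh.write(",".join(cols) + "\n")
            for row in metrics:
                fh.write(",".join(str(row[c]) for c in cols) + "\n")
    ckpt.meta["metrics"] = metrics
    return ckpt


# ---------------------------------------------------------------------------
# inference


def render_image(model: NeuralRadianceField, cam: CameraModel, t: int = 1,
                 S: int = 128, chunk_rows: int = 8) -> tuple[np.ndarray, np.ndarray]:
    """Render a full view (deterministic midpoint sampling), chunked by rows."""
    H, W = cam.height, cam.width
    color = np.zeros((H, W, 3))
    depth = np.zeros((H, W))
    t_norm = model.t_to_norm(t)
    for r0 in range(0, H, chunk_rows):
        r1 = min(r0 + chunk_rows, H)
        rows, cols = np.mgrid[r0:r1, 0:W]
        o, d = cam.rays_for_pixels(rows.ravel(), cols.ravel())
        samples = sample_along_ray(o, d, S, cam.near, cam.far, rng=None)
        R = o.shape[0]
        pos = samples.positions.reshape(R * S, 3)
        dirs = np.repeat(d, S, axis=0)
        c, sigma = model.query(pos, dirs, t_norm)
        res = render_rays(sigma.reshape(R, S), c.reshape(R, S, 3), samples.a, samples.delta)
        color[r0:r1] = res.C.reshape(r1 - r0, W, 3)
        depth[r0:r1] = res.D.reshape(r1 - r0, W)
    return color, depth
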