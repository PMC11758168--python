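"""Multiresolution hash encodings (3D and 4D) and spherical-harmonics
direction encoding.

Each encoding level is a virtual grid of feature vectors over the unit cube
(or unit hypercube with a time axis).  Grid resolutions grow geometrically
from ``n_min`` to ``n_max``.  A level whose full vertex lattice fits in the
feature table is addressed densely; finer levels address vertices through a
prime-XOR spatial hash into a power-of-two table.  Queried features are the
tri-(quadri-)linear interpolation of the corner features, which makes the
encoding piecewise-linear in position and exactly linear in the table
entries — the property the hand-written backward pass relies on.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np

__all__ = [
    "HashEncodingConfig",
    "GridEncoder",
    "combine_static_dynamic",
    "sh_encode",
    "SH_DIM",
]

# one large prime per dimension; first is 1 so dense/hashed agree on axis 0
_PRIMES = np.array([1, 2654435761, 805459861, 3674653429], dtype=np.uint64)


@dataclass
class HashEncodingConfig:
    """Geometry of a multiresolution feature grid.

    ``n_min``/``n_max`` bound the spatial resolutions; ``temporal_max_resolution``
    (4D grids only) is the video length — the finest temporal resolution equals
    the number of frames so each frame can get its own temporal cell.
    """

    n_min: int = 16
    n_max: int = 2048
    levels: int = 16
    features: int = 2
    table_size_log2: int = 21
    temporal_max_resolution: int = 1
    temporal_min_resolution: int = 1

    def __post_init__(self) -> None:
        if self.n_min > self.n_max:
            raise ValueError("n_min must not exceed n_max")
        if self.levels < 1:
            raise ValueError("need at least one level")

    @property
    def table_size(self) -> int:
        return 1 << self.table_size_log2

    def level_resolutions(self) -> np.ndarray:
        """Spatial resolution per level: N_l = floor(n_min * b**l)."""
        return _geometric_levels(self.n_min, self.n_max, self.levels)

    def temporal_resolutions(self) -> np.ndarray:
        return _geometric_levels(
            min(self.temporal_min_resolution, self.temporal_max_resolution),
            self.temporal_max_resolution,
            self.levels,
        )

    @property
    def output_dim(self) -> int:
        return self.levels * self.features


def _geometric_levels(n_min: int, n_max: int, levels: int) -> np.ndarray:
    if levels == 1 or n_min == n_max:
        return np.full(levels, n_max, dtype=np.int64) if n_min == n_max else np.array(
            [n_max], dtype=np.int64
        )
    b = np.exp((np.log(n_max) - np.log(n_min)) / (levels - 1))
    res = np.floor(n_min * b ** np.arange(levels) + 1e-9).astype(np.int64)
    res[-1] = n_max
    return np.maximum(res, 1)


class GridEncoder:
    """Learnable multiresolution grid encoder over ``[0,1]^dim``.

    ``dim`` is 3 (static, spatial) or 4 (dynamic, spatial + normalized time).
    The feature table has shape ``(levels, table_size, features)`` and is the
    single learnable parameter of the encoder.
    """

    def __init__(self, cfg: HashEncodingConfig, dim: int = 3, rng: np.random.Generator | None = None,
                 dtype=np.float32) -> None:
        if dim not in (3, 4):
            raise ValueError("dim must be 3 or 4")
        self.cfg = cfg
        self.dim = dim
        self.dtype = np.dtype(dtype)
        rng = rng if rng is not None else np.random.default_rng(0)
        self.table = rng.uniform(
            -1e-4, 1e-4, size=(cfg.levels, cfg.table_size, cfg.features)
        ).astype(self.dtype)
        self.clamp_count = 0
        # per-level per-axis resolutions, shape (levels, dim)
        spatial = cfg.level_resolutions()
        if dim == 3:
            self._res = np.stack([spatial] * 3, axis=1)
        else:
            temporal = cfg.temporal_resolutions()
            self._res = np.stack([spatial] * 3 + [temporal], axis=1)
        self._corner_offsets = np.array(
            list(product((0, 1), repeat=dim)), dtype=np.int64
        )  # (2^dim, dim)
        # dense addressing where the full vertex lattice fits in the table
        n_vertices = np.prod(self._res + 1, axis=1)
        self._dense = n_vertices <= cfg.table_size
        self._strides = [
            np.cumprod(np.concatenate([[1], self._res[l][:-1] + 1]))
            for l in range(cfg.levels)
        ]

    @property
    def output_dim(self) -> int:
        return self.cfg.output_dim

    # -- addressing ---------------------------------------------------------

    def _vertex_slots(self, corner_coords: list[np.ndarray], level: int) -> np.ndarray:
        """Map per-axis corner coordinates (each (P, 2^dim)) to table slots."""
        if self._dense[level]:
            strides = self._strides[level]
            slots = corner_coords[0] * int(strides[0])
            for a in range(1, self.dim):
                slots = slots + corner_coords[a] * int(strides[a])
            return slots
        with np.errstate(over="ignore"):
            h = corner_coords[0].astype(np.uint64) * _PRIMES[0]
            for a in range(1, self.dim):
                h = h ^ (corner_coords[a].astype(np.uint64) * _PRIMES[a])
        return (h & np.uint64(self.cfg.table_size - 1)).astype(np.int64)

    def _interp(self, x: np.ndarray) -> list[tuple[np.ndarray, np.ndarray]]:
        """Per level: (slots (P, 2^dim), weights (P, 2^dim))."""
        x = np.asarray(x, dtype=np.float64)
        out_of_box = (x < 0.0) | (x > 1.0)
        n_clamped = int(np.any(out_of_box, axis=-1).sum())
        if n_clamped:
            self.clamp_count += n_clamped
            x = np.clip(x, 0.0, 1.0)
        caches = []
        off = self._corner_offsets  # (2^dim, dim)
        for level in range(self.cfg.levels):
            res = self._res[level]
            p = x * res
            cell = np.minimum(np.floor(p), (res - 1).astype(np.float64))
            frac = p - cell
            cell_i = cell.astype(np.int64)
            corner_coords = [
                cell_i[:, a, None] + off[None, :, a] for a in range(self.dim)
            ]
            slots = self._vertex_slots(corner_coords, level)
            w = np.empty((x.shape[0], off.shape[0]), dtype=np.float64)
            w[:] = 1.0
            for a in range(self.dim):
                pair = np.stack([1.0 - frac[:, a], frac[:, a]], axis=1)  # (P,2)
                w *= pair[:, off[:, a]]
            caches.append((slots, w))
        return caches

    # -- forward / backward -------------------------------------------------

    def encode(self, x: np.ndarray, with_cache: bool = False):
        """Encode positions ``x`` of shape (P, dim) into (P, levels*features)."""
        x = np.atleast_2d(np.asarray(x, dtype=np.float64))
        if x.shape[-1] != self.dim:
            raise ValueError(f"expected {self.dim}-vectors, got shape {x.shape}")
        caches = self._interp(x)
        L, F = self.cfg.levels, self.cfg.features
        out = np.empty((x.shape[0], L * F), dtype=self.dtype)
        for level, (slots, w) in enumerate(caches):
            feats = self.table[level][slots]  # (P, 2^dim, F)
            wl = w[:, None, :].astype(self.dtype)
            out[:, level * F : (level + 1) * F] = (wl @ feats)[:, 0, :]
        if with_cache:
            return out, caches
        return out

    def backward(self, caches, dfeat: np.ndarray) -> np.ndarray:
        """Gradient of a scalar loss w.r.t. the feature table.

        ``dfeat`` has shape (P, levels*features); returns an array shaped like
        ``self.table``.
        """
        L, F = self.cfg.levels, self.cfg.features
        T = self.cfg.table_size
        dtable = np.zeros_like(self.table)
        for level, (slots, w) in enumerate(caches):
            g = dfeat[:, level * F : (level + 1) * F]  # (P,F)
            contrib = w[:, :, None] * g[:, None, :]  # (P, 2^dim, F)
            flat = slots.ravel()
            for f in range(F):
                dtable[level, :, f] = np.bincount(
                    flat, weights=contrib[:, :, f].ravel(), minlength=T
                ).astype(self.dtype)
        return dtable


def combine_static_dynamic(e3: np.ndarray, e4: np.ndarray) -> np.ndarray:
    """Element-wise sum of static (3D) and dynamic (4D) feature embeddings."""
    e3 = np.asarray(e3)
    e4 = np.asarray(e4)
    if e3.shape != e4.shape:
        raise ValueError(f"embedding shapes differ: {e3.shape} vs {e4.shape}")
    return e3 + e4


# ---------------------------------------------------------------------------
# spherical harmonics (real basis, degrees 0..3, graphics sign convention)

SH_DIM = 16

_C0 = 0.28209479177387814
_C1 = 0.4886025119029199
_C2 = (1.0925484305920792, 1.0925484305920792, 0.31539156525252005,
       1.0925484305920792, 0.5462742152960396)
_C3 = (0.5900435899266435, 2.890611442640554, 0.4570457994644658,
       0.3731763325901154, 0.4570457994644658, 1.445305721320277,
       0.5900435899266435)


def sh_encode(d: np.ndarray) -> np.ndarray:
    """Real spherical-harmonics basis (degrees 0..3, 16 coefficients).

    ``d`` is one or more direction vectors; non-unit inputs are normalized.
    """
    d = np.atleast_2d(np.asarray(d, dtype=np.float64))
    norm = np.linalg.norm(d, axis=-1, keepdims=True)
    if np.any(np.abs(norm - 1.0) > 1e-6):
        d = d / norm
    x, y, z = d[..., 0], d[..., 1], d[..., 2]
    xx, yy, zz = x * x, y * y, z * z
    out = np.empty(d.shape[:-1] + (SH_DIM,), dtype=np.float64)
    out[..., 0] = _C0
    out[..., 1] = -_C1 * y
    out[..., 2] = _C1 * z
    out[..., 3] = -_C1 * x
    out[..., 4] = _C2[0] * x * y
    out[..., 5] = -_C2[1] * y * z
    out[..., 6] = _C2[2] * (3.0 * zz - 1.0)
    out[..., 7] = -_C2[3] * x * z
    out[..., 8] = _C2[4] * (xx - yy)
    out[..., 9] = -_C3[0] * y * (3.0 * xx - yy)
    out[..., 10] = _C3[1] * x * y * z
    out[..., 11] = -_C3[2] * y * (5.0 * zz - 1.0)
    out[..., 12] = _C3[3] * z * (5.0 * zz - 3.0)
    out[..., 13] = -_C3[4] * x * (5.0 * zz - 1.0)
    out[..., 14] = _C3[5] * z * (xx - yy)
    out[..., 15] = -_C3[6] * x * (xx - 3.0 * yy)
    return out
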