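"""Hash-grid encodings and spherical-harmonics direction encoding."""

import numpy as np
import pytest
from numpy.testing import assert_allclose

from nerfrgbd.encoding import (
    SH_DIM,
    GridEncoder,
    HashEncodingConfig,
    combine_static_dynamic,
    sh_encode,
)

# independent re-derivation of the corner addressing used by the oracle below
_ORACLE_PRIMES = (1, 2654435761, 805459861, 3674653429)


def _oracle_slot(coords, res, table_size):
    n_vertices = 1
    for r in res:
        n_vertices *= r + 1
    if n_vertices <= table_size:
        slot, stride = 0, 1
        for c, r in zip(coords, res):
            slot += c * stride
            stride *= r + 1
        return slot
    h = np.uint64(0)
    for c, p in zip(coords, _ORACLE_PRIMES):
        h ^= np.uint64(c) * np.uint64(p)
    return int(h % np.uint64(table_size))


def _oracle_encode(enc: GridEncoder, x: np.ndarray) -> np.ndarray:
    """Naive multi-linear interpolation over all 2^dim corners."""
    from itertools import product

    cfg = enc.cfg
    out = np.zeros(cfg.levels * cfg.features)
    for level in range(cfg.levels):
        res = enc._res[level]
        p = np.clip(x, 0, 1) * res
        cell = np.minimum(np.floor(p).astype(int), res - 1)
        frac = p - cell
        acc = np.zeros(cfg.features)
        for off in product((0, 1), repeat=enc.dim):
            wgt = 1.0
            for a, o in enumerate(off):
                wgt *= frac[a] if o else 1.0 - frac[a]
            slot = _oracle_slot(cell + np.array(off), res, cfg.table_size)
            acc += wgt * enc.table[level, slot]
        out[level * cfg.features : (level + 1) * cfg.features] = acc
    return out


@pytest.fixture
def small_cfg():
    # coarse levels are densely addressed, fine levels hashed
    return HashEncodingConfig(n_min=4, n_max=32, levels=4, features=2, table_size_log2=9)


class TestLevelGeometry:
    def test_default_progression_is_geometric(self):
        res = HashEncodingConfig().level_resolutions()
        assert res[0] == 16 and res[-1] == 2048 and len(res) == 16
        b = 128.0 ** (1.0 / 15.0)
        expected = np.floor(16 * b ** np.arange(16) + 1e-9)
        assert_allclose(res, expected)

    def test_temporal_finest_equals_video_length(self):
        cfg = HashEncodingConfig(temporal_max_resolution=7)
        assert cfg.temporal_resolutions()[-1] == 7

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            HashEncodingConfig(n_min=64, n_max=16)


class TestGrid3D:
    def test_deterministic_and_linear_in_table(self, small_cfg, rng):
        enc = GridEncoder(small_cfg, dim=3, rng=rng, dtype=np.float64)
        x = rng.random((5, 3))
        assert_allclose(enc.encode(x), enc.encode(x))
        enc.table[:] = 0.0
        assert_allclose(enc.encode(x), 0.0)

    def test_matches_bruteforce_interpolation_oracle(self, small_cfg, rng):
        enc = GridEncoder(small_cfg, dim=3, rng=rng, dtype=np.float64)
        enc.table = rng.standard_normal(enc.table.shape)
        for x in rng.random((20, 3)):
            assert_allclose(enc.encode(x[None])[0], _oracle_encode(enc, x), atol=1e-10)

    def test_vertex_query_collapses_to_table_entry(self, small_cfg, rng):
        enc = GridEncoder(small_cfg, dim=3, rng=rng, dtype=np.float64)
        enc.table = rng.standard_normal(enc.table.shape)
        level, res = 1, None
        res = enc._res[level][0]
        v = np.array([2, 1, 3]) / res  # exact vertex of that level
        got = enc.encode(v[None])[0][level * 2 : (level + 1) * 2]
        expect = enc.table[level, _oracle_slot([2, 1, 3], enc._res[level], enc.cfg.table_size)]
        assert_allclose(got, expect, atol=1e-10)

    def test_out_of_box_positions_clamped_and_counted(self, small_cfg, rng):
        enc = GridEncoder(small_cfg, dim=3, rng=rng, dtype=np.float64)
        inside = enc.encode(np.array([[1.0, 1.0, 1.0]]))
        outside = enc.encode(np.array([[1.5, 2.0, 1.1]]))
        assert_allclose(inside, outside)
        assert enc.clamp_count == 1

    def test_continuity_lipschitz(self, small_cfg, rng):
        enc = GridEncoder(small_cfg, dim=3, rng=rng, dtype=np.float64)
        enc.table = rng.standard_normal(enc.table.shape)
        x = rng.uniform(0.05, 0.95, (50, 3))
        eps = rng.normal(scale=1e-6, size=(50, 3))
        d = np.abs(enc.encode(x + eps) - enc.encode(x)).max(axis=1)
        # piecewise-linear: bounded by finest resolution * max |table| * dim
        C = enc._res.max() * np.abs(enc.table).max() * 3
        assert np.all(d <= C * np.linalg.norm(eps, axis=1) + 1e-12)

    def test_gradient_matches_finite_differences(self, rng):
        cfg = HashEncodingConfig(n_min=2, n_max=4, levels=2, features=2, table_size_log2=7)
        enc = GridEncoder(cfg, dim=3, rng=rng, dtype=np.float64)
        enc.table = rng.standard_normal(enc.table.shape) * 0.1
        x = rng.random((7, 3))
        v = rng.standard_normal((7, cfg.output_dim))  # loss = sum(v * encode(x))
        _, caches = enc.encode(x, with_cache=True)
        g = enc.backward(caches, v)
        h = 1e-6
        idx = [(0, 3, 0), (1, 10, 1), (0, 60, 1)]
        for (l, s, f) in idx:
            enc.table[l, s, f] += h
            up = float((v * enc.encode(x)).sum())
            enc.table[l, s, f] -= 2 * h
            dn = float((v * enc.encode(x)).sum())
            enc.table[l, s, f] += h
            fd = (up - dn) / (2 * h)
            assert abs(fd - g[l, s, f]) <= 1e-4 * max(1.0, abs(fd))


class TestGrid4D:
    def test_degenerate_time_axis(self, small_cfg, rng):
        cfg = HashEncodingConfig(n_min=4, n_max=8, levels=2, features=2,
                                 table_size_log2=9, temporal_max_resolution=1)
        enc = GridEncoder(cfg, dim=4, rng=rng, dtype=np.float64)
        x = rng.random((4, 3))
        e0 = enc.encode(np.concatenate([x, np.zeros((4, 1))], axis=1))
        # with T_video = 1 every frame maps to t_norm = 0, same embedding
        assert_allclose(e0, enc.encode(np.concatenate([x, np.zeros((4, 1))], axis=1)))

    def test_matches_bruteforce_quadrilinear_oracle(self, rng):
        cfg = HashEncodingConfig(n_min=4, n_max=16, levels=3, features=2,
                                 table_size_log2=8, temporal_max_resolution=5,
                                 temporal_min_resolution=2)
        enc = GridEncoder(cfg, dim=4, rng=rng, dtype=np.float64)
        enc.table = rng.standard_normal(enc.table.shape)
        for x in rng.random((15, 4)):
            assert_allclose(enc.encode(x[None])[0], _oracle_encode(enc, x), atol=1e-10)

    def test_4d_vertex_collapse(self, rng):
        cfg = HashEncodingConfig(n_min=2, n_max=4, levels=2, features=2,
                                 table_size_log2=12, temporal_max_resolution=4,
                                 temporal_min_resolution=4)
        enc = GridEncoder(cfg, dim=4, rng=rng, dtype=np.float64)
        enc.table = rng.standard_normal(enc.table.shape)
        level = 0
        res = enc._res[level]
        coords = np.array([1, 0, 1, 2])
        v = coords / res
        got = enc.encode(v[None])[0][:2]
        assert_allclose(
            got, enc.table[level, _oracle_slot(coords, res, cfg.table_size)], atol=1e-10
        )


class TestCombine:
    def test_additive_identity_and_cancellation(self):
        e3 = np.array([1.0, 2.0])
        assert_allclose(combine_static_dynamic(e3, np.zeros(2)), e3)
        assert_allclose(combine_static_dynamic(e3, -e3), 0.0)
        assert_allclose(combine_static_dynamic(e3, np.array([3.0, 4.0])), [4.0, 6.0])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            combine_static_dynamic(np.zeros(4), np.zeros(6))


class TestSphericalHarmonics:
    def test_constant_term_and_length(self, rng):
        d = rng.standard_normal((10, 3))
        d /= np.linalg.norm(d, axis=1, keepdims=True)
        sh = sh_encode(d)
        assert sh.shape == (10, SH_DIM)
        assert_allclose(sh[:, 0], 1.0 / (2.0 * np.sqrt(np.pi)))

    def test_parity_under_direction_flip(self, rng):
        d = rng.standard_normal((20, 3))
        d /= np.linalg.norm(d, axis=1, keepdims=True)
        sp, sm = sh_encode(d), sh_encode(-d)
        assert_allclose(sm[:, 0:1], sp[:, 0:1], atol=1e-12)  # degree 0 even
        assert_allclose(sm[:, 1:4], -sp[:, 1:4], atol=1e-12)  # degree 1 odd
        assert_allclose(sm[:, 4:9], sp[:, 4:9], atol=1e-12)  # degree 2 even
        assert_allclose(sm[:, 9:16], -sp[:, 9:16], atol=1e-12)  # degree 3 odd

    def test_orthonormality_by_quadrature(self):
        """Independent oracle: numerically integrate Y_i Y_j over the sphere."""
        n_th, n_ph = 200, 400
        th = (np.arange(n_th) + 0.5) * np.pi / n_th
        ph = (np.arange(n_ph) + 0.5) * 2 * np.pi / n_ph
        TH, PH = np.meshgrid(th, ph, indexing="ij")
        d = np.stack(
            [np.sin(TH) * np.cos(PH), np.sin(TH) * np.sin(PH), np.cos(TH)], axis=-1
        ).reshape(-1, 3)
        Y = sh_encode(d)
        wgt = np.repeat(np.sin(th), n_ph) * (np.pi / n_th) * (2 * np.pi / n_ph)
        G = (Y * wgt[:, None]).T @ Y
        assert_allclose(G, np.eye(SH_DIM), atol=2e-3)

    def test_non_unit_input_normalized(self):
        assert_allclose(sh_encode(np.array([0.0, 0.0, 2.0])),
                        sh_encode(np.array([0.0, 0.0, 1.0])), atol=1e-12)
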