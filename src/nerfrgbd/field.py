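"""The radiance-field MLP: encoded position/time + encoded view direction
-> colour and volumetric density.

The network is split in the usual way for this model family: a position
trunk produces the raw density together with a geometry latent, and a small
colour head consumes the latent concatenated with the spherical-harmonics
direction features.  Density therefore cannot depend on viewing direction by
construction.  Activations: ReLU hidden, softplus for density (non-negative,
smooth), sigmoid for colour (componentwise in [0,1]).

Implemented in NumPy with an explicit backward pass; gradients are verified
against finite differences in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["FieldConfig", "RadianceFieldMLP"]


@dataclass
class FieldConfig:
    hidden_layers: int = 3
    hidden_width: int = 256
    geo_features: int = 15
    color_hidden_layers: int = 1
    color_hidden_width: int = 64
    density_activation: str = "softplus"  # or "trunc_exp"

    def __post_init__(self) -> None:
        if self.hidden_layers < 1 or self.hidden_width < 1:
            raise ValueError("hidden_layers and hidden_width must be >= 1")


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.log1p(np.exp(-np.abs(x))) + np.maximum(x, 0.0)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    return out


class RadianceFieldMLP:
    """MLP ``(c, sigma) = F_theta(gamma(x, t), d)`` with manual backprop."""

    def __init__(self, in_dim: int, sh_dim: int, cfg: FieldConfig | None = None,
                 rng: np.random.Generator | None = None, dtype=np.float32) -> None:
        self.cfg = cfg or FieldConfig()
        self.in_dim = in_dim
        self.sh_dim = sh_dim
        self.dtype = np.dtype(dtype)
        rng = rng if rng is not None else np.random.default_rng(0)
        c = self.cfg
        trunk_dims = [in_dim] + [c.hidden_width] * c.hidden_layers + [1 + c.geo_features]
        color_dims = (
            [c.geo_features + sh_dim]
            + [c.color_hidden_width] * c.color_hidden_layers
            + [3]
        )
        self.params: dict[str, np.ndarray] = {}
        for name, dims in (("trunk", trunk_dims), ("color", color_dims)):
            for i, (a, b) in enumerate(zip(dims[:-1], dims[1:])):
                scale = np.sqrt(2.0 / a)  # fan-in (He) scaling for ReLU nets
                self.params[f"{name}_w{i}"] = (rng.standard_normal((a, b)) * scale).astype(self.dtype)
                self.params[f"{name}_b{i}"] = np.zeros(b, dtype=self.dtype)
        self._n_trunk = len(trunk_dims) - 1
        self._n_color = len(color_dims) - 1

    def zero_output_layers(self) -> None:
        """Zero the final layer of both heads (diagnostic initialisation)."""
        self.params[f"trunk_w{self._n_trunk - 1}"][:] = 0
        self.params[f"trunk_b{self._n_trunk - 1}"][:] = 0
        self.params[f"color_w{self._n_color - 1}"][:] = 0
        self.params[f"color_b{self._n_color - 1}"][:] = 0

    # -- forward ------------------------------------------------------------

    def _check_finite(self) -> None:
        for k, v in self.params.items():
            if not np.all(np.isfinite(v)):
                raise FloatingPointError(f"non-finite values in parameter {k!r}")

    def query(self, feat: np.ndarray, sh: np.ndarray, with_cache: bool = False):
        """Evaluate the field for a batch of encoded inputs.

        Parameters
        ----------
        feat : (P, in_dim) combined positional embedding gamma(x, t)
        sh : (P, sh_dim) spherical-harmonics direction features

        Returns ``(color (P,3), sigma (P,))`` and optionally a cache for
        :meth:`backward`.
        """
        feat = np.asarray(feat, dtype=self.dtype)
        sh = np.asarray(sh, dtype=self.dtype)
        if feat.shape[1] != self.in_dim or sh.shape[1] != self.sh_dim:
            raise ValueError(
                f"input widths ({feat.shape[1]}, {sh.shape[1]}) do not match the "
                f"configured architecture ({self.in_dim}, {self.sh_dim})"
            )
        self._check_finite()
        trunk_acts = [feat]
        h = feat
        for i in range(self._n_trunk):
            z = h @ self.params[f"trunk_w{i}"] + self.params[f"trunk_b{i}"]
            h = np.maximum(z, 0.0) if i < self._n_trunk - 1 else z
            trunk_acts.append(h)
        sigma_raw = trunk_acts[-1][:, 0]
        latent = trunk_acts[-1][:, 1:]
        if self.cfg.density_activation == "trunc_exp":
            sigma = np.exp(np.clip(sigma_raw, -15.0, 15.0))
        else:
            sigma = _softplus(sigma_raw)
        cin = np.concatenate([latent, sh], axis=1)
        color_acts = [cin]
        h = cin
        for i in range(self._n_color):
            z = h @ self.params[f"color_w{i}"] + self.params[f"color_b{i}"]
            h = np.maximum(z, 0.0) if i < self._n_color - 1 else z
            color_acts.append(h)
        color = _sigmoid(color_acts[-1])
        if with_cache:
            cache = (trunk_acts, color_acts, sigma_raw, sigma, color)
            return color, sigma, cache
        return color, sigma

    # -- backward -----------------------------------------------------------

    def backward(self, cache, dcolor: np.ndarray, dsigma: np.ndarray):
        """Backprop through the MLP.

        Returns ``(grads, dfeat)`` where ``grads`` maps parameter names to
        gradients and ``dfeat`` is the gradient w.r.t. the positional
        embedding (needed to update the hash tables).
        """
        trunk_acts, color_acts, sigma_raw, sigma, color = cache
        grads: dict[str, np.ndarray] = {}

        # colour head: d/dz sigmoid(z) = s(1-s)
        delta = np.asarray(dcolor, dtype=self.dtype) * color * (1.0 - color)
        for i in range(self._n_color - 1, -1, -1):
            a_prev = color_acts[i]
            grads[f"color_w{i}"] = a_prev.T @ delta
            grads[f"color_b{i}"] = delta.sum(axis=0)
            delta = delta @ self.params[f"color_w{i}"].T
            if i > 0:
                delta *= color_acts[i] > 0
        dlatent = delta[:, : self.cfg.geo_features]

        # density branch
        if self.cfg.density_activation == "trunc_exp":
            dsigma_raw = np.asarray(dsigma, dtype=self.dtype) * sigma
        else:
            dsigma_raw = np.asarray(dsigma, dtype=self.dtype) * _sigmoid(sigma_raw)

        delta_t = np.concatenate([dsigma_raw[:, None], dlatent], axis=1)
        for i in range(self._n_trunk - 1, -1, -1):
            a_prev = trunk_acts[i]
            grads[f"trunk_w{i}"] = a_prev.T @ delta_t
            grads[f"trunk_b{i}"] = delta_t.sum(axis=0)
            delta_t = delta_t @ self.params[f"trunk_w{i}"].T
            if i > 0:
                delta_t *= trunk_acts[i] > 0
        dfeat = delta_t
        return grads, dfeat
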