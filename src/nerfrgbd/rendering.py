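"""Ray sampling and quadrature volume rendering.

Colour is accumulated along each ray as ``C = sum_i U_i (1 - exp(-sigma_i
delta_i)) c_i`` with transmittance ``U_i = exp(-sum_{j<i} sigma_j delta_j)``;
depth uses the same weights on the sample distances, ``D = sum_i w_i a_i``.
There is no background model and no normalisation by accumulated opacity:
unopacified residual transmittance renders black and contributes no depth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "RaySamples",
    "RenderResult",
    "sample_along_ray",
    "render_rays",
    "render_rays_backward",
    "render_patch",
]


@dataclass
class RaySamples:
    """Stratified samples along a batch of rays (all arrays (R, S))."""

    positions: np.ndarray  # (R, S, 3) world-frame points
    a: np.ndarray  # (R, S) distance from the camera along the ray
    delta: np.ndarray  # (R, S) spacing between consecutive samples


@dataclass
class RenderResult:
    C: np.ndarray  # (R, 3) predicted colour
    D: np.ndarray  # (R,) predicted depth (metres)
    weights: np.ndarray  # (R, S)
    opacity: np.ndarray  # (R,) = sum of weights


def sample_along_ray(
    origins: np.ndarray,
    directions: np.ndarray,
    S: int,
    near: float,
    far: float,
    rng: np.random.Generator | None = None,
) -> RaySamples:
    """Stratified sampling of S points per ray within [near, far].

    The interval is split into S equal bins; with an ``rng`` each sample is
    uniform in its bin (stratified), without one it sits at the bin midpoint
    (deterministic rendering mode).  The last spacing ``delta_S`` is set to
    the bin width, which keeps the weight-sum identity of the renderer exact.
    """
    if S < 2:
        raise ValueError("need at least 2 samples per ray")
    if not near < far:
        raise ValueError("need near < far")
    origins = np.atleast_2d(np.asarray(origins, dtype=np.float64))
    directions = np.atleast_2d(np.asarray(directions, dtype=np.float64))
    R = origins.shape[0]
    bin_width = (far - near) / S
    edges = near + bin_width * np.arange(S)
    if rng is None:
        a = np.broadcast_to(edges + 0.5 * bin_width, (R, S)).copy()
    else:
        u = rng.random((R, S))
        a = edges[None, :] + u * bin_width
    delta = np.empty_like(a)
    delta[:, :-1] = np.diff(a, axis=1)
    delta[:, -1] = bin_width
    positions = origins[:, None, :] + a[:, :, None] * directions[:, None, :]
    return RaySamples(positions=positions, a=a, delta=delta)


def render_rays(
    sigma: np.ndarray, color: np.ndarray, a: np.ndarray, delta: np.ndarray,
    with_cache: bool = False,
):
    """Quadrature rendering of a batch of rays.

    Parameters: ``sigma`` (R,S) non-negative densities, ``color`` (R,S,3),
    ``a`` (R,S) camera distances, ``delta`` (R,S) positive spacings.
    """
    sigma = np.atleast_2d(np.asarray(sigma, dtype=np.float64))
    delta = np.atleast_2d(np.asarray(delta, dtype=np.float64))
    a = np.atleast_2d(np.asarray(a, dtype=np.float64))
    color = np.asarray(color, dtype=np.float64).reshape(sigma.shape + (3,))
    if np.any(sigma < 0) or np.any(delta <= 0):
        raise ValueError("densities must be >= 0 and spacings > 0")
    tau = sigma * delta
    # U_i = exp(-sum_{j<i} tau_j): exclusive cumulative sum
    cum = np.cumsum(tau, axis=1)
    U = np.exp(-(cum - tau))
    alpha = -np.expm1(-tau)  # 1 - exp(-tau), accurate for small tau
    w = U * alpha
    C = np.einsum("rs,rsc->rc", w, color)
    D = (w * a).sum(axis=1)
    opacity = w.sum(axis=1)
    result = RenderResult(C=C, D=D, weights=w, opacity=opacity)
    if with_cache:
        return result, (sigma, color, a, delta, U, alpha, w)
    return result


def render_rays_backward(cache, dC: np.ndarray, dD: np.ndarray):
    """Gradients of the rendered colour/depth w.r.t. per-sample sigma and colour.

    ``dC`` is (R,3), ``dD`` is (R,).  Returns ``(dsigma (R,S), dcolor (R,S,3))``.
    """
    sigma, color, a, delta, U, alpha, w = cache
    dC = np.asarray(dC, dtype=np.float64)
    dD = np.asarray(dD, dtype=np.float64)
    # dL/dw_i = dC . c_i + dD * a_i
    dLdw = np.einsum("rc,rsc->rs", dC, color) + dD[:, None] * a
    # w_i = U_i (1 - e^{-tau_i});  dw_i/dtau_i = U_i e^{-tau_i};
    # dw_i/dtau_j (j<i) = -w_i.  Suffix sums give the second term.
    emt = 1.0 - alpha  # exp(-tau)
    direct = dLdw * U * emt
    prod = dLdw * w
    # suffix_j = sum_{i>j} prod_i
    suffix = np.cumsum(prod[:, ::-1], axis=1)[:, ::-1] - prod
    dtau = direct - suffix
    dsigma = dtau * delta
    dcolor = w[:, :, None] * dC[:, None, :]
    return dsigma, dcolor


def render_patch(
    field_fn,
    origins: np.ndarray,
    directions: np.ndarray,
    shape: tuple[int, int],
    S: int,
    near: float,
    far: float,
    t_norm: float = 0.0,
    rng: np.random.Generator | None = None,
    pixel_spacing: float = 1.0,
    stencil: str = "forward",
):
    """Render an (M, N) patch of rays into colour, depth and normal maps.

    ``field_fn(positions (P,3), directions (P,3), t_norm)`` must return
    ``(color (P,3), sigma (P,))`` — either the neural field or an analytic
    density for tests.  Normals are derived from the rendered depth map with
    the same operator used for supervision targets.
    """
    from .losses import normals_from_depth

    M, N = shape
    R = M * N
    origins = origins.reshape(R, 3)
    directions = directions.reshape(R, 3)
    samples = sample_along_ray(origins, directions, S, near, far, rng=rng)
    P = R * S
    pos = samples.positions.reshape(P, 3)
    dirs = np.repeat(directions, S, axis=0)
    c, sigma = field_fn(pos, dirs, t_norm)
    result = render_rays(
        sigma.reshape(R, S), c.reshape(R, S, 3), samples.a, samples.delta
    )
    color_map = result.C.reshape(M, N, 3)
    depth_map = result.D.reshape(M, N)
    normal_map = None
    if M >= 2 and N >= 2:
        normal_map = normals_from_depth(depth_map, pixel_spacing=pixel_spacing, stencil=stencil)
    return color_map, depth_map, normal_map, result
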