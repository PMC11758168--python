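# Methods

## The reconstruction problem

A handful of fixed RGB-D cameras observe a room from entirely different
vantage points — the typical multi-camera rig of an operating room.  Each
camera provides colour images, metric time-of-flight (ToF) depth aligned to
the colour viewpoint, calibrated intrinsics/extrinsics, and (for videos) a
time index per frame.  With so few and such divergent views, photometric
supervision alone leaves the 2D→3D problem badly ill-posed: a radiance field
can reproduce the training views while placing density almost anywhere.

The package fits a neural radiance field to such data with three
complementary supervision signals:

1. **Colour** — squared error between rendered and observed pixel colours.
2. **Metric sensor depth** — squared error between rendered depth and the ToF
   measurement, on pixels where the sensor returned a value.  ToF maps are
   incomplete: zeros appear at the sensor border, on reflective materials and
   in "depth shadows" around object boundaries.
3. **Surface normals from dense depth** — a monocular depth estimator
   provides a *complete* but only relative-scale depth map.  Its absolute
   values are meaningless in the camera's metric frame, but the *direction of
   local depth change* is informative exactly where the ToF map has holes.
   Normals computed from depth gradients are invariant to additive depth
   offsets, which makes them comparable across depth modalities of different
   scale.

## Model

The scene is the function `(c, σ) = F_Θ(γ(x, t), d)`: colour `c ∈ [0,1]³`
and density `σ ≥ 0` at position `x`, time `t`, viewing direction `d`.

**Positional encoding** `γ` is a multiresolution hash grid.  Positions are
normalized into the unit cube by the manifest's scene bounds.  Each of `L`
levels is a virtual grid whose resolution grows geometrically from `n_min`
to `n_max` (`N_l = ⌊n_min · b^l⌋`, `b = exp((ln n_max − ln n_min)/(L−1))`);
a level stores `F`-dimensional feature vectors in a table of `2^k` entries,
addressed densely when the full vertex lattice fits and through a prime-XOR
spatial hash otherwise.  Queried features are the trilinear interpolation of
the 8 cell corners.  Dynamic scenes add a second, 4-dimensional grid over
(x, y, z, t_norm) with quadrilinear interpolation, whose finest temporal
resolution equals the video length so each frame can occupy its own temporal
cell; static and dynamic embeddings are summed element-wise,
`γ(x,t) = γ_3D(x) + γ_4D(x,t)`.  Positions outside the unit cube are clamped
and counted.  Tables initialize uniformly in [−10⁻⁴, 10⁻⁴].

**Direction encoding** is the real spherical-harmonics basis up to degree 3
(16 coefficients, graphics sign convention).

**The MLP** splits into a position trunk (ReLU, `hidden_layers × hidden_width`)
that outputs raw density plus a 15-dimensional geometry latent, and a small
colour head consuming latent ⊕ SH features.  Density therefore cannot depend
on the viewing direction by construction.  Density activation is softplus
(smooth, non-negative; a truncated exponential is available by config),
colour activation sigmoid.

**Volume rendering** uses the standard quadrature: with sample spacings `δ_i`
and transmittance `U_i = exp(−Σ_{j<i} σ_j δ_j)`, per-sample weights are
`w_i = U_i (1 − e^{−σ_i δ_i})`, colour is `Σ w_i c_i` and depth `Σ w_i a_i`
where `a_i` is the metric distance from the camera along the ray.  There is
no background model and no division by accumulated opacity: residual
transmittance renders black and contributes no depth.  The last spacing
`δ_S` is set to the stratified bin width, which keeps the identity
`Σ w_i = 1 − exp(−Σ σ_i δ_i)` exact — the test suite asserts it to 1e-5.

## Losses and patch-based training

Per training step, a random frame is drawn, then a random `M×N` (default
8×8) pixel patch at a resolution level `l` drawn uniformly from
`{0..p_levels−1}`; the patch's pixels are `2^l` apart, so coarse levels
supervise normals over larger spatial baselines.  Strided patches index the
target images at the strided pixel positions (no downsampling/averaging).
All patch rays are rendered, and

    L = L_color + α·L_depth + β·L_normal,    α = β = 0.5 by default,

with all three terms **summed** (not averaged) over the patch rays — the
default weights are calibrated against the summed form.  `L_depth` is masked
to pixels with a non-zero sensor value and is zero when the whole patch lacks
depth (a counter records such steps).

**Normal operator.**  The supervision normal at a patch pixel is

    N = (∂D/∂x, ∂D/∂y, 1) / ‖(∂D/∂x, ∂D/∂y, 1)‖₂ ,

with forward finite differences across the patch grid (defined on the
(M−1)×(N−1) support; a central stencil is available by config) and the pixel
spacing scaled by the patch stride `2^l`.  The gradient-to-normal promotion
makes the third component positive (front-facing convention); any consistent
sign convention is equivalent under the symmetric loss as long as both sides
use the same operator.  The predicted normal map N̂ is computed *from the
rendered depth patch* with the identical operator — the model has no analytic
density-gradient normals, and using the same operator on both sides is what
makes the comparison meaningful.  Dense-depth values are used as-is (relative
scale, typically in [0,1]); no affine alignment to sensor depth is performed —
offset invariance is exact by construction, and residual sensitivity to the
multiplicative scale is small (tested: < 30° mean angular change for scale
factors in [0.5, 2] on smooth surfaces).

One 8×8 patch is 64 rays, which we treat as one optimizer step's batch;
`patches_per_step` scales this up.  Optimization is Adam (β₁ = 0.9,
β₂ = 0.99, ε = 10⁻¹⁵) at learning rate 0.01 with no schedule, for a fixed
iteration budget (2000 for static scenes by default).  Training aborts with
diagnostics and the last periodic parameter snapshot if the loss goes
non-finite.

## Implementation notes

The field, encodings, renderer and losses are implemented in NumPy with
hand-written backward passes (renderer and interpolation gradients in closed
form, standard MLP backprop); every backward path is verified against finite
differences in the test suite.  Training arithmetic defaults to float32;
gradient-check tests run the same code in float64.  Loss trajectories are
bit-reproducible for a fixed seed because all stochastic draws derive from
one seeded generator and execution is serial; the `deterministic` config
flag documents that intent but does not change the numerics.

### Default parameters

| parameter | default | notes |
|---|---|---|
| patch size M×N | 8×8 | 64 rays per step |
| resolution levels `p_levels` | 4 | reference value; 3 in the desk preset (a stride-8 patch spans 57 px > 48 px) |
| loss weights α, β | 0.5, 0.5 | summed-loss calibration |
| learning rate | 0.01 | Adam, no decay |
| iterations | 2000 static / 10000 dynamic reference | desk tests use 1000–2000 |
| samples per ray S | 128 | reference configuration uses orders of magnitude more with GPU-class throughput |
| encoding (reference) | n_min 16, n_max 2048, L 16, F 2, table 2^21 | `HashEncodingConfig` defaults |
| encoding (desk preset) | n_max 512, L 8, table 2^16 | `desk_train_config()`; sized for 48-px images, chosen by benchmarking fit quality at equal runtime |
| MLP | 3 × 256 reference; 3 × 64 desk | hidden layers count the hidden stack; sigma/latent head width 16 |
| SH degree | 3 | 16 coefficients |

## Synthetic test bed

`nerfrgbd.synthetic` generates complete datasets standing in for multi-camera
room captures: analytic scenes (checkerboard ground plane, four room walls,
two textured spheres — one labelled reflective — and a box "table") rendered
from `n` cameras on a ring at varied heights, all facing the scene centre,
60° FOV, angular separation 360/n°.  Ground-truth colour and depth are exact
ray-primitive intersections; depth is the metric distance along the pixel
ray.  Sensor depth is the true depth corrupted by the three ToF mechanisms:
a zeroed border margin, Bernoulli dropout on reflective-labelled surfaces,
and depth shadows — pixels within a window of an object boundary (a change in
the primitive label map) across which depth jumps by more than a threshold.
A label change alone (two touching surfaces) casts no shadow, and a steep but
continuous surface is not a boundary; at 48-px resolution a pure
depth-range detector would flag most of the obliquely viewed floor.  Pixels
whose ray exits the scene without a hit are zeroed as out-of-range.  Dense
depth is an affine map of true depth to [0, 1] plus a smooth low-frequency
perturbation (≤ 2% of range) standing in for estimator error.  Dynamic
presets translate one sphere at constant velocity (0.15 m per time step).

What the generator does **not** emulate: view-dependent shading, image noise,
calibration error, ToF multi-path and asynchronicity, and the systematic
(non-affine) distortions of real monocular depth estimators.  Passing tests
therefore demonstrate the correctness and the geometric behaviour of the
method, not its photometric performance on real OR captures.

### Problem sizes used by the test suite

Desk-scale runs use 48×48 images, 6 cameras, S = 128, and 1000–2000
iterations (1500 for the dynamic odd/even protocol with T = 4); these sizes
were chosen so a full fit is a couple of minutes of single-core work while
leaving every qualitative relationship of the method intact.

## Evaluation

PSNR uses peak 1.0 on float images.  SSIM is the standard Gaussian-window
form (11×11, σ = 1.5, K1 = 0.01, K2 = 0.03) on the luma channel.  Depth
errors are reported on pixels with a valid sensor measurement, consistent
with the loss masking.  Protocols: `train-views` (fit quality),
`holdout-view` (all frames of a camera excluded from training), and
`even-frames` (dynamic: train odd `t`, synthesize even `t` from training
camera poses, reported per time step).  A circular-trajectory generator
renders novel-view sweeps starting from a training camera's azimuth.

## Known limitations

* No occupancy acceleration: the reference sample count (16384/ray) is
  config-reachable but impractical here; desk runs use S = 128.
* No hierarchical (coarse/fine) sampling, proposal networks, background
  model, or per-image appearance embeddings.
* The 4D grid interpolates between trained time steps; extrapolation beyond
  the last trained frame falls back towards the static component (near-zero
  dynamic features).
* `D̂` is not normalized by opacity, so depth supervision also implicitly
  pushes rays towards full opacity; this matches the rendering equations
  used but means depth in nearly transparent regions is biased low.
* Dense-depth normals inherit the estimator's (here: the mock's) affine
  scale; gradient magnitudes differ from metric ones, so normal supervision
  is strongest where surfaces are near-fronto-parallel and weakest at
  grazing angles.
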