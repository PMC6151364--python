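# Methods

This note records the models the package implements, the numerical choices
behind them, and what the synthetic phantoms do and do not establish about
behavior on real 3D echocardiography (3DE).

## Problem setting

Left-ventricle (LV) segmentation on 3DE is hard for two reasons the pipeline
is built around: the images are speckle-dominated with weak edges, and the
left atrium (LA) shares the LV's blood-pool intensity across the open mitral
valve, so boundary-seeking methods tend to "leak" from ventricle into atrium.
The pipeline is coarse-to-fine: a 2D fully-convolutional classifier segments
each short-axis slice (coarse), a geometric stage turns the coarse masks into
a ring-parametrized surface `X_init`, and a spatially regularized 3D active
surface (snake) refines it (fine).

## Phantoms

`lvseg.phantom` generates the study volumes. The LV cavity is a truncated
half-ellipsoid with semi-axes `(a, b, c)` mm (default 14, 14, 28 on a 64 mm³
grid at 1 mm isotropic spacing) — the standard geometric LV approximation,
consistent with the circular short-axis cross-section assumption the
initializer also makes. A constant-thickness bright wall (default 4 mm) is
obtained by thresholding the Euclidean distance transform of the blood pool,
so the wall follows every cavity, including the atrium and the mitral
channel. Intensities default to cavity 0.10, wall 0.80, background 0.30.

Speckle is multiplicative unit-mean gamma noise (`speckle_scale` = relative
standard deviation, default 0.15) followed by Gaussian smoothing (1 mm).
This is a first-order B-mode texture surrogate: it reproduces the
low-contrast, noisy character of ultrasound but none of its physics (no
sector geometry, no attenuation, no anisotropic point-spread function, no
shadowing). Tests passing on phantoms therefore establish the geometric and
numerical correctness of the pipeline, not clinical-grade accuracy.

When `atrium_enabled` is set, an atrial cavity (0.85× the LV width) sits
`atrium_offset` mm past the basal plane, connected through a channel of
`mitral_opening_radius` (default 12 mm ≈ the basal cavity radius). The wide
opening is deliberate: with the valve open, the LV–LA junction carries almost
no intensity edge, which is exactly the leak hazard the fine stage must
survive. A narrow opening would leave a bright basal shelf that trivially
stops any method.

`degrade_mask` emulates coarse classifier output on a clean mask: per-slice
erosion/dilation jitter (±1 voxel), random hole dropout (rate 0.1/slice), and
spurious off-target blobs (rate 0.2/slice). These are the failure modes the
initializer is designed to absorb (largest-component selection, curve-fitted
centers, averaged radii).

`sphere_phantom` is a separate validation target: a ball with a clean radial
edge at every latitude, for which the analytic answer of any edge-seeking
surface is known exactly.

## Coarse stage

The classifier is a fusion fully-convolutional network: an encoder of
`depth` = 4 stages (two 3×3 conv + BN + ReLU per stage, 2×2 max-pool), and
one *skip stream* per selected pooling stage P1..P4. Each stream applies a
residual block (four conv-BN-ReLU layers inside an identity shortcut),
projects to the two class channels with a 1×1 convolution, and upsamples to
input resolution with a learned transposed convolution whose kernel equals
its stride (each coarse pixel expands to a learned patch; non-overlapping,
fast, and exactly the adjoint of strided averaging). The final score map is
the sum of the stream score maps. The two deepest streams form the baseline
fusion and are always present; P1/P2 add fine detail. Channel widths are
configurable (`base_width`, capped at 4×) so the identical topology trains at
desk scale.

The layers are implemented directly on numpy arrays with explicit
forward/backward passes (im2col convolution, standard batch-norm backward,
first-argmax pooling gradient) and a momentum-SGD optimizer; a numeric
gradient check of the assembled network is part of the development history
and the loss/gradient identities are covered by the test suite. Pretrained
backbone weights can be injected by name through `load_state_dict` — the
package ships no weights and trains from random (He) initialization.

The loss is class-balanced cross-entropy: with `Y+` foreground and `Y-`
background pixels and `a = Y-/(Y+ + Y-)`,
`Loss = -a Σ_fg log P(y=1) - (1-a) Σ_bg log P(y=0)`.
Probabilities are clamped at 1e-12 inside the log (the expression is
undefined at P = 0). For optimization the batch loss is additionally divided
by the pixel count so learning rates are resolution-independent; the
reported/public loss is the plain sum above.

Training is two-stage: the encoder is frozen for `stage1_iter` iterations
while the streams/upsamplers learn, then everything fine-tunes. The learning
rate decreases linearly in steps:
`lr(t) = lr0 · (1 − ⌊t/decay_every⌋ · decay_every / max_iter)` — the phrase
"linear decrease every N iterations" is ambiguous; this step-wise reading is
the adopted interpretation. Defaults mirror a full-scale schedule
(lr0 1e-4, momentum 0.99, batch 256, 10 000 iterations, stage 1 = 1000);
the desk-scale runs in the tests and acceptance script use 200 slices at
64×64, `base_width` 8, batch 8, lr0 0.2, momentum 0.9, 300 iterations
(stage 1 = 50) — sizes chosen so a single-CPU run finishes in minutes, and
the threshold they are checked against (mean IOU > 0.8) was established by
running that experiment across seeds (observed 0.83–0.92).

Slicing-based augmentation: volumes are cut along Z into 2D planes
(multiplying samples by the Z extent), gray slices are replicated to three
identical channels (the input contract of RGB-pretrained encoders), and
random rotation/resizing is applied identically to image and mask, with the
mask re-binarized at 0.5 after interpolation. Exact multiples of 90° at
scale 1 take a grid-exact `rot90` path.

## Initialization

From the coarse mask stack: (1) per-slice centers as the mean foreground
coordinate; (2) least-squares quadratic fit of x(z), y(z) over foreground
slices — raw centers of noisy masks are non-collinear, and stacking rings on
them misaligns slices; the fit also interpolates across empty interior
slices; (3) per-slice radius as the mean of 8 ray-cast radii at 45°
increments, `R = (R1+…+R8)/8`, measured on the corrected centers against the
slice's largest connected component (islands ignored); rays that never meet
foreground are excluded, and a slice with fewer than 4 valid rays is
rejected; (4) ring resampling at interval `k` (0-based positions 0, k, 2k, …;
the basal ring is force-included so the tube spans the chamber); (5) tube
meshing: adjacent rings stitched with 2N triangles by angular index, an apex
fan closing the apical end (apex placed one slice beyond the apical ring on
the fitted center curve), base left open. N = 36 points per ring (10°
sampling) by default. Apex/base orientation is auto-detected from the
foreground-area trend along z and can be overridden.

## Fine stage: spatially regularized 3D snake

State: the ring grid (M × N × 3) plus the apex. Energy per vertex:

    E = ½α|X′|² + ½β|X″|² + δ·E_ext(X) + η·|X − X_init|²

* **Internal terms.** The parametric derivatives are realized as circular
  finite differences along each ring (unit parameter step) and open-chain
  differences along the apex-to-base direction, the apex heading every
  angular chain. Because rings sit several image slices apart while ring
  points are ~2 mm apart, the chain differences use a parameter step equal to
  the mean axial ring gap divided by the mean in-ring point spacing — the
  standard non-uniform-grid quadrature of the continuous integral. With unit
  steps instead, the sparse vertical direction would feel a tension out of
  proportion to the dense angular one and the tube would collapse axially.
* **External term.** `E_ext = −‖∇(G_σ * I)‖²`, the classical edge-attraction
  energy, normalized to [−1, 0] so that δ weighs images of any contrast
  comparably. It is sampled by trilinear interpolation whose analytic
  in-cell derivative supplies the force, making value and force consistent —
  the total analytic gradient matches central finite differences to < 1e-4
  relative error, which the test suite asserts.
* **Regularization term.** `η|X − X_init|²` ties each vertex to its
  initialization counterpart (correspondence by ring/index, which exists by
  construction). Its gradient is `2η(X − X_init)`.

Minimization is explicit-Euler gradient descent `X ← X − τ∇E`
(τ = 0.1 mm per unit force), stopping when the mean vertex displacement
falls below `tol` = 1e-3 mm or at 500 iterations; out-of-bounds vertices are
clamped to the volume and counted; a non-finite energy aborts. Weights
default to α = 0.1, β = 0.2, δ = 0.1, η = 0.1 and the ring resampling
interval to k = 10. Both ½ factors are used on the internal terms (the
conventional form). Vertices move in full 3D.

The basal ring is *not* hard-pinned to its plane by default (a
`pin_base_plane` option exists): axial drift of the open base at the
edge-free mitral junction is precisely the failure mode the η-term exists to
prevent, and pinning it would decide by fiat what the regularization should
decide by energy. Observed behavior on the atrium phantom: with η = 0.1 the
surface stays at the initialization (zero vertices beyond the basal plane);
with η = 0 the unanchored tube retracts and deforms absurdly at the junction
(~3× worse Hausdorff distance). An *upward* excursion into the atrium does
not occur in this energy: a pure edge-attraction snake under gradient
descent cannot cross the external-energy gap between the LV edge basin and
the atrial one (there is no balloon/pressure term, which is out of scope),
so the ablation manifests as basal collapse rather than atrial overshoot —
either way, the spatial tie is what keeps the base where the chamber ends.

## Metrics

* Mean surface distance `d_m = d̄(S, S_t) + d̄(S_t, S)` — the **sum** of the
  directed mean nearest-point distances (an `average=True` flag gives the
  halved convention common elsewhere; all numbers this package reports use
  the summed form).
* Hausdorff `d_h` — the standard symmetric max-min distance.
* Modified Dice `D* = 1 − 2|V∩V_t|/(|V|+|V_t|)` on voxel masks (0 perfect).
* `EF = (EDV − ESV)/EDV`; volumes in ml via voxel volume / 1000.
* Bland-Altman bias (mean estimate−reference difference), sample SD
  (ddof = 1), limits = bias ± 1.96·SD.
* 2-class pixel metrics: accuracy, mean per-class recall, mean IOU; classes
  absent from the truth are excluded from means with a warning.

Surfaces are compared point-set-to-point-set on area-weighted random samples
of the meshes (default 5000 points; 20 000 where sub-voxel tolerances are
asserted, since the finite-sample nearest-neighbour excess of two 5000-point
clouds of this surface area is itself ~0.6 mm on the summed convention) with
a KD-tree; the O(n²) brute-force oracle is kept in the tests.

## Problem sizes

Phantoms are 64³ voxels at 1 mm; toy training uses 200 slices of 64×64 for
300 iterations; snake runs use ≤ 2000 iterations on meshes of ~7–15 rings ×
36 points. These sizes make the full suite and the acceptance script
single-CPU friendly while keeping every stage's behavior observable.

## Known limitations

* The phantom's speckle is statistically, not physically, ultrasound-like;
  transfer of the trained toy network to real 3DE is not claimed.
* The snake has no balloon/pressure force and no topology changes; it
  refines a good initialization rather than segmenting from scratch.
* Per-slice contours are circles by construction; strongly non-circular
  cross-sections (aneurysms, trabeculation) are outside the model.
* The transposed-convolution upsamplers are non-overlapping; class maps are
  blocky at the stream strides, which bounds the achievable boundary
  precision of the coarse stage (the fine stage exists to fix this).
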