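# Methods

This note documents the models, conventions and numerical choices behind
`mr4dctreg`, and what the synthetic experiments do and do not demonstrate.

## Coordinate and field conventions

Images live on axis-aligned regular grids; a voxel's physical position is
its center, and a grid's extent is the box of centers plus half a spacing
per side. Displacement fields are stored in *voxel units of their own
grid* and define the map `φ(x) = x + u(x)`; warping an image samples the
moving image at `φ(x)` (so the field "pulls" intensities from the moving
frame). Fields are converted to millimetres only at NIfTI export (4D
volume, last axis = xyz). Composition follows the warping order:
`compose(φ_then, φ_after)(x) = u2(x) + u1(x + u2(x))`, so warping once
with the composition matches warping sequentially up to one extra
interpolation.

Oblique NIfTI affines are rejected rather than silently reoriented: the
pipeline resamples everything onto the CT reference grid up front, and
supporting rotated headers would add failure modes without adding
capability.

Intensities are normalized for loss/network consumption — CT clamped to
[−1000, 1000] HU and mapped to [0, 1], MR scaled by its 1st–99th
percentiles — as an explicit step, not inside the reader, so that files
round-trip bit-identically. Bounded inputs are required by the MI
histogramming.

## SVF parametrization and integration

Deformations are exponentials of stationary velocity fields, computed by
scaling and squaring: scale `u` by `2^-N`, then self-compose `N = 7`
times. Self-composition samples the field with border-clamped coordinates
(preventing boundary blow-up), while image warping uses zero fill to
match the zero-padding convention of the preprocessing. Against a
256-step Euler flow integration the 7-step map agrees to well under 0.1
voxel for smooth velocities up to 3 voxels, and negating the velocity
inverts the warp to ≲0.05 voxel in the interior — the practical content
of "near-diffeomorphic".

Jacobians are computed on the map `x + u(x)` with central differences
(one-sided at faces). A voxel counts as folded when `det ≤ 0` — the
degenerate `det = 0` is treated conservatively as folded, a choice this
package makes explicit because conventions differ. The log-Jacobian
standard deviation is taken over voxels with `det > 1e-6`, where the log
is well defined. Folding counts are reported as percentages.

## Losses

* **LNCC** — squared windowed normalized cross-correlation (default 9³
  window), with per-voxel in-window counts so boundary statistics are
  exact, and variances clamped at 1e-5 (stabilizes constant patches).
  The squared form is sign-robust; loss = 1 − mean NCC². Window size is
  configurable; no canonical value exists for this task, and 9³ at the
  working resolution is common practice for abdominal CT.
* **Mutual information** — differentiable Parzen-window joint histogram,
  32 bins, Gaussian kernels of one bin width centered on bin centers,
  per-voxel normalized weights; MI in nats. Restricting to a mask is a
  row-weighting of the joint histogram and equals computing on the voxel
  subset. For well-separated intensity levels the estimator recovers the
  exact label entropy (the within-level kernel spread factorizes out of
  the MI sum), which is what the quantized-image oracle checks.
* **Soft Dice** — per-organ probability channels, ε = 1e-5 in numerator
  and denominator, mean over organs; an organ empty on both sides
  contributes zero loss.
* **DetJac penalty** — `mean((det ∇φ − 1)²)`, same Jacobian scheme as the
  QA report: it penalizes volume change and foldings without penalizing
  large rigid-like motion, which is why the temporal branch uses it.
* **First-order penalty** — mean squared forward-difference derivative of
  `u` over 3 components × 3 axes; zero for any translation. The
  multi-modal branch wants *small* warps after rigid alignment, hence a
  magnitude-of-gradient regularizer instead.

All losses reduce by means, so the weights (λ, γ) are independent of the
working resolution. The Dice supervision warps the *moving organ
probabilities with the field predicted from the images* — one field per
image pair; trilinear (soft) warping keeps it differentiable, while
exported contours are warped nearest-neighbour.

## Network and training

The SVF predictor is an attention-gated 3D encoder–decoder (levels and
base channels configurable; gates can be disabled for a plain U-Net).
The final convolution is initialized at 1e-5 scale so an untrained
network predicts a near-identity warp — registration must start from
identity or early training destroys the images it is comparing.

The backend is a small reverse-mode autodiff engine on float64 numpy
arrays implementing exactly the needed operations (3D convolution as
shift-accumulated matmuls, 2× average pooling / nearest upsampling,
trilinear grid sampling with gradients w.r.t. both image and
displacement, finite-difference stencils as explicit linear operators
with hand-derived adjoints). Gradients are finite-difference-checked in
the test suite.

Training uses Adam (lr 1e-3 by default) with global gradient-norm
clipping at 1.0 — the registration objective is stiff: once a field
folds, the Jacobian penalty explodes and unclipped steps diverge.
Sampling, initialization and the training loop are fully seeded; the
checkpoint with the best validation loss is retained (validation at
iteration 0 counts, so the retained model is never worse than the
near-identity start).

The direct model reuses the multi-modal objective on (MR, CT-φ) pairs for
all six phases: mutual information is the only similarity in the package
that is valid across modalities at every phase.

## Rigid pre-registration

6-DOF (translation mm, per-axis rotations about the volume center),
optimized by Powell's method over a 64-bin histogram-MI objective on a
3-level image pyramid, from the identity start plus two seeded random
restarts at the coarsest level. If the search cannot improve on the
identity, the identity is returned with `converged=False`. Derivative-free
search is robust for coarse alignment and completely seedable; MI keeps
the objective consistent with the multi-modal branch. The recovered map
is exported as a dense field so rigid and deformable legs compose through
one mechanism, and the MR support mask transported by it defines the
overlap region Ω∩.

## Phantom generator

One phantom study = superellipsoid organs (body, lungs, heart, stomach,
liver, spleen, kidneys, vertebrae) at anatomically plausible relative
positions with seeded jitter, HU-like CT contrast plus Gaussian texture
(sd 20 HU); respiratory motion prescribed *as an SVF per phase*:
superior–inferior velocity `−a(φ)·A·w(x)` with `a(φ) = (cos 2πφ + 1)/2`
(zero at the 50% reference, maximal at 0%), `w` = 1 below the diaphragm
plane (placed just above the liver dome) decaying smoothly to zero toward
the lung apex and the lateral grid boundary, plus small seeded lateral
components (≤ 0.2 A). The default excursion A = 15 mm is a typical
liver-SBRT diaphragm amplitude. Phase labels {0,16,33,50,66,83}% are read
as sixths of the cycle. The MR volume applies a permuted organ-contrast
table (re-drawn until |Spearman ρ| ≤ 0.5 against the CT means, so the
modalities genuinely disagree), a smooth ±10% bias field, noise, a known
rigid misalignment (default (6, −4, 8) mm, 0.02 rad about z) and a 75% z
field-of-view crop. Optional binning artifacts duplicate a shifted axial
slab with a configurable per-phase probability.

Because motion lives in the same parametrization the networks predict,
ground truth is exact: propagating contours with the generating fields
reproduces the phase labels, and the reference-phase field is identically
zero.

What the phantom does *not* emulate: sliding interfaces (liver/chest
wall), scanner-specific noise spectra and reconstruction artifacts,
anatomical variability beyond jittered ellipsoids, and MR distortion.
Passing the phantom experiments therefore demonstrates that the machinery
(losses, integration, composition, training dynamics, statistics) is
correct and that the networks can recover motion of this smooth family —
not clinical-grade accuracy on real anatomy.

## Problem sizes

The packaged end-to-end comparison trains on three phantoms (one more for
validation) at native 48×48×32 (2 mm) with fields predicted on a 24×24×16
working grid, 16 base channels, 200 iterations per network, and evaluates
on three held-out phantoms. These sizes were chosen so the full
comparison — three trainings, nine propagations, the complete metric
suite — completes in minutes on a single CPU; a paper-scale profile
(512×512×D native, (128,128,64) working grid) is expressible through the
same configuration objects but is not exercised by the tests.

## Evaluation choices

* H95 is the 95th percentile of the *pooled* symmetric surface-distance
  set (surface = mask minus erosion, exact Euclidean distance transform
  with anisotropic spacing); pooled is the common convention where the
  directed variant is not specified.
* Organs not fully inside the MR field of view are compared within Ω∩
  only; aggregates ("seen"/"unseen"/"all") are unweighted means over
  organs.
* Wilcoxon signed-rank drops zero differences and uses the exact null
  distribution for n ≤ 25 without ties (mid-ranks plus the normal
  approximation otherwise); endpoints are reduced to per-patient medians
  across phases/organs before testing, matching the patient-level paired
  design. BH-FDR is applied across the requested comparison set at
  q = 0.05, and significance stars are assigned from adjusted p-values
  (ns, *, **, ***, **** at 0.05 / 0.01 / 0.001 / 1e-4).

## Known limitations

* The autodiff engine is single-threaded numpy; paper-scale training is
  out of reach (by design — the architecture and objectives are the
  point, not throughput).
* Rigid search assumes the coarse alignment basin is reachable from the
  identity (±40 mm, ±0.35 rad bounds); grossly misaligned inputs need a
  better initializer.
* The temporal branch assumes the 50% phase is a valid motion-free
  reference; irregular-breathing artifacts are only emulated as slab
  duplications.
* `evaluate_result` needs reference labels per phase; on real data these
  would come from an auto-segmenter plus the QC filter, both outside the
  scope of the phantom experiments.
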