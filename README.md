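# mr4dctreg

Weakly supervised deformable registration for mapping MR-defined organ
contours onto every respiratory phase of a planning 4D-CT — the contour
propagation problem of MR-guided liver stereotactic body radiotherapy
(SBRT).

In that workflow the tumour and organs-at-risk are best delineated on a
breath-hold MR, but treatment planning happens on a 4D-CT whose phases
move with respiration. Mapping the MR contours onto *every* phase
therefore has to solve two problems at once: cross-modality appearance
difference (MR vs CT) and intra-4D-CT respiratory motion. This package
implements both a single-network solution and a two-step decomposition,
together with the deformation-QA machinery needed to trust the result.

## Method

All deformable maps are parametrized by a **stationary velocity field**
(SVF) `v` predicted by a 3D attention-gated encoder–decoder from the
channel-stacked (fixed, moving) volume pair. The displacement field is the
exponential of the velocity, computed by **scaling and squaring** over 7
steps (`Φ = exp(v)`), which yields near-diffeomorphic warps; a spatial
transformer resamples the moving image at `x + u(x)`.

Training minimizes the generic registration objective

```
Φ* = argmin  L_sim(F, M∘Φ) + λ L_reg(Φ) + γ L_Dice(S_F, S_M∘Φ)
```

with terms matched to the sub-task:

* **temporal** (CT-50 → CT-φ, mono-modal): LNCC similarity, a Jacobian
  determinant penalty `mean((|∇Φ| − 1)²)` that permits large but
  volume-preserving motion, λ = 0.3, γ = 0.7;
* **multi-modal** (MR → CT-50, after rigid pre-alignment): negative
  Parzen-window mutual information restricted to the MR/CT overlap region
  Ω∩, first-order smoothness `‖∇u‖²`, λ = γ = 0.5;
* **direct**: the multi-modal objective applied to (MR, CT-φ) pairs for
  all six phases.

The Dice term weakly supervises four abdominal organs (liver, spleen, both
kidneys) that are fully inside the MR field of view. At inference the
**pipeline** composes the two stage maps per phase,

```
Φ_MR→CT-φ = Φ_CT50→CT-φ ∘ Φ_MR→CT50,
```

with the rigid pre-alignment folded into the MR→CT-50 leg; fields are
predicted at a low working resolution and trilinearly upsampled to the
native grid before contours are warped (nearest-neighbour, so exported
label maps stay crisp).

Evaluation covers Dice, 95th-percentile Hausdorff distance (mm),
folding percentage and log-Jacobian spread (global and within organ
masks), and mutual information (whole image and within Ω∩); method
comparisons use paired Wilcoxon signed-rank tests on patient-level medians
with Benjamini–Hochberg FDR correction at q = 0.05.

Because clinical MR/4D-CT cohorts are not public, the package ships a
first-class **synthetic phantom generator**: seeded dual-modality 4D
studies with analytic diffeomorphic respiratory motion (zero at the 50%
end-expiration reference phase), permuted MR organ contrast, a known rigid
misalignment and a reduced MR field of view — so every experiment is a
parameter-recovery experiment with exact ground truth.

## Worked example

```bash
python examples/04_rigid_alignment.py
```

prints (seed 5 phantom):

```
true translation:      [ 6. -4.  8.] mm
recovered translation: [ 6.07 -4.03  7.94] mm (error 0.07 mm worst axis)
recovered rotation:    [0.0011 0.0028 0.0199] rad
overlap region: 67.4% of the CT grid (the rigidly transported MR field of view)
```

The MI-driven rigid search recovers the phantom's known misalignment —
(6, −4, 8) mm translation, 0.02 rad rotation about z — to well under a
tenth of a millimetre, and the transported MR support mask defines the
overlap region used by all multi-modal similarity.

The miniature end-to-end run

```bash
python examples/05_train_and_propagate.py
```

trains the temporal and multi-modal networks on two phantoms and
propagates the MR contours of a held-out phantom, printing the mean
supervised-organ Dice of the rigid baseline vs the two-step pipeline —
the gain is the motion the phase-independent rigid map cannot express.

A thin CLI wraps the same library calls:

```bash
mr4dctreg phantom  --seed 0 --out study0
mr4dctreg train    --studies studies/ --kind temporal --out ckpt/temporal.npz
mr4dctreg propagate --study study0 --method pipeline --checkpoints ckpt --out result0
mr4dctreg evaluate --study study0 --result result0 --out metrics.csv
```

## Layout

```
src/mr4dctreg/
  grids.py        grid-aware containers, NIfTI I/O, resampling, support masks
  fields.py       SVF integration, warping, composition, Jacobian QA
  autodiff.py     numpy reverse-mode autodiff (conv3d, grid_sample, ...)
  losses.py       LNCC, Parzen MI, soft Dice, field penalties
  network.py      attention U-Net SVF predictor, Adam, checkpoints
  rigid.py        MI-driven 6-DOF pre-registration, overlap mask
  phantom.py      synthetic 4D dual-modality study generator
  training.py     objectives, training loop, QC filter, patient splits
  propagation.py  rigid / direct / pipeline inference, study I/O
  evaluation.py   Dice, H95, field stats, MI records, Wilcoxon + BH-FDR
  benchmark.py    desk-scale end-to-end comparison
examples/         one narrative script per capability
docs/methods.md   modelling assumptions, parameters, limitations
```
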