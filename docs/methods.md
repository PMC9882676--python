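# Methods

This note documents the models, algorithms and numerical choices behind
`surview3d`, and what the synthetic-phantom experiments do and do not
demonstrate.

## Forward model: topogram synthesis

A topogram is simulated as a cone-beam projection from a fixed X-ray point
source onto a flat virtual detector behind the patient. For each detector
pixel, one ray is cast from the source through the pixel center (no
detector-area integration). Attenuation is monoenergetic: HU are converted to
relative attenuation μ/μ_water = 1 + HU/1000 (clipped at 0, since HU below
−1000 arise only from noise), and intensities follow Beer–Lambert,

    I = I0 · exp( − μ_water · Σᵢ μ_rel(i) · Δxᵢ ),

with μ_water = 0.0192 mm⁻¹ (≈ 70 keV effective energy, configurable). No
scatter, detector noise, polychromatic spectrum, bowtie filtration or
helical source motion is modeled.

**Geometry.** Source on the anterior–posterior axis (coronal view) or the
left–right axis (sagittal view) through the volume center; defaults 600 mm
source-to-isocenter and 1100 mm source-to-detector (typical CT numbers —
they are a package choice, configurable). The default detector pitch makes
the detector span 1.2× the magnified volume extent, magnification =
source-to-detector / source-to-isocenter. Detector row 0 is superior;
column 0 is the patient's left (coronal) or anterior (sagittal).

**Exact traversal.** The line integral Σ μ_rel·Δx is computed exactly for the
piecewise-constant voxel field by the plane-crossing (Siddon-type)
construction: the ray's crossing parameters with all x/y/z grid planes are
merged and sorted; each inter-crossing segment belongs to the voxel
containing its midpoint and contributes its geometric length. Degenerate
crossings (edges/corners, i.e. two borders within numerical coincidence)
yield zero-length segments, which are dropped; total path length equals the
in-volume chord to ~10⁻¹⁵ relative. An independent Riemann-sum oracle
(nearest-voxel sampling at a uniform step) is kept in the package purely as
a cross-check; its discretization error falls roughly linearly with step,
reaching ~10⁻⁴ relative at step = spacing/500 on noisy phantoms. At the
coarser step spacing/50 the oracle's own error (~10⁻³ on individual rays
crossing many tissue boundaries) dominates the comparison, so ensemble
agreement is judged on the mean over rays at that step and ray-by-ray at the
finer step.

**Network input.** The network consumes the line-integral image min-max
normalized to [0, 1] per image, not raw intensity: line integrals are the
information-bearing quantity and are scale-stable under i0 changes. Whether
a log transform is applied before a reconstruction network is a free design
choice; this one keeps the input linear in tissue thickness.

## Synthetic thoracic phantoms

Each phantom is fully determined by a seeded parameter set: an elliptical
soft-tissue body cross-section (+40 HU, semi-axes 80×105 mm), two lung
ellipsoids (−800 HU, semi-axes 85×45×30 mm at x = ±50 mm), a spine cylinder
(+700 HU, radius 12 mm near the posterior wall), an air trachea (−1000 HU,
radius 8 mm, midline, superior half), Gaussian noise (σ = 10 HU), on a
64³ grid at 4 mm spacing — chosen to span the tissue classes the evaluation
discusses (soft tissue, lung, bone, airway) at a size a CPU can train on.
Shapes are analytic quadrics rasterized by voxel-center inclusion, so exact
ground-truth body/lung masks exist for DICE and D_w oracles; masks are
computed before noise. Datasets jitter sizes multiplicatively (default ±10 %
on body/lung semi-axes, ±5 % on lung centers, ±10 % on spine radius), with
each sample's stream seeded by (dataset seed, sample index) so sample *i* is
identical regardless of dataset size.

What the phantoms do **not** emulate: ribs and other bony detail, mediastinal
organs, lesions, respiratory/cardiac motion, realistic HU texture, and the
anatomical variability of a clinical population. Passing phantom experiments
therefore demonstrates that the pipeline's machinery is correct and that the
architectures can learn 2D→3D mappings of this complexity class — not
clinical-grade reconstruction accuracy.

## Architectures

Both networks are encoder-decoders with an explicit dimensionality-raising
transformation between them.

* **Representation** (per view): six 2D conv blocks with batch normalization
  and ReLU. Full-scale flow 1024×1024×1 → 1024×1024×32 → 512×512×64 →
  256×256×128 → 128×128×256 → 64×64×512 → 32×32×1024. The first block
  preserves spatial size (3×3, stride 1); the rest halve it while doubling
  channels. Kernel 4×4 / stride 2 / pad 1 for the halving blocks is a
  standard encoder choice consistent with the stated shapes; kernel sizes
  are otherwise a free parameter of this design.
* **Transformation**: the latent tensor is memory-reshaped (row-major,
  channels-last) onto the generation entry grid — 4×4×4 at full scale, with
  the residual dimension as channels (16384) — and a single 1×1×1 convolution
  mixes channels down to 1024. The reshape conserves element count exactly
  (32·32·1024 = 4·4·4·16384); it invents and drops nothing. In the dual-view
  variant each view's latent is reshaped separately and the two are
  concatenated along channels (4×4×4×32768) before the convolution; this
  ordering makes "the half of the 1×1×1 kernel belonging to view 2" well
  defined, so zeroing it provably silences that view.
* **Generation**: 3D transposed-conv blocks (kernel 4³, stride 2, pad 1),
  each doubling every spatial side and halving channels:
  4×4×4×1024 → 8×8×8×512 → 16×16×16×256 → 32×32×32×128 → 64×64×64×64, and a
  final transposed-conv block to the 128×128×128×1 output. ReLU between
  blocks; a sigmoid on the output maps to [0, 1] to match window-normalized
  targets. No batch normalization in the decoder.

The two dual-view representation branches share architecture but not weights.
A uniform `channel_divisor` scales every channel count down; the desk-scale
default (divisor 8, 128² inputs, 32³ outputs, generation entry 2³) has
~1.1 M dual-view parameters versus ~100 M at full scale. The generation
entry side is an explicit configuration field validated for element-count
divisibility and power-of-two doubling to the output size, because no single
closed-form rule links latent side, entry side and output side at both
scales. Weights are Kaiming-uniform initialized from a seeded generator;
inference is deterministic and training is bit-reproducible on a fixed
device.

### The NumPy layer engine

The networks run on a purpose-built NumPy engine (`surview3d.nn`): conv and
transposed-conv layers expressed as im2col/col2im matrix products (so the
inner loops are BLAS GEMMs), batchnorm with running statistics, hand-derived
backward passes verified against central finite differences in the test
suite, and Adam. float32 throughout training; layers are dtype-agnostic so
gradient checks can run in float64.

## Training protocol

Adam at learning rate 2·10⁻⁴ minimizes voxel-wise MSE between predicted and
window-normalized ground-truth volumes. Weights checkpoint every 10 epochs;
training stops at `max_epochs` or when validation MSE has not improved for
`patience` epochs (default 20) — "convergence" is operationalized as this
patience rule since no sharper criterion is standard. The best-validation
weights (including batchnorm running statistics) are retained. A validation
fraction (default 10 %) is carved from the training portion; the held-out
test samples never influence weights. Batch size defaults to 4 at desk scale
(2 at full scale, where memory binds). No learning-rate schedule is applied
by default; an optional step decay is exposed in the config.

## Evaluation

* **Similarity**: MAE, MSE, PSNR = 10·log₁₀(R²/MSE) with data range R = 1
  (+∞ sentinel at MSE 0), and SSIM computed per axial slice (11-pixel
  Gaussian window, σ 1.5, K₁ = 0.01, K₂ = 0.03, range 1) and averaged. Metrics
  are computed on volumes normalized to the −1000…1000 HU window; HU-domain
  error maps are exposed separately.
* **Segmentation**: body mask = largest 26-connected component above
  −500 HU with per-slice hole filling; lungs = sub-(−320 HU) voxels inside
  the body, 26-connected components larger than 1 % of the body volume (so
  both lungs are kept whether or not they connect through the airways, while
  the isolated trachea falls below the size cut). Thresholds are common
  literature values and configurable; on noiseless phantoms the result is
  identical for any lung threshold between the −800 HU lungs and +40 HU body.
  DICE = 2|A∩B|/(|A|+|B|), with a TP/FP/FN label map for visualization; two
  empty masks define DICE 1.
* **Water-equivalent diameter**: per axial slice,
  A_w = A_pixel · Σ(CT#/1000 + 1) over the body mask and D_w = 2·√(A_w/π).
  The "+1" is the standard water-normalization convention (water pixels
  contribute 1, air 0); a formulation without it would assign water zero
  equivalent area. Negative slice sums (noise) clip to 0. Profile agreement
  reports the mean relative |ΔD_w| over nonzero slices, the Pearson
  correlation of the profiles, and 1 − mean relative error as a single
  score; which scalar best summarizes profile agreement is genuinely open,
  so all three are returned. Profiles can be exported as stacked-circle
  meshes whose enclosed volume approximates Σ A_w·Δz (within ~2 %, the
  stacking discretization).

## Study problem sizes

The packaged experiments are sized for a single CPU: the overfit experiment
trains the divisor-8 dual-view model on 8 phantoms for up to 300 epochs
(reaching train MSE < 10⁻³ and train-set lung DICE ≈ 0.94); the
architecture-comparison experiment trains both arms on 12-phantom datasets
(2 held-out test phantoms) for 60 epochs across 3 seeds, where the dual-view
model's median test MSE undercuts the single-view model's — the same
qualitative ordering the two architectures show at full scale. Full-scale
training (1024² inputs, 128³ outputs, ~10⁵ voxelwise-supervised exams) is
out of scope here; the full-scale graph is validated by shape audit and
parameter count only.

## Known limitations

* Monoenergetic projector: no beam hardening, so synthetic topograms are
  idealized relative to scanner scouts.
* The phantom family is geometric; generalization claims beyond it require
  real data.
* SSIM on 32³ volumes uses 11-pixel windows on 32×32 slices — meaningful,
  but coarser than at clinical resolution.
* The D_w agreement score is one of several defensible scalar summaries of
  profile agreement; all candidates are reported.
* DICOM support covers plain axial CT series (no gantry tilt, no
  multi-energy); DICOM writing is intentionally unsupported.
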