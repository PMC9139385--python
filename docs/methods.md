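# Methods

This note documents the models and procedures the package implements,
the parameters that matter, the choices made where the design was open,
and what the synthetic experiments do and do not show.

## Problem setting

The target mapping is from a pair of orthogonal 2D radiographs — an
anteroposterior (AP) and a lateral (Lat) view of the thoracolumbar spine
— to the 3D binary segmentation of the spine on a known voxel grid. The
package treats this as conditional image-to-volume generation: a
generator `G(z)` conditioned on the bi-planar pair `z`, adversarially
regularised by a discriminator `D` that also sees `z`, and anchored by a
voxelwise reconstruction term against the ground-truth mask `y`.

Axis convention throughout: `x` left→right, `y` posterior→anterior,
`z` inferior→superior; voxel indices are 0-based and corner-anchored
(physical position = index · spacing). Radiograph images store row 0 as
the superior edge; AP columns run left→right, Lat columns
posterior→anterior.

## Spine phantoms

Clinical CT studies are replaced by a procedural phantom whose purpose is
to expose every pipeline stage to data with the right *structure*, not
the right anatomy:

* torso = elliptic soft-tissue cylinder (40 HU) with two lung ellipsoids
  (−800 HU) in air (−1024 HU);
* vertebral bodies = elliptic cylinders with a trabecular core (400 HU)
  and a one-voxel cortical shell (1200 HU), separated by disc-tissue gaps
  (80 HU); a thin posterior cortical slab models the spinous process;
* per-phantom jitter: ±15 % on body radii, ±10 % on vertebral height, a
  mild sinusoidal lateral bow with random amplitude and phase;
* stationary additive Gaussian HU noise (default σ = 15 HU, clipped at
  ±6σ and at the −1024 HU floor).

Defaults: 9 vertebrae of 20 mm with 6 mm discs, body radius 14 mm,
process length 24 mm, on a 64×64×128 grid at 2 mm isotropic spacing
(desk scale; the full-scale grid is 128×128×256 at 1 mm). The HU levels
were chosen so that bone falls inside the enhancement window below and
soft tissue just outside the amplification range. The ground-truth mask
is exactly the set of bone-class voxels, so vertebra counts, disc gaps
and process geometry are recoverable by construction — properties the
test suite exploits as oracles.

What the phantom does *not* emulate: real vertebral shape variation,
ribs, pathology, scanner noise texture, beam hardening, or partial-volume
effects. Passing tests therefore demonstrate that the pipeline's
machinery is correct and that its comparative findings hold on a
controlled distribution — not that the learned model transfers to
patients.

## Bone-signal enhancement

Raw HU volumes are converted to "imaging signal" by a fixed empirical
recipe, applied per voxel:

1. clamp below −1024 HU; set values above 1000 HU to 0 HU (a literal,
   deliberately kept quirk of the recipe — the densest bone is knocked
   to water level rather than clipped);
2. body mask = 1 where HU > −400 (strictly);
3. signal = (HU − RescaleIntercept)/RescaleSlope, the inverse DICOM
   rescale transform (for the common intercept −1024, slope 1 this maps
   HU to stored detector values);
4. window: zero outside the open interval (874, 2024); triple the signal
   strictly above 1300.

One composition choice required judgement: multiplying the mask into the
*HU* values (as a literal reading of the numbered steps suggests) sends
every masked-out voxel to 0 HU, which the rescale inversion then maps to
1024 — *inside* the window — so air and lung would emerge at water-level
signal and the radiograph background would glow. The package instead
multiplies the mask into the windowed signal, so out-of-body voxels are
exactly zero. All scalar rules above are otherwise verbatim, boundary
strictness included (≤ 874 and ≥ 2024 are zeroed; exactly 1300 is not
amplified). The "original" control condition is defined as the bare
rescale inversion of clamped HU with no masking or windowing.

## Radiograph simulation

The default projector is parallel-beam: pixel (u, w) integrates the
signal along the projection axis (AP along y, Lat along x), scaled by
the voxel spacing. Intensity follows a Beer–Lambert-style transfer
`I = 1 − exp(−k · ∫ signal ds)`. The attenuation scale `k` is chosen
per image so the median positive ray maps to intensity 0.7, which keeps
enhanced and original conditions at comparable global contrast — the
conditions then differ in *structure* (what tissue contributes), not in
overall brightness. Parallel geometry was preferred as the default
because the source/detector distances of a cone-beam setup are free
parameters with no principled value here, and because parallel beams
obey exact conservation and linearity laws the tests verify to 1e−9. A
basic cone-beam mode (point source, ray-driven trilinear sampling) is
provided for geometry experiments.

Radiographs are cropped to the ground-truth spine bounding box dilated by
8 voxels — both signal conditions share the same framing — and resampled
bilinearly to the detector shape (128 × 256 at full scale, scaled
proportionally otherwise).

## Network

**Generator.** Each view is encoded by its own eight-block 2D CNN
(channels 64,64,64,64,32,16,8,4; first kernel 7×7, then 4×4; stride-1
convolutions with BN → ReLU and an in-block residual addition where
channel counts match; 2×2 max pooling after the first `log2(H/8)` blocks
so the bottleneck is always 8×4 spatial with 4 channels). At the
bottleneck the 4-channel 2D map is reinterpreted as a one-channel 3D
volume: the channel axis becomes the spatial axis the projection lost
(y for AP, x for Lat); after permutation to a common (x, y, z) order the
two volumes are averaged into a 4×4×8 seed.

The decoder has two parts. Per-view 2D decoders (nearest-neighbour ×2
upsample + 3×3 conv + BN + ReLU; channels 32,16,8,4 at full scale) start
from the concatenated outputs of encoder blocks 5–8 (the skip
connections) and stay cheap because they are 2D. The central 3D decoder
grows the seed by ×2 upsampling stages; at each stage the view-decoder
features are tiled along their projection axes, permuted, averaged
across views, and concatenated in. 3D convolutions (3³, BN, ReLU) are
applied only at stages up to 16×16×32 voxels; finer stages are pure
upsample-and-fuse, and a final 1×1×1 convolution followed by a sigmoid
mixes the accumulated multi-resolution channels into the probability
volume. Concentrating 3D convolution at coarse scales keeps the CPU
memory traffic of volumetric im2col buffers bounded while the per-view
2D decoders carry full-resolution detail in the (x,z) and (y,z) planes;
the final 1×1×1 mixing then acts much like an algebraic fusion of the
two silhouettes. The output bias is initialised to the foreground-prior
logit (p ≈ 0.05) so an untrained generator predicts a near-empty volume.

**Discriminator.** A 3D Patch-GAN: the candidate volume (probability map
during training, so the pipeline stays differentiable; binary mask only
at inference) is concatenated with a two-channel conditional volume (AP
and Lat radiographs tiled along their projection axes), then passed
through four stride-2 4³ convolutions (channels 32,64,128,256, LeakyReLU
0.2, batch norm after the first block) and a final stride-1 1-channel
convolution. A 32×32×64 input yields a 2×2×4 grid of unbounded patch
scores.

**Losses.** Least-squares adversarial objectives
(`½E[(D(x)−1)²] + ½E[D(G(z))²]` for D, `½E[(D(G(z))−1)²]` for G),
plus voxel MSE to the mask, combined as `λ₁·LSGAN + λ₂·MSE` with
λ₁ = 2, λ₂ = 100. With these weights the reconstruction term dominates
early training, which is what makes the short desk-scale runs converge.

**Optimisation.** Adam, learning rate 2×10⁻⁴, β = (0.5, 0.999) — the
standard conditional-GAN recipe — batch size 4 at desk scale, alternating
one discriminator and one generator update per batch. Training is fully
deterministic given the seed: a single `numpy` generator drives
initialisation and shuffling, and every layer is pure numpy. Probability
maps are binarised at threshold 0.4 (ties resolved upward: p ≥ 0.4 → 1).
The nominal full-scale schedule is 50 epochs; the desk-scale experiments
below use 15.

**Tensor stack.** The network runs on a small reverse-mode autodiff
implemented in `nn.py`: convolutions are offset-major im2col gathers
followed by per-offset GEMMs, input gradients are computed as the exact
adjoint scatter (no dilated full convolutions), and stride-2 even-kernel
convolutions take a space-to-depth fast path (stride-1 half-kernel
convolution on phase-split channels). Every layer is verified against
central-difference numerical gradients in the test suite.

## Evaluation

Five per-case metrics: DSC = 2|A∩B|/(|A|+|B|), JSC = |A∩B|/|A∪B|,
OV = |A∩B|/min(|A|,|B|), and SSIM between the AP and between the Lat
sum-projections of prediction and ground truth (binary masks are
projected and min-max normalised; the radiograph intensity model is
deliberately not reused here, since the objects compared are the 3D
structures). SSIM uses the standard product form with α=β=γ=1,
C1=(0.01L)², C2=(0.03L)², C3=C2/2, L=1, and an 11×11 Gaussian window
(σ=1.5) with the half-window border excluded; a uniform-window flag
exists. Degenerate conventions: DSC/JSC of two empty volumes is defined
as 1 (with a warning); OV of an empty volume is an error; in pipeline
summaries an empty prediction scores 0 on all metrics.

Cross-validation shuffles case ids by seed into k near-equal folds; split
f tests on fold f and validates on fold (f+1) mod k. For k = 2 that
rolling rule would leave no training data, so the validation set is
carved from the non-test fold (≈ one ninth, at least one case) instead;
the 8:1:1 train/validation/test principle is preserved in spirit at
every k. Condition comparisons use the two-sided Mann–Whitney U test
(exact enumeration when n₁+n₂ ≤ 12 without ties, tie-corrected normal
approximation otherwise, via scipy); size comparisons use tie-corrected
Kruskal–Wallis with a chi-square reference. α = 0.05 per test, no
multiple-testing correction. All-identical samples short-circuit to
H = 0, p = 1.

## Desk-scale experiment and what it shows

The quantitative suite trains at quarter scale (32×32×64 volumes,
32×64 radiographs): 40 phantoms, 2-fold cross-validation, 15 epochs,
both signal conditions, three seeds — sizes chosen so a single CPU core
completes the whole grid in well under half an hour. Two directional
findings are asserted: (1) held-out mean DSC under the enhanced
condition is at least 0.5 and at least twice the untrained-generator
baseline; (2) mean DSC under enhanced signals is at least that under
original signals, averaged over seeds. Observed values in this
configuration are ≈ 0.72 (enhanced) vs ≈ 0.69 (original) with baselines
below 0.07. These replicate the *direction* of the full-scale clinical
result; the absolute gap between conditions is much smaller here because
the phantom's background anatomy is far simpler than a chest CT, so the
original-signal condition is less handicapped than with real data.

## Numerical choices and degenerate inputs

* All training arithmetic is float32; Adam moments and metric/projection
  accumulations are float64.
* Conservation and linearity of the projector hold to 1e−9 relative;
  enhancement is exactly elementwise (vectorised path equals a scalar
  reference loop on random HU values).
* Convolution geometry must be stride-aligned ((S+pad−K) divisible by
  the stride); violations raise rather than silently crop.
* Non-finite losses abort training with the epoch/batch in the message.
* Empty crop ROIs, empty masks for OV, zero rescale slope, and unknown
  views are explicit errors.

## Known limitations

* The phantom's simplicity understates the clinical advantage of bone
  enhancement and cannot probe generalisation across scanners/patients.
* The parallel-beam projector ignores scatter, beam hardening and
  magnification; the cone-beam mode is geometric only.
* The GAN is small and CPU-bound; full-scale (128×128×256, 50-epoch,
  thousand-study) training is configurable but not practical here.
* The discriminator's adversarial signal contributes little at desk
  scale — with λ₂ = 100 the MSE term dominates, and the short schedule
  ends before adversarial refinement matters.
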