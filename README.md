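# biplanar3d

Automatic reconstruction of a 3D binary spine volume from two orthogonal,
simulated plain-film views (anteroposterior and lateral), built for
researchers prototyping 2D→3D skeletal reconstruction methods without
access to a clinical CT archive or a GPU.

A plain radiograph collapses the spine onto a single plane, yet many
orthopaedic questions (vertebral alignment, canal geometry) are
three-dimensional. CT answers them at the cost of a much higher radiation
dose. This package implements a prototype of the middle road: a
conditional generative adversarial network that maps a bi-planar pair of
digitally reconstructed radiographs (DRRs) to the 3D spine segmentation
they came from.

## What is inside

The pipeline runs end to end on synthetic data:

1. **`phantom`** — procedural spine phantoms: a soft-tissue torso with
   lungs and a column of vertebra-like bodies (trabecular core, cortical
   shell, disc gaps, posterior spinous processes) on an HU-calibrated
   grid, with a paired binary ground-truth mask. Per-phantom size and
   curvature jitter gives the training distribution its variability.
2. **`enhance`** — an empirical bone-signal enhancement recipe applied
   voxelwise to the CT before projection: threshold filters, a body mask,
   inversion of the DICOM rescale transform, a signal window (874, 2024)
   and ×3 amplification of strong bone signal. The un-enhanced
   ("original") condition is the bare rescale inversion.
3. **`drr`** — a parallel-beam projector producing AP and lateral
   radiographs, `I = 1 − exp(−k·∫signal ds)`, cropped to the spine ROI
   (128 × 256 pixels at full scale; an optional cone-beam mode exists).
4. **`gan`** — the conditional GAN: dual-view 2D ResNet-style encoders
   (channels 64,64,64,64,32,16,8,4), a fused 3D decoder whose bottleneck
   reinterprets the 2D channel axis as the projection axis each view
   lost, and a 3D Patch-GAN discriminator (channels 32,64,128,256,
   4³ kernels). Training minimises

   `G* = λ₁ · argmin L_LSGAN(G, D) + λ₂ · L_re`,  λ₁ = 2, λ₂ = 100,

   where `L_LSGAN` is the least-squares adversarial objective and
   `L_re` the voxelwise MSE to the ground-truth mask. Probability maps
   are binarized at 0.4. Runs on a small numpy tensor stack with
   hand-derived backpropagation — no deep-learning runtime needed.
5. **`metrics`** — DSC, JSC, overlap volume (OV) on volumes;
   SSIM (11 × 11 Gaussian window) on AP/Lat projections.
6. **`evaluation`** — k-fold cross-validation over the condition × size
   experiment grid, with Mann–Whitney U (conditions) and Kruskal–Wallis
   (dataset sizes) comparisons at α = 0.05.

## Worked example

```python
from biplanar3d import (PhantomSpec, generate_dataset, GeneratorConfig,
                        TrainConfig, DiscriminatorConfig, LossWeights,
                        ExperimentGrid, run_grid)

spec = PhantomSpec(grid_shape=(32, 32, 64), spacing_mm=(4.0, 4.0, 4.0))
phantoms = generate_dataset(40, spec, seed=7)
grid = ExperimentGrid(signal_conditions=("original", "enhanced"),
                      dataset_sizes=(40,), k=2, seed=7)
results = run_grid(grid, phantoms, GeneratorConfig(scale=0.25),
                   DiscriminatorConfig(), LossWeights(),
                   TrainConfig(epochs=15, batch_size=4))
print(results.groupby("condition")[["dsc", "baseline_dsc"]].mean())
```

which prints (about six minutes on one CPU core):

```
                dsc  baseline_dsc
condition
enhanced   0.718708      0.063430
original   0.685051      0.000000
```

Read: after 15 epochs of 2-fold cross-validation on 40 phantoms at
quarter scale, the held-out Dice overlap reaches ≈ 0.72 under the
enhanced bone-signal condition — an order of magnitude above the
untrained-generator baseline (`baseline_dsc`) — and the enhanced
condition outperforms the original signals, the same direction the
full-scale clinical experiment reports. Absolute values at this desk
scale are not comparable to a full-resolution, thousand-study run.

The same pipeline is scriptable from the shell:

```sh
biplanar3d phantom --n 40 --seed 7 --out data/ --scale 0.25
biplanar3d train --data data/ --condition enhanced --scale 0.25 \
                 --epochs 15 --seed 7 --out run/
biplanar3d predict --model run/gen.ckpt.npz \
                   --ap case_ap.npy --lat case_lat.npy --out pred.nii.gz
biplanar3d evaluate --pred preds/ --gt data/ --out metrics.csv
```

## Layout

```
src/biplanar3d/    phantom, enhance, drr, nn, gan, metrics, evaluation,
                   io, cli  (one module per pipeline stage)
tests/             pytest suite, including the end-to-end checks
docs/methods.md    model, assumptions, parameter choices, limitations
```
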