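# mscc — multiscale CNN-CRF segmentation of environmental microorganisms

Environmental microorganisms (EMs) — the protozoa, algae and other
microscopic organisms that decompose pollutants and indicate water quality —
are identified under the microscope by their shape, which makes automatic
foreground segmentation the first step of any EM analysis pipeline.  EM
datasets are small (tens of annotated images per class) and object sizes
vary enormously between classes, so this package segments grayscale EM
micrographs with two cooperating branches at different spatial scales and
fuses them:

1. **Pixel level** — an encoder-decoder network predicts a per-pixel
   foreground probability map.  Four block variants are provided: the plain
   U-Net block and three multi-receptive-field blocks (B1: parallel
   1×1/3×3/5×5/7×7 filters; B2: a shared stack of three 3×3 stages with
   intermediate-output concatenation; B3: additionally factorising each 3×3
   into 3×1 + 1×3).  B3 keeps the widened receptive field at less than a
   fifth of the baseline's parameters (5.8M vs 31.0M).  The binarised
   output then initialises a fully connected CRF with energy

   ```
   E(x) = Σᵢ U(xᵢ) + Σ_{i<j} [xᵢ ≠ xⱼ] · k(fᵢ, fⱼ)
   k(fᵢ,fⱼ) = w₁·exp(−‖pᵢ−pⱼ‖²/2σ_α² − (Iᵢ−Iⱼ)²/2σ_β²) + w₂·exp(−‖pᵢ−pⱼ‖²/2σ_γ²)
   ```

   solved by parallel mean-field inference (exact dense message passing on
   small grids, truncated-window passing on images).

2. **Patch level** — the image's non-overlapping 8×8 tiles are classified
   *WithObject* / *WithoutObject* (strict half-area criterion) by a small
   CNN or a frozen-base VGG-16 head, and the labels are reassembled into a
   coarse mask that recovers detail the pixel branch under-segments.

The two results meet through a **buffer**: the patch mask is kept only
within a disk-dilation of the pixel mask (radius swept over 2–40 px and
selected at the Accuracy/Recall intersection of the fused result), and the
final mask is the union of the two branches.  Evaluation reports Dice,
Jaccard, Recall, Accuracy and VOE (= 1 − Jaccard).

Because real EM datasets are distributed on request only, the package
includes a first-class synthetic generator: per-class scenes of ellipses,
random-walk filaments or star-blobs with exact analytic ground truth and
overlapping foreground/background intensity distributions, emulating the
layout and patch-label prevalence of the reference data.  The neural
networks run on a compact NumPy autodiff engine included in the package
(`mscc.nn`), gradient-checked against finite differences.

## Worked example

The reduced test profile (64-pixel synthetic scenes, 3 classes × 16 scenes
split 1:1:2, the B3 variant at half width, 10/5 training epochs) runs the
whole workflow on one CPU core in about two minutes:

```
$ mscc run-all --seed 1 --out runs/demo
buffer size: 2
overall: dice 90.87%, jaccard 83.52%, recall 98.17%, accuracy 96.84%, voe 16.48%
```

Reading the numbers: the fused mask overlaps ground truth at Dice 90.87%
(Jaccard 83.52%, i.e. VOE 16.48% of the union is mislabeled); Recall 98.17%
says almost all true foreground is recovered — the union fusion can only
add foreground, so Recall is its strong suit — while Accuracy 96.84% counts
all pixels.  The selected buffer size is the Dice-maximising fallback
(2 px) because at this working point the pixel branch is strong enough that
the Accuracy and Recall sweep curves never cross.  `runs/demo/` holds the
raw, CRF-refined, patch, and final masks, colour overlays (red = pixel
only, green = patch only, yellow = both, purple = ground-truth contour),
the 20-row buffer-sweep table and per-image/per-class metric CSVs.

Each stage is also a subcommand (`synth`, `prepare`, `train-pixel`,
`refine-crf`, `train-patch`, `segment-patch`, `sweep-buffer`, `fuse`,
`evaluate`) exchanging artefacts through a run directory, and everything is
callable as a library:

```python
from mscc import RunConfig, run_pipeline
result = run_pipeline(RunConfig.test_profile().with_seed(1))
print(result.report.overall.dice)      # 0.9087
```

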