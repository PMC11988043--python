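# rgbdweight

Non-contact body-weight estimation for small livestock from paired
top-view **RGB and depth images**, using a two-stream bidirectional
cross-modal fusion network — plus a synthetic RGB-D scene generator so the
whole train/evaluate/ablate pipeline runs end to end with no external data
and no GPU.

**Who it is for.** Researchers in precision livestock farming and
biological image analysis who want a fully reproducible, CPU-runnable
reference implementation of multi-scale RGB-D fusion for weight
regression: the fusion blocks, the baselines (single-modality, early/late
fusion), the ablation harness, and Grad-CAM inspection.

## The model

Each sample is a colour image and an aligned depth map (mm) of one animal
seen from above, labelled with a weight y (kg). Two six-stage
convolutional branches encode the modalities; in stages 1–4 a
cross-modality feature supplementation (CFS) block exchanges information
bidirectionally:

```
f̄a = Conv₁ₓ₁(fa),  f̄b = Conv₁ₓ₁(fb),  f̄F = f̄a ⊙ f̄b
fF  = DSConv₃ₓ₃([ f̄F + f̄a , f̄F + f̄b ])          (feature fusion, FF)
bfR = fR + σ(BAM(fR)) ⊙ fF
bfD = fD + σ(BAM(fD)) ⊙ fF                        (supplementation)
```

Stages 5–6 are weight-shared between branches. A decoder of three
cross-modality feature fusion (CFF) levels aggregates the two feature
pyramids coarse-to-fine (FF within each branch across adjacent scales,
then FF across branches, refined by a receptive-field block with channel
split/shuffle), and a pooled two-layer head outputs ŷ. Evaluation uses
MAE = (1/n)Σ|ŷᵢ−yᵢ|, RMSE = √((1/n)Σ(ŷᵢ−yᵢ)²) and
R² = 1 − Σ(ŷᵢ−yᵢ)²/Σ(ȳ−yᵢ)².

The synthetic generator renders half-ellipsoid bodies whose weight is
exactly density × volume, with density encoded only in the colour hue and
volume recoverable only from depth — so neither modality alone can solve
the task, and the benefit of fusion is testable by construction. See
`docs/methods.md` for the full model and generator description.

Everything runs on a compact numpy autodiff engine included in the package
(`rgbdweight.nn`); no deep-learning framework is required.

## Worked example

```python
import numpy as np
from rgbdweight.config import ModelConfig, TrainConfig
from rgbdweight.datagen import generate_dataset, split_manifest
from rgbdweight.pipeline import train, evaluate

manifest = generate_dataset(512, seed=31, out_dir="scenes", resolution=96)
manifest = split_manifest(manifest, 416, 96, seed=2)

result = train(manifest,
               ModelConfig.tiny(),                       # width-reduced preset
               TrainConfig(epochs=18, input_size=48, seed=0, augment="flips"))
report, per_sample = evaluate(result, manifest, split="test")
print(report)
```

This trains the width-reduced two-stream model on 416 synthetic pairs for
18 epochs (a few minutes on one CPU core) and prints, for the 96 held-out
pairs:

```
n=96  MAE=0.1492 kg  RMSE=0.1920 kg  R2=0.9828
```

i.e. the model recovers weight to ≈0.15 kg mean absolute error over the
0.5–5.5 kg range, explaining ≈98% of the held-out variance — which is only
possible by combining the density cue (colour) with the volume cue
(depth); the same budget gives ≈0.55 kg for a colour-only and ≈1.2 kg for
a depth-only baseline (`examples/03_ablation.py`). Exact numbers vary a
few hundredths of a kg with the seed.

The `examples/` directory holds one short script per capability:
generation, training/evaluation, the ablation harness, and Grad-CAM. The
same workflow is available from the shell:

```bash
rgbdweight generate --n 512 --seed 31 --out scenes --resolution 96
rgbdweight split --manifest scenes/manifest.csv --n-train 416 --n-test 96 --seed 2
rgbdweight train --manifest scenes/manifest.csv --out run/
rgbdweight eval --checkpoint run/checkpoint.npz --manifest scenes/manifest.csv
rgbdweight ablate --manifest scenes/manifest.csv --axis modality --values rgb,depth,rgbd --out abl/
rgbdweight gradcam --checkpoint run/checkpoint.npz --manifest scenes/manifest.csv --sample-id s00001 --out cam.png
```

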