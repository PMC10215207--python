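# znet3d

Densely connected 3D encoder–decoder segmentation of multimodal brain MRI,
with a fully synthetic phantom pipeline so every stage runs offline on a CPU.

The package covers the whole workflow:

* **`brats_io`** — read/write BraTS-layout cases (per case: `_flair`, `_t1`,
  `_t1ce`, `_t2`, optional `_seg` NIfTI volumes) without reorienting voxels.
* **`preprocessing`** — per-modality min-max normalization, trilinear /
  nearest-neighbour resizing to the network resolution (default 128³),
  derivation of the nested binary masks WT (labels 1,2,4), TC (1,4), ET (4)
  from the 4-valued ground truth, and stacking into `(4,D,H,W)` /
  `(3,D,H,W)` tensors.
* **`augmentation`** — deterministic in-plane rotation expansion; the default
  plan (original + rotations by −5°, 5°, 10°, 15°) grows 369 cases into 1845
  training pairs.
* **`znet_model`** — the network: input block, four (configurable) encoder
  stages (double conv3d k3/s1/p1 + batch-norm + ReLU, then 2× max-pool),
  mirrored decoder stages (trilinear 2× upsampling, concatenation with all
  same-resolution encoder/input feature maps, double conv block), and a
  1×1×1 conv + sigmoid output block. Implemented on a small NumPy layer
  library (`nn.py`) with exact hand-derived backward passes — no deep
  learning framework required.
* **`train_eval`** — ADAM + binary cross-entropy training (batch size 1),
  thresholded prediction, dice evaluation (`2|MS∩GT|/(|MS|+|GT|)`, empty
  vs. empty scores 1.0), and overlay PNG export.
* **`phantom_generator`** — synthetic BraTS-layout cases: a brain ellipsoid
  with a nested spherical lesion (edema 2 / non-enhancing core 1 / enhancing
  core 4) rendered with modality-specific contrasts plus Gaussian noise.
* **`cli`** — a `znet3d` command wiring all stages together.

## CLI walkthrough

```sh
znet3d synth --n 20 --shape 32 32 32 --seed 0 --out work/cases
znet3d preprocess --cases work/cases --target-shape 32 32 32 --out work/stacks
znet3d augment --stacks work/stacks --out work/aug          # 5x expansion
znet3d train --stacks work/aug --epochs 10 --learning-rate 1e-3 \
             --depth 3 --base-width 8 --seed 0 --out work/run
znet3d evaluate --checkpoint work/run/checkpoint.npz \
                --stacks work/stacks --out work/eval
znet3d predict --checkpoint work/run/checkpoint.npz \
               --case work/cases/phantom_00000 --out work/pred
znet3d overlay --checkpoint work/run/checkpoint.npz \
               --stack work/stacks/phantom_00000.npz --out work/overlay.png
```

Every artifact-producing command writes its resolved configuration as YAML
next to its outputs; identical inputs + seed reproduce identical artifacts.

## Notes

* Training at full BraTS scale (128³ inputs, 50 epochs) is supported by the
  same code paths but is far outside desk-scale CPU budgets; the test
  surface uses 16³–64³ volumes.
* Checkpoints are single `.npz` files containing weights, batch-norm
  statistics and the architecture config.
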