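# owsr — arbitrary-scale super-resolution with overlapping-window decoding

`owsr` reconstructs a high-resolution image from a low-resolution input at
**any real-valued scale factor with a single trained model**. It targets the
kind of imagery found in OCT-angiography (OCT-A), where capillary-scale
detail — bright branching vessels 1–4 px wide over a dark, speckled
background — is exactly what clinicians need preserved and what fixed-factor
super-resolution pipelines lose between their discrete scales.

## The model

An LR image `I ∈ [0,1]^{H×W×3}` is encoded once into a latent feature grid

```
ψ = E(I) ∈ R^{H×W×D}
```

by a residual CNN (EDSR-style baseline: 3×3 head conv, 16 residual blocks
without batch normalization, tail conv, global skip; D = 64 by default).
Both the image and ψ live on the unit square with cell-centered pixels, so
an HR pixel center `x = ((r+0.5)/X, (c+0.5)/Y)` is directly a continuous
query coordinate in ψ.

To predict RGB at `x`, the decoder:

1. **gathers a semi-local region** `S ∈ R^{M×M×D}`: an M×M grid of points
   spaced one ψ-cell apart and centered on `x`, each mapped to the nearest
   ψ cell by Euclidean distance (M = 6 by default);
2. **reduces S with overlapping windows**: at window size `m = M−1, …, M/2`,
   the four `m×m` corner crops of the current block are multiplied
   elementwise by learnable per-corner weight tensors `w_i` and summed
   (`Γ = Σ_i s_i ∗ w_i`), shrinking the block one cell per iteration down to
   `(M/2)×(M/2)×D`;
3. **decodes with an MLP**: the 2×2 window centered on the query (chosen by
   the sign of the query's sub-cell offset `(δu, δv)`), flattened and
   concatenated with `(δu, δv)`, is mapped to RGB by a small ReLU MLP.

Training samples random crops, degrades them by bicubic downscaling at a
random continuous factor, and minimizes the L1 loss at 1500 random HR pixel
centers per image (Adam, lr 1e-4 decayed ×0.3 after epochs 40/60/70, batch
16, 100 epochs). Because the decoder is a function of continuous
coordinates, the same weights serve ×1.4 as well as ×4.5.

No external dataset is required: `owsr.phantom` synthesizes OCT-A-like
vessel phantoms (branching curvilinear trees, low-frequency perfusion
texture, multiplicative gamma speckle) plus analytic constant/gradient/
sinusoid fixtures, so training, evaluation and the full test suite run
self-contained on a CPU. The package carries its own small numpy
reverse-mode autodiff core (`owsr.autodiff`) sized to this model.

## Worked example

Train the reduced single-image preset (4 residual blocks, D = 16, M = 4,
4000 steps, ~3 min on one CPU) on a synthetic phantom and compare ×2
reconstruction against bicubic upscaling:

```python
from owsr import (PhantomSpec, gen_vessel_phantom, tiny_overfit_config,
                  train, evaluate)

image = gen_vessel_phantom(PhantomSpec(seed=3))     # 96x96 vessel phantom
model, log = train(tiny_overfit_config(seed=0), [image])
rec = evaluate(model, [image], scales=[2.0])[0]
print(f"model {rec.psnr_model:.2f} dB vs bicubic {rec.psnr_bicubic:.2f} dB")
```

prints

```
model 19.47 dB vs bicubic 18.55 dB
```

i.e. the learned decoder reconstructs the ×2-downscaled phantom about
+0.9 dB PSNR above the bicubic baseline. The L1 loss trace for the same run
falls 4.65 → 0.40 → 0.11 → 0.06 at steps 1 / 10 / 100 / 4000. One
checkpoint then serves any factor:

```python
from owsr import upscale
out = upscale(image, model, scale=2.4)   # 96x96 -> 230x230, values in [0,1]
```

The `examples/` directory holds four narrative scripts (phantom generation,
tiny training, arbitrary-scale upscaling, evaluation vs bicubic); each
prints the numbers above with a note on what they mean. The same
functionality is exposed as a thin CLI:

```bash
owsr synth --n 4 --size 96x96 --seed 0 --out data/
owsr train --config cfg.yaml --data data/ --out run/
owsr upscale --ckpt run/model.npz --in data/phantom_000.png --out up.png --scale 2.4
owsr eval  --ckpt run/model.npz --data data/ --scales 2,3,4 --out eval.csv
```

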