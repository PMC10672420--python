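# Methods

## Model

The method is an implicit-representation super-resolver: instead of mapping
an LR image to a fixed-size HR raster, it learns a function from continuous
image coordinates to RGB, conditioned on a latent feature grid. Three
stages:

**Encoder.** An EDSR-baseline residual CNN without batch normalization:
3×3 head convolution to depth D, `n_resblocks` blocks of
conv–ReLU–conv with identity skip (residual scaled by `res_scale`), a 3×3
tail convolution, and a global skip from the head output. Spatial size is
preserved (padding 1); there is no upsampling head — the feature grid ψ
stays at LR resolution and all magnification happens in the decoder.
Defaults: 16 blocks, D = 64, `res_scale` = 1.0 (the usual baseline-size
convention). Inputs are shifted by 0.5 per channel so [0,1] images are
roughly centered; fixed 0.5 was chosen over dataset statistics for
simplicity and reproducibility.

**Coordinate system and semi-local sampling.** Image and grid share the
unit square with cell-centered pixels: cell (p,q) of a P×Q grid sits at
((p+0.5)/P, (q+0.5)/Q), 0-based, row-major. An HR pixel (r,c) of an X×Y
target maps to ((r+0.5)/X, (c+0.5)/Y), which is directly the query point in
ψ — with shared normalized coordinates the spatial correspondence is the
identity, the simplest realization that is testable in closed form. Around
the query, an M×M grid of sample points spaced exactly one cell apart
(half-integer offsets {−(M−1)/2…+(M−1)/2}·cell) is generated; this offset
rule keeps the grid point-symmetric about the query and yields exactly M×M
samples. Each sample is mapped to the nearest grid cell by Euclidean
distance. Numerical conventions, all verified against an exhaustive
distance scan:

* sample coordinates are clamped to [0,1]² before lookup, so border queries
  replicate edge cells rather than shrinking the region;
* exact ties between two cell centers go to the smaller index. The lookup
  is `p = clamp(ceil(u·P)−1, 0, P−1)` — identical to `floor(u·P)` except on
  exact cell boundaries, where the floor form would contradict the tie rule.
  A consequence is that the query's offset from its nearest cell center,
  in cell units, lies in (−0.5, 0.5] for every interior coordinate (only
  the degenerate clamped coordinate 0 itself maps to −0.5);
* M must be even and ≥ 4; the default M = 6 gives a 6×6 region. M is a
  config parameter.

**Overlapping-window reduction and decoder.** Starting from the M×M×D
region, each iteration takes the four (m−1)×(m−1) corner crops of the
current block, multiplies each elementwise by a learnable per-corner,
per-position, per-depth weight tensor, and sums the four products; the
block shrinks by one cell per iteration through sizes M−1 … M/2 (M/2
iterations; for M = 6: 5, 4, 3). Design choices where the operator algebra
was genuinely open:

* the corner combination is elementwise multiply-and-sum (not a
  convolution and not a scalar gate) — the reading consistent with
  per-corner weights that "combine" four same-shaped crops into one block
  of the next size; this is the package's single largest interpretive
  commitment and is pinned by an independent loop-oracle test;
* weights are distinct per corner and per iteration — corners see
  different spatial content, and sharing would impose a symmetry nothing
  requires;
* initialization is the constant 1/4, which makes the initial cascade an
  exact local average: constant regions pass through unchanged
  (value-preservation is a test), and feature scale is preserved at the
  start of training.

The final 2×2 window is not a corner: it is centered on the query. With
c = floor((m−1)/2), the window's top-left index along each axis is
c − 1 + [offset > 0], clamped to [0, m−2]; for m = 2 the selection is the
identity. The window is flattened and concatenated with the query's
sub-cell offset (δu, δv) — without this augmentation the prediction would
be piecewise constant within a cell — and decoded by a ReLU MLP (default
4×256 hidden, linear 3-unit head). Outputs are raw during training (L1
against [0,1] targets) and clamped to [0,1] only at inference.

## Training

Each step draws, per image: a scale s ~ Uniform(`scale_range`), a random
round(48·s)² crop, its bicubic ×(1/s) downscale to the 48×48 LR patch, and
1500 distinct HR pixel centers of the crop as supervision points (pixel
centers rather than off-grid positions, so targets are exact pixel values
with no resampling noise). The loss is mean |prediction − target|; Adam
(β = 0.9/0.999, ε = 1e−8) with lr 1e−4 multiplied by 0.3 after epochs
40, 60, 70, batch 16, 100 epochs. `scale_range` defaults to [1, 4],
continuous, matching the ×2–×4 regime the method is evaluated in while
exercising truly arbitrary factors. An epoch is one shuffled pass over the
image list; all randomness flows from a single seeded generator, making
runs bit-reproducible.

Two reduced presets are first-class for CPU-scale work: `tiny_config`
(4 residual blocks, D = 16, M = 4, MLP 2×128, 256 points/step) and
`tiny_overfit_config`, the single-image memorization setup used in the
tests (scale range [1, 2] so crops fit a 96 px source; lr 1e−3 — a small
model memorizing one image tolerates and needs a larger step size — decayed
at 70/85/95 % of 4000 steps). On one 96×96 phantom this preset reaches
roughly +1 dB PSNR over bicubic at ×2 reconstruction in about 3 minutes.

## Bicubic dialect

Downscaling dialects differ across libraries, so the package pins its own:
separable Keys cubic convolution with a = −0.5, output centers aligned to
input centers (u = (i+0.5)·n_in/n_out − 0.5), kernel support widened by the
scale ratio when downscaling with antialiasing, per-output-pixel weight
normalization, and a periodic boundary. The periodic boundary keeps the
normalized kernel an exact partition of unity at every output pixel, so the
operator is exactly mean-preserving — a constant image stays constant to
machine precision and an alternating 1-px checkerboard antialiases to
exactly 0.5 — which gives closed-form oracle values for tests ("replicate"
is available as an option). Identity at equal sizes is exact.

## Metrics

PSNR = 10·log₁₀(1/MSE) on [0,1] RGB jointly (MAX = 1), no border crop,
capped at 100 dB when MSE < 1e−10. Luma-only PSNR and SSIM are out of
scope; the joint-RGB convention is stated so numbers are comparable.

## Synthetic phantoms

The generator emulates the features of en-face OCT-A angiograms that matter
to this task: a dark background (level 0.10) with Gaussian-smoothed
low-frequency perfusion texture (amplitude 0.08, σ = 8 px); 3 branching
vessel trees grown as smoothly curving random walks from the image border,
rendered with Gaussian cross-sections, root widths 1–4 px tapering along
the vessel and at branches; and unit-mean multiplicative gamma speckle
(shape 40, i.e. ~16 % standard deviation), the standard coherent-imaging
noise surrogate. The clean render and the centerline mask are returned
alongside the speckled image for oracle-style tests. What the phantoms do
*not* model: flow dynamics, projection and motion artifacts, vendor
post-processing, or the intensity statistics of any real OCT-A device —
so passing tests demonstrate correctness and learnability of the method,
not clinical-grade performance on real angiograms. Analytic fixtures
(constant, linear gradient, sinusoid at pixel centers) provide
deterministic closed-form inputs.

## Numerical and engineering choices

* float64 throughout; the model is small enough that speed is acceptable
  and tolerances can be tight (1e−6 against oracles).
* The autodiff core implements only the operations the model uses; dense
  layers go through `np.einsum`, whose reduction order does not depend on
  the batch size, so decoder outputs are bitwise identical under any query
  chunking (the encoder, which runs once per image, uses BLAS contractions
  for speed).
* Fractional-factor output sizes round half-away-from-zero on scale·dim.
* Checkpoints are `.npz` containers with named arrays, a JSON config echo
  and a format-version tag; loading is bit-exact and validates the version
  and region size.
* Grayscale inputs are replicated to three channels at load time; 8-bit
  conversion is round-half-away after clamping.
* Problem sizes in the tests (48–96 px sources, 4-block/16-depth reduced
  encoder, ≤4000 steps) were chosen so the whole suite runs on a single
  CPU in minutes while still exercising every code path at full fidelity.

## Known limitations

* The full-scale configuration (16 blocks, D = 64, 100 epochs, batch 16)
  is implemented and tested for contracts (shapes, gradients, schedule)
  but not trained to convergence here; quality numbers in this repository
  come from the reduced presets on synthetic phantoms.
* Very large images are encoded whole (no tiled encoding); memory grows
  with H·W·D.
* The overlapping-window operator's elementwise reading is one of several
  defensible algebraizations; the loop-oracle tests pin the implementation,
  not the uniqueness of the interpretation.
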