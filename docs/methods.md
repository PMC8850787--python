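# Methods

This note documents the models, procedures and design choices behind
`badacount`, in the order data flows through the package.

## Supervision rasters from dots

Dot annotations are 0-based `(x, y)` pixel coordinates of plant centres.
Three rasters are derived:

**Density map.** Each dot contributes an isotropic 2-D Gaussian of variance
σ², normalised to unit mass in the continuous plane, evaluated at integer
pixel centres.  Kernel support is cut at a square window of half-width
⌈4σ⌉ — the omitted tail is below 3.4·10⁻⁴ of the peak — and kernels are
truncated, *not* renormalised, at image borders.  Consequently the map total
equals the dot count to ≲0.1% for interior dots and falls short for dots
within 4σ of a border.  σ is dataset-dependent (it should match the object
scale); the package default is 8 px at full working resolution, and the
synthetic experiments use σ = 4 px to match their 5 px mean plant radius.
Nothing downstream assumes a particular σ.

**Local count map.** The density map is summed over non-overlapping
`h×w = 64×64` pixel blocks (equivalently, convolved with an all-ones kernel
at stride 64).  Mass is conserved exactly when 64 | H and 64 | W; trailing
partial blocks are dropped with a warning otherwise (training crops are
always multiples of 64, so that path is advisory).

**Pseudo foreground mask.** `S_gt(i) = 1 iff D_gt(i) ≥ t_c`.  The default
t_c is 5% of the single-kernel peak `1/(2πσ²)`, which marks a disk of
radius `σ·√(2 ln 20) ≈ 2.45σ` around an isolated dot; t_c is exposed in
configuration because the right coverage depends on the empirical object
size.  The segmentation branch operates at 1/8 resolution, so its target is
S_gt max-pooled by 8 (any-pixel semantics), which preserves full coverage
of every object at the cost of dilating the mask by up to 7 px.

## Network

Both size profiles share one code path; only channel widths differ.

| component | full profile | tiny profile |
|---|---|---|
| encoder FE | VGG16 convs, pools after stages 1–3 → 512 ch @ 1/8 | 3×(conv+pool), 8/16/32 ch |
| decoder FD / seg. branch FS | six 3×3 dilated (rate 2) convs, 512,512,512,256,128,64 | two dilated convs, 32,16 |
| regressor FC | 3×3 conv (65→64), avg-pool 2, 3×3 conv (64→32), avg-pool 4, 1×1 conv | same shape, 16,16 |
| discriminators DF/DM | 2 stride-2 3×3 convs (64 ch) + 1×1 conv → 2-ch softmax | same, 16 ch |

Design choices where the architecture was genuinely open:

- **FS input.** The segmentation branch consumes the shared features M_f
  (not the raw image): this keeps both discriminators attached to
  representations the encoder can align, which is the premise of the
  adversarial design.
- **Decoder style.** The dilated-convolution back-end follows the standard
  density-regression counting architecture this model family extends
  (CSRNet-style), with FD and FS as parallel copies differing in their
  heads (64-channel features vs 2-channel softmax).
- **Discriminators.** Exactly two stride-2 stages, because each output cell
  must correspond to a 4×4 patch of the discriminator input.  Channel 0 is
  the target-domain probability, channel 1 the source-domain probability.
- **Count activation.** C_est passes through softplus rather than ReLU.
  Both guarantee non-negativity, but a ReLU count head can saturate into an
  all-zero prediction with zero gradient everywhere — an absorbing state we
  observed at small scale — whereas softplus always admits recovery.
- **Density-regression ablation head.** `head="density"` replaces the
  pooling regressor with the same convolutions and no pooling, emitting a
  1/8-resolution density map; its training target is the density map
  block-summed by 8 so cell values remain patch counts.
- **Pretrained weights.** The full-profile encoder can load VGG16 weights
  from a local `.npz`; nothing is downloaded, and all tests run the tiny
  profile with seeded random initialisation (He-normal).

## Losses and domain labels

All three objectives are means over the elements of their operand grids
(the number of cells differs per branch; a per-element mean keeps the
losses comparable across profiles and only rescales gradients).  Source
images carry the counting and segmentation losses — target images are
unlabelled, which is the premise of unsupervised adaptation — and both
domains feed the adversarial loss.  Domain labels follow source = 1,
target = 0.  The adversarial loss is the sum of the feature-discriminator
and mask-discriminator binary cross-entropies, each against the constant
label map of its input's domain; probabilities are clamped at ε = 10⁻⁷
inside every cross-entropy.

## Training

One optimisation step samples `batch_size` source and `batch_size` target
crops (default 2+2: both loss groups need data every step), augments them
(optional resize, one random crop, horizontal flip with p = 0.5, dots
transformed accordingly and out-of-crop dots dropped), rasterises the
source targets, and takes a single SGD step on
`L_c + L_s + L_a∘GRL(λ)`.  The gradient reversal layer realises the
min–max game inside one backward pass: discriminator parameters descend
L_a while the encoder and segmentation branch receive the gradient
multiplied by −λ.  At λ = 0 the adversarial gradient into the main branch
is exactly zero and the discriminators still learn.

λ is updated once per epoch as `λ = 2/(1+exp(−γ·p)) − 1` with p the
elapsed-epoch fraction and γ = 10, rising from 0 towards 1.  (The rising
sign is the intended reading of the schedule: the stated behaviour is that
λ increases from 0 to 1, which fixes the sign of the exponent.)

The optimiser is SGD with momentum 0.9 and no weight decay.  The
full-scale schedule is 500 epochs at lr 0.01 with tenfold decays at epochs
250 and 400, on 512×512 crops.  The desk-scale configuration used by the
synthetic experiments is 30 epochs, 64×64 crops, lr 0.01, no decay.  All
randomness (initialisation, batch order, augmentation) derives from two
integer seeds (model, training), making training histories bitwise
reproducible on a fixed platform.

## Metrics

MAE, MSE and MAPE are the usual per-image-total error statistics; MSE is
reported as the mean of squared errors with RMSE = √MSE alongside, since
the counting literature prints both under the same name.  MAPE terms with a
zero true count are skipped with a warning; R² is undefined (reported as
missing) when all true counts are equal.

DMAE splits each image's predicted and true counts into foreground and
background parts using the *same* pseudo mask S_gt, then averages
`|ŷ_b − y_b| + |ŷ_f − y_f|`.  Local count predictions are first expanded
to a per-pixel density by spreading each cell's count uniformly over its
64×64 patch — this conserves totals exactly and requires no extra model
output, at the cost of blurring the split when patches are large relative
to the image (at 128×128 evaluation size, a 2×2 count grid places most
mass on background even for a perfect counter; DMAE comparisons at that
scale are therefore meaningful *between* models rather than as absolute
numbers).  The per-image truth side is computed from the density map, so
y = y_f + y_b holds exactly.

## Synthetic domains

The generator renders textured elliptical "plants" (area-preserving
eccentricity, per-pixel shade jitter) over a low-frequency textured soil
background, with exact dot annotations at centres and a pixel-true object
mask.  Objects are placed with pairwise separation so instances never
merge.  Distractors — weed clumps sharing the plant hue but 0.45–0.65× the
radius and more elongated — are rendered beneath plants, unannotated and
excluded from the mask.  Illumination gain and additive Gaussian noise
close the pipeline.  Defaults: 5–12 plants per image, radius 5±1 px, green
hue on brown soil, noise sd 0.02.

Three presets encode one gap axis each: `scale_shift` (target radius
halved), `hue_shift` (yellower hue, 0.72× illumination) and
`distractor_shift` (10 expected weed clumps per target image).  The
scaled adaptation experiment uses `distractor_shift` with 40 images per
domain at 128×128, the tiny profile and 30 epochs — sizes chosen so the
full contrast (two variants, three seeds) runs in minutes on one CPU.

What the generator does *not* emulate: perspective and view geometry,
occlusion between plants, within-domain illumination variation,
photorealistic texture.  Passing tests on these images therefore
demonstrate that the adaptation machinery behaves as designed under a
controlled gap, not that any particular accuracy transfers to real crops.

## Numerical notes

- All computation is float64; results are deterministic for fixed seeds on
  a fixed platform (single-threaded BLAS recommended — the many small
  matmuls gain nothing from thread pools).
- Inference runs in a no-graph mode; training graphs retain the im2col
  buffers needed for backward, which is why the full profile at 512×512
  is forward-only on desk hardware.
- Ties in max-pooling resolve to the first maximal element (argmax order),
  fixing the subgradient choice.
- The L1 loss uses `sign(0) = 0` as its subgradient at exact equality.

## Known limitations

- The adversarial benefit at desk scale is seed-dependent: when a
  source-only model happens not to key on the distractors, the
  discriminators can slightly perturb an already-good solution (the
  full-scale analogue of this observation holds in the ablation analysis
  of the underlying method).  The packaged experiment averages three seeds.
- Uniform patch expansion limits DMAE's spatial resolution to the 64×64
  count grid (see Metrics).
- The full profile is provided for architectural fidelity and shape
  contracts; training it is out of desk-scale scope.
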