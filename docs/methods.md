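# Methods

## Problem and model

`stainshift` translates histological tile images between two stain domains
without paired examples: H&E (hematoxylin–eosin; pink-to-purple tissue,
dark-purple nuclei) and p63 immunohistochemistry (blue counterstained tissue,
brown myoepithelial cells). The backbone is a cycle-consistent GAN — two
generators G_AB, G_BA and two patch discriminators D_A, D_B — augmented with
three mechanisms:

1. **Context-preserving loss.** Each generator is split into an encoder
   G_enc, a latent transformation G_conv (a stack of residual blocks) and a
   decoder. For a real A-tile and its translation B′ = G_AB(A), four Huber
   penalties tie the stages of the two generators together:

       C_α = H(G_enc^AB(A),  G_conv^BA(B′))     C_β = H(G_conv^AB(A), G_enc^BA(B′))
       C_γ = H(G_enc^BA(B),  G_conv^AB(A′))     C_δ = H(G_conv^BA(B), G_enc^AB(A′))

       L_context = (C_α + C_β)/2 · γ_A + (C_γ + C_δ)/2 · γ_B

   with γ_A = γ_B = 5. The intent is that both encoders agree on the
   *structure* of corresponding real/translated tiles, so all stain-specific
   (color) change is forced into the latent transformation. Both arguments
   of each Huber term carry gradients by default; a config switch
   (`context_detach_real`) stops gradients through the real-image latents
   for ablations, since either convention is defensible.

2. **Convolutional-attention skip merging.** The decoder's two bottom-most
   levels merge with the encoder skips through non-local attention
   (query from the decoder path, key/value from the skip, softmax over
   spatial positions, 1×1 output projection) instead of plain concatenation:

       out = dec + out_proj(softmax(qᵀk) · v) + w_skip · skip

   Query/key channels are reduced aggressively — reductions 64 and 32 on
   widths 256 and 128, i.e. 4 attention channels at both levels — which is
   what makes full-scale attention affordable. A learnable scalar w_skip
   (init 1.0) preserves a plain additive skip. Higher levels use plain
   learnable-weight skips.

3. **Explainability-driven training.** Before each generator update the
   discriminator's input-saliency map — |∂ mean score / ∂ image|, normalised
   by its maximum (zero map if the gradient vanishes) — is attached as an
   elementwise gate on the gradient flowing into the fake image. Generator
   learning thus concentrates on the regions the discriminator actually uses.
   The generators also consume a fourth all-ones hard-mask input channel
   (the interpretable-latent mechanism inherited from mask-based CycleGAN
   variants); masked training augmentation is supported but off by default.

Tiles are processed in CIELAB. The network output ends in tanh; per-channel
dataset statistics (min/max over all training pixels, pooled across both
domains) define an affine map between [-1, 1] and the observed L*a*b* range,
so the tanh output covers exactly the data gamut. A trainable luminance
multiplier (init 1.0) scales the L* channel only. A differentiable
joint-bilateral blur guided by the generator's *input* image, followed by an
unsharp mask, is applied to fake images inside the training graph (the guide
is treated as a constant, which makes the filter linear in the image and
keeps gradients exact).

## Closed-form editing

The first convolution of the latent-transform stack is the designated
interpretable latent layer. Its weight tensor [C_out, C_in, k, k] is
flattened to W [C_out, C_in·k·k] and normalised by its global Frobenius norm
(per-row normalisation is available behind a flag, since factorisation
variants differ). Edit directions are the eigenvectors of W_norm W_normᵀ
(symmetric PSD, eigenvalues sorted descending); direction *i* acts as the
outer product V_i = v_i v_iᵀ on the channel vector at every spatial position:

    X_mod = X + Σ_i (V_i · α_i) X

Editing intercepts the forward pass just past that convolution and leaves
the rest of the generator untouched. |α| ≤ 3 is advisory (larger values run
with a warning); all-zero α short-circuits to the identical feature map so
the edited output is bit-for-bit the unedited conversion.

## Losses and optimisation

Least-squares adversarial loss (targets 1/0), L1 cycle loss (weight 10), L1
identity loss (weight 5), context loss as above (Huber δ = 1.0, mean
reduction — δ and the reduction are package choices). Adam with lr 2e-4 and
β = (0.5, 0.999) for all four networks; discriminators update first, then
both generators jointly; no learning-rate schedule. All weights live in a
single `LossWeights`/`TrainConfig` structure serialised into every
checkpoint; a fit is a pure function of (config, data), with batch order
drawn from a seeded generator whose state is checkpointed, so resumed runs
continue bit-identically.

## Numerical engine

The networks run on a compact reverse-mode automatic-differentiation engine
over NumPy (float32 graphs; python scalars join at float32 so they do not
promote the graph). Convolution uses im2col with explicit col2im backward;
every operator is validated against central finite differences in the test
suite. Tensors expose a `grad_hook` applied to the fully-accumulated
gradient before back-propagation to parents — the saliency gate uses exactly
this hook, so gated positions receive *exactly* zero gradient.

## Synthetic data

Real double-stained slides are private, so the generator emulates the
features the pipeline depends on: a near-white background with smooth
intensity non-uniformity (jitter 0.02), blob-shaped tissue regions (smoothed
Gaussian noise thresholded at an exact pixel count, giving a tissue fraction
drawn uniformly from [0.35, 0.75]), nuclei placed uniformly inside tissue
(density 0.004/px, ~30% labelled myoepithelial), and fixed RGB palette
anchors per domain with smooth per-tile mixing plus mild sensor grain
(σ = 0.008). Paired mode renders both stains from one structure field and
exists only for diagnostics; training uses disjoint structures, matching the
unpaired regime. The tiles are *not* photorealistic: no staining artifacts,
no out-of-focus regions, no scanner color profiles, no spatial arrangement
of myoepithelium around ducts. Passing tests therefore demonstrate that the
machinery optimises and translates palettes on structured images — not
clinical-grade virtual staining.

## Desk-scale study conditions

CPU-scale runs use 64 px tiles, a 4-level tiny generator (widths 6/8/12/16,
one latent block, attention reductions 4/3 → 4 attention channels at both
merge levels, ~12k parameters) and tiny discriminators, batch size 1,
400 steps over 200 synthetic tiles per domain. The depth places attention at
8² and 16² spatial positions, keeping the quadratic softmax cheap. Under
these conditions the cycle-reconstruction L1 typically falls to ~0.3× its
initial level within 400 steps and the toy-extractor Fréchet distance of
generated-vs-real p63 tiles drops by an order of magnitude. Evaluation uses
a fixed-seed random-convolution feature extractor; pretrained inception
features require a downloaded network and are deliberately not bundled, so
absolute values are not comparable to published FID scales — only relative
changes under one extractor are meaningful.

## Numerical and degenerate-input policy

- Entropy: 256-bin histogram of 8-bit Rec. 601 luma; filter threshold
  4.0 bits by default, inclusive (≥) at the boundary.
- Tiling: 0-based row-major half-open blocks; partial edge tiles dropped;
  an image smaller than the tile size warns and yields no tiles.
- Downscaling: exact block-mean area averaging, integer factors only
  (associative across power-of-two chains to float tolerance).
- Range mapping: to_model_range errors on a degenerate channel
  (max = min); the inverse is exact by construction.
- Fréchet distance: matrix square roots via eigendecomposition of the
  symmetrised argument with negative eigenvalues clamped to zero; the
  result is floored at 0.
- Survey summaries recover integer rating sums as round(avg · raters)
  before averaging, so published rounded per-pair means reproduce the exact
  overall mean; totals are honest column sums.
- Training aborts with a diagnostic on any non-finite loss.

## Known limitations

- No GPU path; full-resolution (256 px, width-256) training is out of
  practical reach of the NumPy engine and is configuration-only here.
- The bilateral guide is the generator input; guiding by the output (a
  plausible alternative reading) would make the filter nonlinear and is not
  implemented.
- Attention memory grows with the fourth power of the merge-level spatial
  size; 256 px tiles with the default depth imply 64² positions at the
  bottom merge.
- Olympus VSI slide reading is out of scope; sources are PNG/TIFF.
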