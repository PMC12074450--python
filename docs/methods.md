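# Methods

## The synthetic world

Every sample is generated from a latent unit vector `z ∈ R^D` (uniform on
the sphere), with `D = 32` by default.

- **Pixels.** `x = clamp01(0.5 + 0.5·G z + η)`, where `G` (pixel_dim × D) has
  orthonormal columns (QR of a seeded Gaussian matrix, sign-fixed for
  uniqueness) and `η` is i.i.d. Gaussian pixel noise, σ = 0.01. The map is
  linear so that a linear encoder inverts it exactly and attack gradients
  have closed forms.
- **Captions.** The indices of the `m = 6` vocabulary tokens (of 128 unit
  vectors in `R^D`) with the largest dot product to `z`, in descending
  order. This gives graded image–caption similarity (matched-pair mean
  cosine ≈ 0.68 in the toy world), enough structure for retrieval metrics
  to be meaningful.
- **Brain features.** `f_b = ρ f_o + √(1−ρ²) u`, with `f_o` the embedding of
  the *clean* pixels and `u` a seeded unit vector orthogonal to `f_o`, so
  `cos(f_b, f_o) = ρ` exactly. ρ defaults to 0.85 ("good but imperfect"
  decoding); it is a free sweep parameter because real decoder fidelity is
  not a published quantity. Brain features are a function of the clean image
  only — the generating code never sees a perturbed image — which encodes the
  hypothesis that imperceptible perturbations leave brain activity unchanged.
- **Splits.** 600 train / 100 test, preserving a ≈9:1 ratio at desk scale.
  Per-sample random streams are hashed from (global seed, sample index), so
  generating more samples never changes earlier ones and regeneration is
  bit-identical.

What the generator does *not* emulate: natural image statistics (the toy
images are low-contrast linear noise), augmentation-invariant backbone
features (see below), voxel-level fMRI noise structure, or semantic caption
overlap between samples. Passing tests therefore demonstrate that the
*mechanism* — an attack-invariant side channel restoring attacked embeddings
— works as designed, not that the specific numbers transfer to a real
encoder and decoder.

## Encoders

The joint-encoder contract requires unit-norm outputs, pixel-determinism,
and the gradient of the image–caption cosine with respect to pixels. The toy
instance is `e(x) = normalize(Gᵀ(2x − 1))`; pixels are recentred to [−1, 1]
so the constant mid-gray image maps to the zero vector and is rejected as
degenerate rather than silently embedded with a bias. Text encoding is an
order-free normalized sum of token vectors. The analytic cosine gradient is
checked against central finite differences (tolerance 1e-4).

A consequence worth flagging: a *random* linear map is not augmentation-
invariant. Grayscale and blur keep ≈0.97 mean cosine to the original
embedding, but crop/resize and rotate/translate keep only ≈0.37 — real
contrastively trained backbones are far more invariant. This makes the toy
task *harder* than the real one on the clean side (two of five training
views are nearly uninformative) and shapes several results below.

## Augmentation

Slot 0 is the untouched original; slots 1–4 are crop (area fraction
U[0.6, 1.0], resized back bilinearly, horizontal flip w.p. 0.5),
rotation U[−15°, 15°] + horizontal translation U[−10%, 10%] of width with
reflection padding, luminance grayscale (0.299, 0.587, 0.114), and Gaussian
blur (σ = 1, 5×5 support, reflect boundary). The named transform families
follow the usual self-supervised menu; the numeric ranges are common
defaults recorded in config for sweeps. Draws are fixed per (image, seed) —
not per epoch — so the training set is a deterministic function of the
configuration.

## Attacks

All attacks minimize `J(x') = cos(e(x'), t)` subject to
`‖x' − x‖∞ ≤ ε` and `x' ∈ [0,1]`, and return the best iterate evaluated
(including the clean start when random start is off, so the reported
objective never exceeds the clean one).

- `pgd`: 20 signed-gradient steps of ε/4.
- `apgd`: momentum 0.75, initial step 2ε, checkpoint fractions
  p₀=0, p₁=0.22, p_{j+1}=p_j+max(p_j−p_{j−1}−0.03, 0.06); at each checkpoint
  the step is halved and the search restarts from the best iterate if fewer
  than 75% of the interval's steps improved, or if the step was left
  unchanged and the best objective stalled. The plain projected step is also
  evaluated each iteration. With the pgd-sized step the momentum iterates
  sit microscopically inside the ball corners and apgd loses to pgd by ~1e-6
  on every sample; the 2ε start plus halving schedule is the canonical cure.
- `cw`: the margin-attack family adapted to a bounded similarity objective —
  continuous (un-signed) gradient normalized to unit ℓ∞, step ε/10, same
  projections. It is the weakest of the three here, consistent with its
  smaller effective step.

Attacks never touch brain features — the invariance hypothesis is enforced
structurally, not assumed statistically.

**Perceptibility.** PSNR is `10·log₁₀(1/MSE)` on the [0,1] scale (the ratio
is scale-free; a uniform 2/255 perturbation gives 20·log₁₀(255/2) ≈ 42.11 dB,
always above the 40 dB imperceptibility threshold). SSIM uses a 7×7 Gaussian
window (σ = 1.5), K₁ = 0.01, K₂ = 0.03, per channel, averaged. On the
low-contrast toy images the sign-saturating attacks score SSIM ≈ 0.95 —
below the 0.985 threshold that real photographs clear — because the images'
local variance is tiny relative to the perturbation; the audit reports this
honestly rather than emulating the real-image value.

## Defense

Integration is pure concatenation `[f_b ; f_a^n]` (both halves arrive
unit-norm from their providers; no renormalization). The regressor is
2D → 4D → 4D → D with ReLU hidden activations and a linear output — the
smallest round capacity that comfortably fits the ρ = 1 recovery check.
Training: Adam (step 1e-3), 200 epochs, mini-batches of 32 samples (all N
columns of a sample travel together, keeping the loss a per-sample mean),
fixed seed, single-threaded numpy — bit-deterministic. Optional decoupled
weight decay is available in `TrainConfig` and off by default.

**Decoding-noise resampling.** When a fidelity ρ is supplied, the orthogonal
noise component of every brain feature is redrawn each epoch during
training (test-time features stay fixed per sample). Rationale: with a
single frozen noise vector per sample, the 33k-parameter network simply
memorizes the train decodings (clean test cosine ≈ 0.79, *below* the ρ=0.85
brain-alone ceiling), whereas redrawing the noise — the analogue of
trial-to-trial fMRI variability, which real datasets average over repeated
presentations — forces the generalizing conditional estimator (clean ≈ 0.90,
attacked ≈ 0.86). Longer training (400+ epochs) was checked and slightly
*hurts* both numbers, so 200 epochs is the converged choice, not a budget.

Train/test asymmetry follows the stated protocol: training supervises all
five augmented columns against the sample's single `f_o`; testing encodes
the single test image with no augmentation.

## Baselines

- *identity*: the raw encoder (measures attack success).
- *no-fMRI*: same pipeline, input `f_a` alone (width D) — isolates the brain
  contribution.
- *noise control*: brain slot replaced by a per-sample fixed random unit
  vector (chance level; deliberately memorizable, and it memorizes).
- *randomized smoothing*: mean embedding over M = 16 Gaussian-noised copies
  (σ = 0.05), renormalized; *random self-ensemble*: mean over M = 10 noisy
  forward passes (σ = 0.02 on hidden pre-activations) of the trained
  defense. Both are adaptations from classification to embedding regression
  (average, then renormalize where a unit vector is expected); noise scales
  and ensemble sizes are config-exposed since no canonical values exist for
  this setting.
- *adversarial training (ideal)*: D → D regressor from attacked-image
  embeddings to clean embeddings, trained and evaluated on the same attack.

## Evaluation

Sim_image / Sim_text are mean cosines over the test split. Retrieval uses
all S test captions as the candidate pool with exactly one ground truth per
sample; rank is competition-style (1 + number of strictly greater
similarities, so ties never penalize) and top-k membership breaks residual
ties by ascending candidate index — both choices are deterministic and are
verified against an exhaustive sort-based oracle. The experiment driver
validates method/attack names before any compute, generates each attacked
test set once per condition against the encoder (the attacker targets the
backbone, not the defenses), and emits one row per (method, condition).

## Known limitations

- The toy encoder's weak spatial-augmentation invariance caps the defense's
  clean similarity near 0.90 (the converged value across seeds is
  0.897–0.903): the estimator keeps a brain-channel component in its clean
  predictions because two of its five training views are nearly
  uninformative. A backbone with augmentation-invariant features would not
  pay this price.
- Ideal adversarial training is *not* an upper bound at this scale: 600
  embedding pairs in 32 dimensions are too few to learn the attack-inversion
  map (own-attack test cosine ≈ 0.48 vs ≈ 0.80 on train), so the
  brain-integrated defense dominates it under attack. The upper-bound
  relationship reported at full scale needs the large-sample, high-dimension
  regime.
- The ρ = 0 ablation leaves a small (~0.09) attacked-similarity advantage
  over the no-fMRI baseline. This residue is a regularization side-effect of
  noise resampling (pure input noise acts like dropout on the 2D-input
  model), not brain information; the brain-driven part of the advantage
  (~0.32 at ρ = 0.85) collapses by ~75%.
- PNG export quantizes pixels to 8 bits; 1/255-scale perturbations survive
  only in the float TSV/array dumps, which are the canonical storage.
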