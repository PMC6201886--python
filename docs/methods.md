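# Methods

## Problem setting

Whole-slide scanners pick focus points at acquisition time; when a focus
point lands off the true tissue height by a focal offset Ω (μm), the
resulting region is defocused, and the blur grows with |Ω|. `deepfocus`
detects such regions tile-by-tile: a slide is partitioned into
non-overlapping 64×64-px tiles at 40x (0.2461 μm/px), each tile is
classified in-focus vs blurred by a small CNN, and the per-tile decisions
form a focus mask over the slide.

The labelling convention follows the focal-offset acquisition protocol:
tiles scanned at Ω ∈ [−0.5, 0.5] μm (inclusive) are *in-focus*; everything
beyond is *blurred*. The nine-plane protocol uses
Ω ∈ {−2.5, −2, −1.5, −0.5, 0, 0.5, 1.5, 2, 2.5} μm.

## Synthetic acquisition model (`blurlab`)

No scanned slides ship with the package, so all experiments run on a
synthetic emulation of the protocol:

- **Tiles.** Stained-tissue-like 64×64 RGB tiles: a low-frequency
  cytoplasm density field over a glass-white background, plus
  anti-aliased elliptical nuclei (semi-axis 3–8 px at 40x, random
  orientation/eccentricity). Colour schemes model H&E (purple nuclei,
  pink cytoplasm) and DAB-chromogen IHC (Ki67, CD21, CD10) with a
  per-stain fraction of brown nuclei. Geometry draws are independent of
  the stain, so the same seed renders the same tissue under different
  stains. Purely phenomenological — no attempt at chromatin texture or
  stain variability.
- **Defocus.** An isotropic Gaussian PSF whose width is linear in the
  offset magnitude: σ(Ω) = σ₀ + s·|Ω|, defaults σ₀ = 0.4 px (residual
  blur of a perfect scan) and s = 1.0 px/μm. The linear-in-|Ω| law is a
  modelling choice — the protocol only establishes that blur grows with
  the offset distance and is well-described by a Gaussian family; the
  constants are set so the nine-offset grid spans visually sharp to
  clearly blurred at 64×64-px scale. The kernel is normalized, truncated
  at 4σ, reflect boundary, so mean intensity is preserved away from tile
  borders.
- **Sign symmetry.** Blur is symmetric in the sign of Ω by default.
  Real tissue has finite thickness, so some nuclei sit at a different
  depth and stay sharp on the negative side of the sweep; this is opt-in
  (`depth_variation`, default 15% of nucleus regions composited back
  sharp at Ω < 0) because the effect is only qualitative.
- **Noise.** Additive Gaussian sensor noise, sd 0.01 in [0, 1] units,
  applied after blur and clipped. Scanner noise is not otherwise
  characterized; one constant is enough to give the spectral estimators
  a realistic noise floor.
- **Offset pairing.** Within a dataset the per-position render seed is
  shared across offsets, so the nine offset versions of a position show
  the same content at different blur — exactly the property the real
  protocol achieves by rescanning the same ROI at perturbed focus.
- **Slides.** A smooth random field thresholded at the requested
  quantile gives the tissue support (so the tissue fraction is matched
  by construction); tiles of the slide carry a per-tile offset field,
  applied as patchwise blur with smooth blending; ground truth is the
  per-pixel tissue mask and the per-tile label grid.

What the generator does **not** emulate: stain variability and batch
effects, optical aberrations other than Gaussian defocus, tissue folds,
bubbles, pen marks, compression artifacts. Passing tests on this
generator therefore demonstrate that the pipeline recovers a known
blur-labelling rule under controlled conditions, not that any fixed
accuracy carries over to scanner data.

## Preprocessing (`tileset`)

8-bit intensities are scaled linearly to [0, 1] (the scaler refuses
already-scaled float input rather than silently shrinking it). Zero
centering subtracts per-channel means computed **on the training split
only**; the three scalars are stored with the model and re-applied to any
new data, so validation/test data may legitimately have non-zero mean.
Per-channel (rather than per-pixel) centering keeps the statistics small
and storable.

Class balancing samples the majority class down without replacement;
the validation split (default 10%) is stratified by class within one
tile. Augmentation draws uniformly from the 8 dihedral transforms
generated by horizontal/vertical flips and 90° rotation, applied
on-the-fly during training so an epoch remains one pass over the
training tiles.

## The classifier (`focusnet`)

Five stride-1 'same' convolutions with ReLU activations; batch
normalization **after** the activation on every conv block; 2×2 stride-2
max pooling after conv 3, 4 and 5 (64 → 32 → 16 → 8 px); fully connected
ReLU layers with dropout p = 0.2; softmax over the two classes; and
categorical cross-entropy as the objective, minimized by plain SGD
(mini-batches of 64, learning rate 0.01 — the grid-search optimum of the
explored space: layer-1 kernel {3,5,7,9} → 5, layer-2 kernel {3,5,7} → 3,
learning rate {0.01, 0.06, 0.12, 0.22}, batch {32, 64, 128}).

Batch normalization implements û = (u − ū)/√(σ² + ε), BN(u) = γû + β with
per-feature mini-batch statistics (population variance) in training and
running statistics at inference. ε = e⁻¹⁵ ≈ 3.06·10⁻⁷, taken literally
and configurable. Running statistics use an exponential moving average
(momentum 0.99) with bias correction (division by 1 − mᵗ): without the
correction, short desk-scale runs would evaluate inference-mode BN
against near-initialization statistics and validation accuracy would be
meaningless.

The engine is pure NumPy: im2col convolution lowered to BLAS matmuls,
manual backprop (verified against central finite differences to ~1e-8
relative error), He initialization from a seeded generator, and
single-threaded determinism — two runs with the same seed produce
bit-identical histories. The first conv layer skips its input gradient
(nothing consumes it).

Defaults are sized for single-CPU training: conv channels
(8, 16, 16, 32, 32), FC widths (64, 32). Widths are configurable; the
blur-vs-sharp texture decision is low-capacity compared to object
recognition, and at desk scale the small net already saturates the
synthetic task. Training stops at max 20 epochs or after 3 epochs
without validation-accuracy improvement, returning the best-validation
epoch's parameters. Dropout in FC layers only; no BN on FC layers
(regularization there is dropout's job). SGD momentum is 0 (plain SGD),
no weight decay.

Classification thresholds the in-focus probability at 0.5, strictly:
p > 0.5 → in-focus, p = 0.5 → blurred.

## Whole-slide inference (`slidescan`)

A ~1x thumbnail (1/magnification of level 0 when known, else 1/32,
block-averaged) is converted to luminance (0.299R + 0.587G + 0.114B) and
split by Otsu's threshold — the cut maximizing between-class variance on
the 256-bin histogram, computed exactly with ties resolved to the
smallest threshold; the darker class is tissue (stained tissue absorbs
light, glass is bright). A tile is classified iff ≥ 50% of its footprint
maps to tissue (configurable); partial edge tiles are dropped, matching
the non-overlapping 64×64 arithmetic. A constant all-glass thumbnail
yields an empty tissue mask and an all-background focus mask rather than
an error. Tiles stream row-by-row in bounded batches, so memory does not
scale with slide area. The mask renders as a green (in-focus) / red
(blurred) alpha overlay and exports as PNG + TSV + summary JSON.

Vendor WSI formats are out of scope; the reader accepts in-memory
arrays and plain/pyramidal TIFF via `tifffile`.

## Classical baseline (`classical_baseline`)

The comparison pipeline: 2× area-average downsampling to 20x, Tenengrad
(mean squared 3×3 Sobel magnitude, reflect boundary — the plain variant;
no threshold), and Haralick statistics (contrast, entropy, plus energy
and homogeneity as optional extras) of a gray-level co-occurrence matrix
(32 levels, distance 1, four angles averaged, symmetric, normalized —
parameters unpublished for the original, so fixed here once). A CART
decision tree (Gini, depth ≤ 8) classifies the feature vectors, and the
label map is cleaned by gray-scale 3×3 closing-then-opening, which
removes isolated single-tile errors and is idempotent on binary maps.

## Evaluation (`evalkit`)

Accuracy = (TP + TN)/(P + N) over in-focus (P) and blurred (N) tiles at
the strict 0.5 threshold. Per-offset tables report the accuracy of each
slide at each offset, the mean and **sample (n−1) standard deviation**
over slides per offset, and the grand mean/std over per-offset means —
the sample-std convention reproduces the published aggregate (93.2% ±
9.6% for the CNN from its nine printed per-offset values; 69.4% for the
baseline; 23.8% difference of grand means), which is how those
aggregates are verified arithmetically in the tests. A single-slide
group reports std 0 and is flagged. ROC curves sweep the unique scores
(scikit-learn), with trapezoidal AUC; the tests pin AUC to the pairwise
Mann-Whitney construction.

### Blur-width estimation

`estimate_blur_sigma` performs blind deconvolution restricted to the
parametric family of isotropic Gaussian PSFs. The observation model is
y = k_σ ∗ x + n with a power-law Gaussian spectral prior on the sharp
image (S(f) ∝ f^(−α), α ∈ {1.5 … 3.5}) and white sensor noise. For each
σ on a 0–6 px grid (step 0.1), the sharp image is integrated out
analytically, giving independent per-frequency exponential likelihoods
of the periodogram, v(f) = A·|K_σ(f)|²·f^(−α) + η²; the prior amplitude
A is profiled out by fixed-point iteration and the grid argmax is
returned. Numerical details: per-RGB-channel periodograms of the
reflect-padded (64→128 px), Hann-windowed tile; η² estimated from the
median periodogram above 0.42 cycles/px (where any σ ≥ 0.5 blur is
spectrally dead), floored at 10⁻⁶ of total power; and a second fitting
pass restricted to the sub-band where the first-pass kernel retains
> 10⁻³ of its power, so noise-floor bins cannot steer the fit. A
constant tile is unidentifiable and returns σ = 0 with a flag.

A naive "deconvolve, re-blur, compare" residual is *not* identifiable —
a converged deconvolution re-blurred with any kernel reproduces the
observation — which is why the marginal-likelihood form is used. The
estimator assumes a sensor-noise floor; on noise-free heavy blur
(σ ≳ 2) it underestimates. On generator tiles with the default noise it
recovers σ ∈ [0.5, 3] with group-mean error ≤ ~0.35 px.

## Desk-scale experiment sizes

The full protocol (16 slides × 9 offsets × 2,500 tiles = 360,000) is
exercised as bookkeeping only (manifests carry labels without pixels).
The rendered end-to-end experiment uses 15 source slides × 9 offsets ×
30 positions = 4,050 tiles (2,700 after balancing, 2,430/270
train/validation), the default architecture, 5 epochs — sizes chosen so
the whole pipeline trains in minutes on one CPU while still reaching
≥ 90% held-out accuracy on clearly blurred (|Ω| ≥ 1.5 μm) tiles from
unseen synthetic slides, and ≥ 80% agreement with ground truth on a
2,048² synthetic slide with a defocused quadrant. Held-out evaluation
uses 4 fresh slides × 9 × 20 = 720 tiles.

## Known limitations

- Synthetic tissue is far simpler than real histology; absolute
  accuracies here do not transfer to scanner data.
- The ±0.5 μm offsets sit near the labelling boundary by construction
  (σ = 0.9 px vs 0.4 px) and dominate the residual error, mirroring the
  fact that sub-half-micron defocus is hard to call visually.
- The offset→σ constants are package choices, not measured optics.
- The NumPy engine is single-threaded CPU code; it is deterministic and
  auditable, not fast. Large-scale retraining would use a compiled DL
  framework with the same architecture.
- Blur-width estimation assumes an isotropic Gaussian PSF and a
  power-law texture spectrum; strongly anisotropic motion-like blur or
  near-periodic textures would violate it.
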