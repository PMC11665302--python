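# Methods

## Models

A bag is one slide: an `n × d` matrix of tile embeddings (d = 1024 by
default, matching the common output length of pretrained histology
encoders; synthetic fixtures use d = 32 for speed) with one binary label.
Three variants share a two-layer attention scorer
`ψ_a(h) = wᵀ·act(V·hᵀ)` with `V ∈ R^{D×d}`, `w ∈ R^D`:

| variant | attention activation | head |
| --- | --- | --- |
| `amil` | tanh | affine classifier on the pooled vector `Σ aᵢhᵢ` |
| `admil` | LeakyReLU (slope 0.01) | affine patch score layer on each `aᵢhᵢ`, summed |
| `admil_tanh` | tanh | additive head of `admil` |

Attention weights are the softmax of the instance scores, so they are
nonnegative and sum to one; all three forward passes are permutation
invariant. For additive variants the bag logits equal the column sum of the
per-patch logits by construction — the decomposition that makes each
patch's contribution explicit. Sigmoid-bounding a patch's positive-class
logit yields a score in (0, 1); a score of exactly 0.5 is classed
inhibitory (the negative side of the boundary is treated as closed).

Design choices where the architecture is genuinely open:

* **Attention width D = 128** (configurable) — the customary width in the
  attention-MIL lineage; the gated-attention variant is deliberately not
  implemented.
* **Head ψ_p is a single affine layer producing C = 2 logits.** The
  two-class softmax with cross-entropy on the positive class is identical
  to binary cross-entropy on a single sigmoid logit, but keeps an explicit
  per-class score for the contribution maps.
* **A single shared attention vector** is used for the additive variants
  (not per-class attention).
* Both attention variants use the same two-layer scorer form, differing
  only in the activation; whether the original additive architecture used
  more layers before its LeakyReLU is not recoverable, so the shared form
  is assumed and configurable.

### Numerics

Parameters are stored in float32. Forward passes upcast to float64 so that
softmax simplex sums and the additive bag-logit identity hold to ~1e-9 even
for large bags, and the closed-form backprop used in training is exact for
the same reason. Initialization is uniform fan-in (`U(±1/√fan_in)`), fully
determined by an integer seed.

## Training protocol

Slides are split 80/20 (stratified by label; per-class train counts are
apportioned by largest remainder so `|train| = round(0.8·N)` exactly). The
training set undergoes stratified 5-fold cross-validation (plain k-fold
with a warning when a class has fewer members than folds); the model from
the fold with the best validation AUC is evaluated once on the held-out
test set (ties break to the lowest fold index; folds whose validation split
has one class have undefined AUC and are excluded). This is repeated over
replicate seeds — 5 by default, each re-splitting train/test — and the mean
and standard deviation of the test AUCs are reported.

Optimization: Adam (lr 1e-4, β = 0.9/0.999), 30 epochs, one bag per step
(bags have variable size), no early stopping, no weight decay by default.
These settings were chosen at desk scale: the one-bag-per-step regime
overfits quickly at higher learning rates, while 30 epochs at 1e-4 trains
all three variants to their generalization plateau on the synthetic
fixture. All settings are config keys.

AUC is the tie-aware rank statistic (Mann–Whitney U normalized by
`n₊·n₋`, ties at half credit), computed via scikit-learn and cross-checked
in the tests against a brute-force all-pairs concordance count.

## Slide pipeline

Coordinates are 0-based `(x, y)` per level with half-open 512-px tile
footprints snapped to a non-overlapping grid; cross-level mapping goes
through base-level coordinates using the pyramid's downsample factors. The
magnification ladder is fixed at 5×/10×/20× with factor-2 steps.

1. **Tissue mask** (thumbnail = coarsest level): grayscale → Otsu →
   darker-class mask → morphological closing (3×3 square, one pass). A
   uniform thumbnail has no Otsu split and yields an empty mask with a
   warning.
2. **Artifact filter:** the mean RGB color of the masked pixels is computed
   once; pixels farther than a threshold (default 100 RGB units) from that
   mean are dropped. This removes saturated marker-pen strokes and stray
   background whose color is far from tissue.
3. **Tile mapping:** each surviving thumbnail pixel maps to the covering
   tile index at the target magnification; duplicates collapse; output is
   row-major.
4. **Acceptance:** each fetched tile is padded right/bottom to 512 × 512
   with the mean background color (mean RGB outside the tissue set,
   rounded for integer images) when undersized; its tissue fraction is the
   share of pixels darker than the thumbnail's global Otsu threshold
   (passing the global threshold avoids the degenerate per-tile Otsu on
   near-uniform tissue tiles); accept iff fraction ≥ 0.3 (configurable).
5. **Sampling:** at the coarsest magnification, if more than `tile_limit`
   (default 1000) tiles survive, a uniform 60% sample is drawn. Descending
   a magnification, surviving tiles are k-means clustered on their
   embeddings (k = 4 by default, echoing the four-group morphology
   clustering used in related mutation-prediction work) and at most 20
   tiles are drawn per cluster; each drawn tile expands to the 2×2 grid of
   child tiles covering its footprint, which are then accepted like any
   tile. The color-distance, tissue-fraction, limit and k values have no
   canonical published setting; all are config keys.
6. **Augmentation and encoding:** two augmentations per accepted tile
   (HED-space stain scaling `U(0.95, 1.05)` and offset `U(±0.02)`, Gaussian
   noise with σ up to 0.02 of full scale, a quarter-turn rotation, random
   flips), then batched encoding to `d`-vectors and storage.

The tile-count "limit" for fraction sampling is interpreted per slide.

## Encoder and store

Encoders satisfy a small contract (`d`, `name`, batched `encode`). The
built-in `ReferenceEncoder` mean-pools a tile onto a 16×16×3 lattice and
passes the flattened statistics through a fixed seeded Gaussian projection
with tanh — deterministic, dependency-free, and carrying enough spatial
color information for the pipeline's clustering and store tests to be
meaningful. It is a stand-in interface implementation, not a learned
histology encoder; plugging in a pretrained network is the intended use on
real slides. Projection is applied row by row so results are independent of
batch size.

The HDF5 store (schema attribute `schema = 1`) keeps one group per slide:
`embeddings` (float32, n×d), `aug_embeddings` (float32, 2n×d, rows 2i and
2i+1 belonging to parent i), `coords` (int64, n×3: magnification code, x,
y), attributes `label`, `d`, `encoder_name`; row-chunked, gzip-compressed,
written to a temporary file and atomically renamed. Readers can fold the
augmented rows into a bag (training, size 3n) or exclude them (evaluation,
size n); whether augmented embeddings belong inside training bags is left
as a reader flag because both conventions are defensible.

## Heatmaps

Attention overlays min-max rescale the per-tile attention *within one
slide* and map it through a continuous perceptually uniform colormap
(viridis, opacity 0.5, both configurable); absolute attention magnitudes
are not comparable across slides. Contribution overlays use exactly two
colors: red for excitatory (> 0.5), blue for inhibitory (≤ 0.5). Pixels
outside every tile footprint are bit-identical to the input thumbnail, and
rendering is a pure function of its inputs. Attention-pooling models expose
only attention maps; contribution maps require an additive head.

## Synthetic fixtures and what they show

**Bags:** background instances are standard spherical Gaussian noise in
d = 32 dimensions; witness instances are shifted by a vector of norm
μ = 2.0 along a seeded random direction; positive bags contain at least one
witness (expected witness fraction 0.3 — tumor slides typically carry
substantial tumor fractions), negative bags none; 200 bags of 20–100
instances, balanced classes. The mean-statistic oracle separates these
classes perfectly, so the fixture is separable by construction; with μ = 0
the classes are exactly exchangeable and serve as a null control.

**Slides:** white background, smoothly colored eosin-pink tissue disks,
optional saturated green marker strokes (artifact ground truth), optional
darker dotted "signal" regions inside tissue; coarser levels are exact 2×
decimations, so cross-level arithmetic is checkable without interpolation
ambiguity.

These fixtures exercise geometry, contrast, bookkeeping and the MIL
assumption — not stain physics, cell morphology, scanner noise, or the
covariance structure of real histology embeddings. Green tests demonstrate
that the machinery is correct under the stated assumptions, not clinical
performance.

### Observed attention-sparsity behavior

A tracked empirical comparison measures the normalized Shannon entropy of
attention distributions for the two additive variants on matched bags and
seeds. The motivating expectation is that LeakyReLU, passing large
positive scores unchanged into the softmax, concentrates attention on
fewer instances than the compressing tanh. On the Gaussian fixture the
measured ordering is consistently the *opposite*: the tanh scorer develops
a wider attention-logit range and lower entropy at every witness rate and
training length tried. A plausible mechanism is that with isotropic
embeddings and symmetric initialization, roughly half of the LeakyReLU
units sit in the 0.01-slope regime and learn slowly, while the bounded but
nonlinear tanh features let the outer weight vector grow and separate
instances sharply. The corresponding acceptance test encodes the original
qualitative expectation and therefore fails on this fixture; the
discrepancy is reported rather than hidden, and says nothing either way
about behavior on real histology embeddings, where the expectation
originated.

## Problem sizes

Test-suite and reproduction-script runs use the fixture defaults above:
200-bag protocols (5 replicates × 5 folds), a 10-replicate null control,
20 matched entropy runs at 60 bags, 10 slides of 1024² base resolution for
mask recovery, and 3 small pyramids for the pipeline count checks. The
whole suite completes in a few minutes on one CPU.

## Known limitations

* No scanner-vendor formats (SVS/NDPI/DICOM); slides enter via multi-level
  TIFF or the `PyramidHandle` contract.
* No pretrained histology encoder is bundled; the reference encoder is
  deliberately simple.
* Two-class heads only; no gated attention, self-attention, dual-stream or
  instance-dropping variants.
* Stain normalization beyond the HED augmentation, and pen-annotation-
  specific detectors, are out of scope.
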