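# Methods

## Problem setting

Arterial vessels in TOF-MRA appear as bright, thin, sparse tubular
structures — on the order of 0.3–1.5% of head voxels — surrounded by
darker tissue, a bright skull border, and bright non-arterial distractors
(venous sinuses, extracranial arteries) that must remain background.
Whole volumes are too large to process at once, so segmentation is
phrased as voxel-wise classification on patches, with a dual-resolution
context path supplying the anatomical neighbourhood a small patch lacks.

## Architectures

Four variants are built from one declarative `ArchitectureConfig`:

* **unet** — 4-level 3-D encoder–decoder.  Level sequence is
  conv(3×3×3, stride 1, same padding) → ReLU → batch-norm, twice, with
  dropout after the first batch-norm of each level; 2×2×2 max-pooling
  (stride 2) between encoder levels; channel width doubles per level from
  `base_width`; the bottom level is followed by two 1×1×1 convolutions
  with ReLU ("fully connected" layers); the decoder mirrors the encoder
  with parameter-free nearest-neighbour up-sampling and skip
  concatenation; a final 1×1×1 convolution + sigmoid yields the
  probability map.  An initial batch-normalization layer is applied to
  the raw input of every encoder path, replacing any intensity
  pre-processing.
* **context** — adds a parameter-disjoint duplicate encoder whose input
  is the 2×-larger co-centred patch, first 2×2×2 average-pooled to
  primary-patch dimensions (half resolution).  The two bottom outputs are
  concatenated before the 1×1×1 layers, and both encoders' per-level
  feature maps are concatenated into the decoder skips.
* **ds** — deep supervision: every intermediate decoder level (all
  except bottom and final) is up-sampled to output dimensions and passed
  through its own 1×1×1 convolution + sigmoid head.  Head losses are
  weighted 0.5 on the final output and 0.5 split equally across
  intermediate heads.
* **bravenet** — context + deep supervision.

Fixed numerical choices, and why:

* Layer order is conv → ReLU → batch-norm (not the more common
  conv → BN → ReLU); the sequence is part of the architecture definition.
* Up-sampling is parameter-free nearest-neighbour.  Transposed
  convolutions would add parameters and break the reference totals.
* The bottom 1×1×1 layers are 256-channel (i.e. `base_width · 2^(levels−1)`)
  and carry ReLU but no batch-norm.  With base width 32 this puts the
  baseline at 5,970,435 and BRAVE-NET at 10,131,815 trainable scalars
  (~6 M and ~10 M), verified against a closed-form layer-by-layer sum
  (27·c_in·c_out + c_out per 3×3×3 convolution, 2·c per batch-norm).
* Dropout rate defaults to 0.1 (configurable); it sits after the first
  batch-norm of each level.
* The sigmoid is the standard 1/(1 + exp(−f(x))).
* Patch sizes must be divisible by 2^(levels−1) per axis; with the
  default [64 × 64 × 8] and 4 levels the bottom z-extent is 1, which is
  legal and handled.
* Batch-norm uses ε = 1e−5 and running-statistics momentum 0.9; inference
  always uses running statistics.

The networks run on `bravenet.autodiff`, a reverse-mode automatic
differentiation engine over numpy arrays written for this package.  It
implements exactly the primitives the architectures need (same-padded
stride-1 3-D convolution via shift-and-matmul, batch-norm, ReLU, sigmoid,
2×2×2 max/average pooling, nearest up-sampling, concatenation, dropout,
and the reductions used by the loss) plus Adam.  Every primitive's
gradient is tested against central finite differences in float64, and the
convolution forward pass against `scipy.ndimage.correlate`.

## Loss

Soft Dice between a probability patch p and binary labels g:

    DSC(p, g) = (2 Σ p·g + ε) / (Σ p² + Σ g² + ε),   loss = 1 − DSC.

The stabilizer ε = 1 appears in numerator and denominator so the
empty/empty case — frequent, since half the training patches are not
vessel-centric — counts as a perfect score instead of 0/0, and a binary
perfect match still scores exactly 1.  Batches are scored per sample and
averaged.  The analytic gradient

    ∂DSC/∂p_j = 2·[g_j·(Σp² + Σg²) − 2·p_j·Σp·g] / (Σp² + Σg²)²

is implemented as a verification oracle (ε = 0 reproduces it exactly);
training itself uses automatic differentiation.  For deep supervision the
per-head losses are combined as Σ w_i (1 − DSC_i) with the 0.5-final
weighting above.

## Sampling and cross-validation

* **Heuristic mask** (training only): a 16×16×16 box-mean filter
  (stride-1 sliding window, replicate edge padding, implemented with
  `scipy.ndimage.uniform_filter`) followed by a strict intensity->10
  threshold.  This keeps head tissue plus a thick border shell around the
  skull — border patches matter for learning the skull/vessel
  distinction — and removes far-field air.  Inference never uses a mask.
* **Patch centers**: 2,000 per volume by default, drawn inside the mask
  with replacement; exactly ⌈n · vessel_fraction⌉ of them (default 50%)
  sit on vessel-labelled voxels ("vessel-centric" = the center voxel
  itself is a vessel).  The non-vessel quota is drawn from non-vessel
  mask voxels so the split is exact; with vessel_fraction = 0 draws are
  unconstrained within the mask.  Centers are drawn once per volume per
  experiment, not per epoch, to keep runs reproducible.
* **Patches**: primary [64 × 64 × 8], context [128 × 128 × 16], label
  [64 × 64 × 8], all co-centred.  Even sizes have no exact center voxel;
  the center occupies index size/2 per axis, consistently everywhere.
  Out-of-bounds positions are zero-padded.
* **Splits**: per source cohort, each of the k folds' test sets receives
  ⌊count/k⌋ ids; remainder ids stay in training in every fold.  From each
  fold's non-test pool, ⌊0.15 · pool⌋ ids move to validation, stratified
  per source by the same floor rule, any shortfall filled from the
  largest source.  On cohort sizes (74, 9, 181) with 4 folds this yields
  170/29/65 train/validation/test in every fold.  When cohort sizes are
  divisible by the fold count, every id is tested exactly once; otherwise
  the few remainder ids are only ever trained on.

## Training protocol

Adam (β₁ = 0.9, β₂ = 0.999), Glorot-uniform convolution weights, batch
size 16 by default (configurable; in practice the largest that fits),
learning rate selected from {1e−2, 1e−3, 1e−4} by highest mean
whole-volume validation DSC across folds (ties toward the smaller rate).
Patch-level validation loss is monitored each epoch; training stops when
it fails to improve for 3 consecutive epochs (or at max_epochs, default
100), and the best-validation-epoch weights — including batch-norm
running statistics — are restored.  All randomness (sampling, shuffling,
initialization, dropout) is seeded; identical configurations produce
bit-identical histories.

## Inference and evaluation

Whole volumes are tiled with the primary patch (default stride = patch,
i.e. non-overlapping, last tile clamped to the boundary; smaller strides
give overlap-averaging).  Only the final head's probabilities are used.
Binarization is strict (p > 0.5; ties to background).  Fold models are
ensembled by voxel-wise probability averaging before thresholding.

Metrics: Precision, Recall and DSC from the voxel confusion table
(degenerate-denominator conventions: DSC = 1 when both foregrounds are
empty; precision of an empty prediction is 1 only when the ground truth
is empty too; recall is vacuously 1 for an empty ground truth).  AVD is
the maximum of the two directed mean nearest-neighbour distances over all
foreground voxels (not extracted surfaces); 95HD the maximum of the two
directed 95th-percentile distances, with linear interpolation between
order statistics.  Both are computed with Euclidean distance transforms
and verified against brute-force double-loop oracles.  Distances are
reported in voxel units by default; a physical-spacing mode is available.
One empty foreground gives +inf with a warning; two empty foregrounds
give 0.

## Phantom generator

Each phantom emulates the features of a raw TOF head volume that the
pipeline exploits or must be robust to: near-zero air (mean 2) around a
bright ellipsoidal head (tissue mean 80) so the box-mean/threshold-10
mask separates them; a bright ellipsoidal shell (mean 120) as a skull
analogue; vessels as rasterized stochastic branching centerline trees
(direction-persistent random walk, monotonically tapering radii,
0.6–1.6 voxels) at intensity 300; bright unlabelled distractor blobs
(mean 250) as sinus/extracranial analogues; additive Gaussian noise
(σ = 10) clipped at zero.  The per-tree node budget is derived from the
target vessel fraction (default 0.8% of head voxels, inside the 0.3–1.5%
physiological bracket) and trees are added until the target is reached,
so the fraction tracks the target across volume sizes.  The head fills
roughly a third to half of the volume so that air and border patches
exist.  Datasets are round-robin-tagged across synthetic "source"
cohorts to exercise stratification.  All geometry and intensity constants
are package fixtures.

What the phantoms do **not** emulate: MR flow physics and inflow-related
intensity gradients, coil inhomogeneity, Rician noise spectra, anatomy
(Circle of Willis topology, cortical folding), pathology (stenoses,
occlusions), or inter-scanner variability.  Passing the end-to-end tests
therefore shows the pipeline is correct and the architectures can learn a
sparse bright-tubular-structure segmentation; it says nothing about
clinical performance on patient data.

## Desk-scale test sizes

The repository's end-to-end gate trains a base-width-8 BRAVE-NET on
reduced patches (32, 32, 8)/(64, 64, 16) with 48 centers per volume on
six default-size phantoms for up to 8 epochs, and checks whole-volume
DSC ≥ 0.8 on two held-out phantoms (measured: 0.865 and 0.850); the
4-fold cross-validation smoke uses 16 centers per volume and one epoch.
These sizes are the package's CPU-scale defaults for its own tests; the
library defaults remain 2,000 centers, [64 × 64 × 8] patches and base
width 32.

## Known limitations

* The numpy engine is single-threaded and roughly two orders of magnitude
  slower than a GPU framework; full-width training at paper scale is out
  of reach of this implementation.  The architectures, losses and
  protocol are nevertheless exact, and the parameter accounting matches
  the reference totals.
* Tiling strategy and overlap aggregation at inference are choices
  (non-overlapping default with boundary clamping); overlap-averaging is
  available via the stride argument.
* No post-processing (connected components, hole filling) is applied, by
  design.
* Sampling with replacement means duplicate training patches are possible
  when admissible voxels are scarce.
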