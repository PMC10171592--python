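# Methods

## Problem and model

Orbital CT slices of Graves' orbitopathy (GO) patients contain tissues with
distinct Hounsfield-unit (HU) signatures — orbital fat (~ −80 HU), the
vitreous (~ +5 HU), extraocular muscle (~ +50 HU), optic nerve (~ +35 HU),
lacrimal gland (~ +40 HU), bone (~ +1000 HU) — but GO deforms shapes and
sizes, so a segmenter must recover thin, variable structures with clean
boundaries. The package implements an encoder–decoder network designed for
this setting and a SegNet baseline for comparison.

**Encoder.** Five blocks; blocks 1–2 hold two, blocks 3–5 three Conv–BN–ReLU
layers (3×3 kernels, stride 1, same padding; widths 64, 128, 256, 512, 512),
each block followed by a 2×2/stride-2 max pooling that records per-window
argmax positions. Ties break to the first position in row-major scan order.

**Decoder.** Five symmetric blocks, deepest first. Each block (i) restores
resolution by *max-unpooling*: every value is scattered back to the argmax
location recorded by the counterpart encoder pooling, zeros elsewhere; then
(ii) concatenates the counterpart encoder block's pre-pool feature map along
channels; then (iii) applies the mirror conv stack, whose last conv reduces
to the next level's width. The final conv of block 1 is a bare 3×3 conv to
the class logits (sigmoid at inference only). Skip features therefore arrive
at all five scales {1, ½, ¼, ⅛, 1/16} of the input; the bottleneck after
the fifth pooling is at 1/32. The SegNet baseline omits step (ii).

Skip fusion is **concatenation**, with the first conv of each decoder block
absorbing the doubled channels. Additive fusion would add no parameters and
could not produce the observed parameter-count gap between the two
networks; concatenation yields 34,935,169 (proposed) vs 29,442,433 (SegNet)
trainable scalars — conv weights and biases plus BN affine parameters —
i.e. 34 vs 29 truncated millions. Parameter totals are reported with
integer division by 10⁶ because truncation is the convention that makes
both printed values consistent with the same architecture.

One network is trained per target tissue (`num_classes=1`, sigmoid); a
multi-label head is a configuration option.

## NumPy training stack

No autodiff framework is used. Layers are channels-last `(N, H, W, C)`
float32 with hand-derived backward passes: convolution as nine shifted
BLAS matrix products (only the padded input is cached), standard batch-norm
backward, pooling/unpooling as scatter/gather along a per-window axis.
Gradients are verified against finite differences in the test suite (conv
weights and inputs, BN, pooling routing, and the loss gradient). A conv
bias that feeds directly into BN has exactly zero gradient (BN subtracts
the batch mean); such biases are retained for parameter-count parity but
are mathematically inert.

The optimizer is AdamW with decoupled weight decay
(`p ← p − lr·(m̂/(√v̂+ε) + λp)`), defaults lr 1e-3, weight decay 1e-4,
batch size 16, 50 epochs; after each epoch the validation loss is computed
with batch-aggregated soft counts, and the returned checkpoint is the epoch
of minimum validation loss (earliest on ties). There is no learning-rate
schedule or early stopping. Given equal seeds and single-threaded
execution, runs are bit-reproducible.

## Objective

Focal Tversky loss on sigmoid probabilities:
`TI = (Σpt + ε) / (Σpt + α·Σp(1−t) + β·Σ(1−p)t + ε)`, `loss = (1 − TI)^γ`,
with soft counts summed over the whole batch rather than averaged per image,
and ε = 1e-6 defining the empty-vs-empty limit (TI → 1, loss → 0). Defaults
α = 0.7, β = 0.3, γ = 4/3 follow the originating focal-Tversky formulation
(they weight false negatives harder, appropriate for thin structures); all
are configurable. With α = β = 0.5, γ = 1 the loss is exactly 1 − soft Dice,
which the tests assert to 1e-10.

## Preprocessing and splitting

VOI-LUT windowing maps HU to [0, 1] by the linear clamp
`y = clip((x − (center − width/2))/width, 0, 1)` with center 0, width 200.
The DICOM PS3.3 variant (width−1, center−0.5) is available as a switch; at
width 200 the two differ by under 1%.

Splits are 0.7/0.15/0.15 with `floor` rounding for train and validation and
the remainder to test — 701 ids give (490, 105, 106). Repetition r shuffles
with seed `base + r`, so each of the (default ten) repetitions is a
distinct, reproducible partition; all three subsets are resampled each
repetition. Within a repetition every compared model sees the identical
partition, which makes per-repetition test means paired across models.

## Evaluation and statistics

Probabilities are thresholded at 0.5 (ties to foreground); Dice and IoU are
computed from per-image confusion counts and averaged per image over the
test set (per-image rather than pooled-count aggregation). Empty-vs-empty
images score 1 by convention and are flagged degenerate; the phantom
generator never produces them. Model comparison: per (tissue, metric) the
model with the highest mean over repetitions anchors the block, and every
other model is tested against it with a classical two-sided paired t-test
on per-repetition means (df = n−1), significance flagged at p < 0.001.
Zero-variance differences are reported as degenerate (identical samples:
t = NaN, p = 1; constant non-zero shift: t = ±∞, p = 0) rather than
producing a spurious finite statistic.

## Synthetic phantoms

The generator renders the three annotated views as schematic geometry:

* **axial1** (eye level): two orbits, each an eyeball (sclera ring around a
  vitreous-valued interior disc — the eyeball *mask* is the interior),
  an optic nerve band running posteriorly, and medial/lateral rectus bands;
  a bony nasal septum and posterior skull base. Masks: eyeball,
  optic_nerve, MRM, LRM.
* **axial2** (superior): smaller globe cross-sections and a lacrimal-gland
  crescent supero-temporal to each globe (the only annotated tissue).
* **coronal** (retrobulbar): a bone ring, the optic nerve as a central
  disc, and the four rectus bands at compass positions. Masks:
  optic_nerve, MRM, LRM, SRM, IRM.

Pixel values are integers clipped to [−1024, 3071]; Gaussian noise
(default SD 8 HU, a typical soft-tissue CT noise level) is added before
rounding. Geometry jitters ±10% per item; masks are made pairwise disjoint
by construction. `enlargement_factor ≥ 1` multiplies muscle-band thickness
to emulate GO muscle enlargement and is monotone in mask area at fixed
seed. Item i of a dataset uses seed `base + i`, so items are independently
reproducible; images are written as 16-bit PNG storing HU + 1024, masks as
{0, 255} 8-bit PNG, tied together by a manifest CSV.

What the phantoms deliberately are **not**: anatomically realistic. Tissue
boundaries are analytic curves, HU distributions are unimodal, and there is
no partial-volume effect, beam hardening, patient variation in pose, or
annotation noise. Passing tests on phantoms therefore demonstrates that the
architecture, objective, metrics and protocol are implemented correctly and
that the skip-connected decoder has the expected qualitative advantage —
not that clinical-grade Dice values are attainable; those depend on real
data this package does not ship.

## Problem sizes used in tests and the acceptance script

The full-width networks (34M/29M parameters) are built and counted but not
trained in the suite; training runs use narrow widths (8, 16, 32, 64, 64)
at 64×64 phantoms (both divisible by 2⁵, preserving all five pooling
levels), which keeps a pure-NumPy run on one CPU core to minutes:

* overfit property: 8 eyeball phantoms, batch 16 (one step per epoch),
  200 steps — train Dice ≥ 0.95 (observed ≈ 1.00);
* ordering property: 60 phantoms, 3 repetitions, 15 epochs — proposed mean
  Dice ≥ SegNet mean Dice on the medial rectus band. Three repetitions
  establish the direction, not p < 0.001 significance.

These are scaled-down study conditions chosen once as the package's own
test sizes; the thresholds and directions asserted are unchanged by the
scaling.

## Known limitations

* 2D single-slice segmentation only; no 3D context.
* The hand-rolled stack is CPU-bound; full-width 512×512 training is out of
  practical reach without a GPU framework, so defaults that matter for
  accounting (widths, kernel sizes) are exercised structurally rather than
  by full-scale training.
* Focal-Tversky hyperparameters are declared defaults, not values fitted to
  clinical data.
* DICOM support is read-only (RescaleSlope/Intercept honored); no DICOM
  writing.
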