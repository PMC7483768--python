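# Methods

`cribnet` detects the cribriform growth pattern — a Gleason grade 4
architecture in which a confluent epithelial mass is perforated by multiple
gland lumina — in H&E-stained prostate needle-biopsy images. This note
documents the model, the numerical choices, the synthetic data the package
trains and validates on, and what the tests do and do not establish.

## The detection model

**Classes.** Seven tissue labels: `non-labelled` (background, stroma, benign
and rare patterns), `G3`, and the five G4 growth patterns (`fused`,
`ill-defined`, `complex fused`, `glomeruloid`, `cribriform`). Only the
cribriform channel is evaluated; the other classes are auxiliary training
targets that sharpen the decision boundary between cribriform tissue and its
morphological neighbours.

**Network.** A coarse-output segmentation CNN: `n_blocks` residual
convolution blocks, each two 3x3 convolutions with batch normalization, a
squeeze-and-excitation (SE) channel-attention unit and an additive shortcut
(1x1 projection where the channel count changes); between consecutive blocks
a learned 2x2 stride-2 downsampling convolution followed by BN and ReLU; a
final 1x1 projection to 7 channels and a channel softmax. With `n_blocks`
blocks the output grid is `2^(n_blocks-1)` times coarser than the input: the
full-scale configuration (6 blocks, 1024-px patches at 0.92 um/px) emits
32x32 probability maps, one output pixel per 29.44 um. Reference masks are
average-pooled by the same factor, giving soft per-cell class fractions that
sum to 1.

Feature widths double per block from `base_features`. The width, SE
reduction ratio and initialization scale are configuration, not constants;
the engine defaults to fan-in-scaled uniform initialization
(U(+-sqrt(6/fan_in))).

**Loss.** Training minimizes the negative class-weighted soft Dice of a
batch of P patches:

    L_D = -(1/P) * sum_p sum_l w_l * [ 2 sum_i y yhat / (sum_i (y + yhat) + eps) ]

with w_cribriform = 0.4 and 0.1 for the six other classes (weights sum
to 1), and eps = 1e-5 guarding only the denominator (the formula is applied
literally: a class absent from both reference and prediction contributes 0,
not a perfect score). Checkpoints are compared on a validation set with

    V = alpha * L_D + (1 - alpha) * L_S,

where L_S is the negative mean pixel specificity with the same class
weights; V(alpha=1) is identically the Dice loss. Low alpha favours
specific (false-positive-averse) checkpoints.

**Optimization.** Plain SGD, learning rate 0.01, momentum 0.99, batch size 7
(one patch per label pool, so every batch contains all seven labels), no
stopping criterion; checkpoints every `checkpoint_interval` iterations and
selection by V afterwards. The `decay` of 5e-4 is applied to the learning
rate per iteration, `lr_t = lr / (1 + decay * t)`; this follows the Keras
SGD semantics of the original implementation environment. A flag switches to
L2 weight decay instead.

**Augmentation.** Per draw: independent vertical/horizontal flips (p = 0.5
each), rotation up to +-5 degrees, scaling in [0.9, 1.1], translation up to
+-10% of the patch size (in that order, about the patch centre; bilinear for
the image, nearest for the label map, background-white / non-labelled fill),
then photometric changes on the image only: per-channel intensity shift
+-0.05 and a linear rescale of the full intensity range onto
[lo in [0, 0.1], hi in [0.9, 1]].

**Ensembles.** Members differ in training order (seed) and in the alpha used
for checkpoint selection (alphas {0.2, 0.3, 0.4, 1}); the ensemble
prediction is the arithmetic mean of member probability maps, which remains
normalized. The full-scale scheme is 4 repeats x 4 alphas = 16 members per
fold; the desk-scale study uses 1 repeat x 4 alphas = 4 members.

**Fold assignment.** Cross-validation folds are packed in two passes:
biopsies containing cribriform regions first, in decreasing cribriform
region count, each into the currently lightest fold (first-fit decreasing);
then the remaining biopsies, each into the fold minimizing the summed
squared deviation of per-fold per-label region counts from uniform targets
(with a small tie-break toward emptier folds; all residual ties go to the
lowest fold index). The exact bin-packing variant is a design choice made
for determinism; on the reference instance {5,4,3,2,1,1} into 3 folds it
reaches the exhaustive optimum (max load 6).

## Preprocessing and reassembly

Background is identified per pixel through the optical density
`OD_c = -log10(I_c / I_max)`: a pixel is background when OD_c < 0.12 in
*any* channel. I_max defaults to the per-image, per-channel maximum
(configurable to 255). "Any" is the literal reading of the rule; because a
strongly eosinophilic pixel can be bright in red only, an "all channels"
mode is available behind a flag. Zero intensities are clamped to one 8-bit
unit before the log. Comparisons are strict (`<` for background, `>` for
the patch discard fraction).

Biopsies are padded with background white by patch/4 on all sides (then to
the stride grid), subdivided into half-overlapping patches, and patches with
more than 99.5% background are discarded. At prediction time only the
central half-size window of each patch's output is kept; these windows tile
the padded biopsy exactly once, and the padding guarantees every tissue
pixel falls in some centre window. Discarded (all-background) patches
contribute a non-labelled one-hot fill to the reassembled map. The output is
cropped back to the unpadded extent.

## Evaluation

Cribriform pixels (probability strictly greater than a cut-off) are grouped
into 8-connected regions (4-connectivity optional) on the output grid;
regions can be filtered by physical area, strictly larger than a minimum
(the full-scale study uses 0.0150 mm^2 = 17.3 output pixels, chosen below
the smallest annotated cribriform region of 0.0155 mm^2; an 18-pixel region
passes, a 17-pixel region does not).

* **Biopsy-wise ROC** — reference-positive if the biopsy has >= 1 cribriform
  annotation; prediction-positive at cut-off c if >= 1 qualifying region
  exists. Because qualification is monotone in the cut-off, each biopsy
  reduces to a scalar qualifying score (found by binary search over the
  unique probabilities) and the sweep to a ranking; AUC by the trapezoid
  rule, equal to the tie-aware Mann-Whitney statistic.
* **Annotation-wise FROC** — an annotated region counts as detected when at
  least one predicted-region pixel overlaps it; false positives are
  predicted regions overlapping no cribriform annotation, reported per
  biopsy. Annotations are pooled to the output grid; a cell is annotated
  when its pooled cribriform fraction is positive.
* **Contour-restricted decisions** — for delineated-region use, predictions
  outside the contour are discarded and the image is called cribriform iff
  any in-contour output pixel exceeds the cut-off (reference cut-offs
  0.0125 / 0.1 / 0.5).
* **Cohen's kappa** with marginal-product chance agreement quantifies rater
  agreement; the degenerate case p_e = 1 is defined as 1.

A caveat found while testing: the FROC false-positive count is *not*
globally monotone in the cut-off — lowering the cut-off can merge several
false-positive regions into one, or merge a false positive into a detected
region. Sensitivity is monotone (regions nest), and the FP count is monotone
whenever regions do not merge across the sweep; the property tests assert
exactly that. Relatedly, at near-zero cut-offs all tissue merges into a
single region per biopsy, which makes "sensitivity at low FP/biopsy"
trivially attainable; the end-to-end checks therefore only consider
operating points with cut-off >= 0.05.

## Synthetic data

The generator emits an elongated, wavy tissue strip (needle-biopsy
geometry) on a near-white background and places non-overlapping gland
archetypes inside it. Each archetype is a geometric caricature:

| archetype | rendering |
|---|---|
| G3 | small gland, single round central lumen, thin epithelial ring |
| fused | elongated mass with a chain of 2-4 medium lumina |
| ill-defined | diffuse, partially transparent epithelium, no lumina |
| complex fused | large branched mass with irregular elongated slit lumina |
| glomeruloid | one large lumen containing a wall-attached tuft |
| cribriform | one epithelial blob perforated by >= 3 small round lumina |

Design rules: the epithelial palette, nuclear density and noise are shared
across gland classes, so mean colour carries no class signal (asserted: the
mean epithelial RGB of cribriform vs fused regions differs by less than the
noise amplitude) and a classifier must use morphology. Nuclei are
anti-aliased ellipses with jittered size and orientation; texture is
Gaussian-filtered white noise. Tissue colours are kept dark enough that the
OD < 0.12 background rule recovers the strip (>= 99% of non-tissue pixels
read as background; lumina intentionally read as background, mirroring real
gland lumina). Every placed archetype contributes one polygon annotation
(48-vertex radial-jitter blob outline), and the returned masks are produced
by rasterizing exactly those polygons, so mask/annotation agreement is exact
by construction.

Abundances are study conditions: biopsies emulate tumor-dense needle cores
(the motivating cohort selected, per patient, the biopsy with the most
tumor volume, containing mainly G3/G4 carcinoma), so glands pack a large
share of the strip; cribriform archetypes appear in ~35% of biopsies
(allocated exactly per dataset, matching the cohort's 45/128 prevalence),
the other patterns in 70-100% of biopsies with 1-7 glands each. Canvases
are 2048x6144 px at 0.92 um/px (full) or 512x1536 px (desk); glands are
18-55 um in radius at desk scale so that several fit a 470-um-wide strip.
The class-defining morphological contrast lives at the lumina scale:
cribriform glands carry 6-10 small round perforations, fused glands a chain
of fewer, markedly larger lumina, complex-fused masses elongated slits.

What the synthetic data does *not* emulate: stain physics and scanner
artefacts, nuclear atypia, stromal reaction, tissue tears and retraction
artefacts, G5/mucinous/perineural mimickers (all folded into generic
non-labelled texture), and the annotation noise of human raters. Passing
tests therefore demonstrate that the pipeline is implemented correctly and
can learn morphological class distinctions end to end — not that the
trained weights transfer to clinical material.

## Desk-scale study and problem sizes

The package's own evaluation study (also run by `scripts/acceptance.py`)
uses the desk profile: 512x1536 canvases, 256-px patches with stride 128, a
3-block network (widths 4/8/16, SE reduction 4, output 64x64 at 3.68 um/px),
2000 SGD iterations, batch 7, checkpoints every 500 iterations, a 4-member
ensemble (1 repeat x alphas {0.2, 0.3, 0.4, 1}), 50 training, 8 validation
and 10 held-out test biopsies with independently allocated prevalence.
These sizes were chosen so the whole study trains in roughly ten minutes on
a single CPU core while keeping every mechanism of the full-scale design
(the full profile — 6 blocks, 1024-px patches, 60000 iterations, 16-member
ensembles, 8-fold cross-validation — is configuration, not separate code).
The minimum-area filter transfers to desk scale by the same rule that fixed
the full-scale value (just below the smallest cribriform region: 0.0150
< 0.0155 mm^2 at full scale): desk cribriform archetypes are >= 0.0045 mm^2,
so the desk filter is 0.0040 mm^2. The full-scale filter's exact boundary
semantics (an 18-output-pixel region passes, 17 does not) are verified by a
dedicated unit test.

Two optimization dynamics observed at this scale are worth knowing about.
First, the Dice loss initially collapses the softmax onto the dominant
non-labelled class; rare-class gradients then scale with their near-zero
probabilities and recovery is slow. Tumor-dense biopsies and label pools
that require meaningful class presence (a gland class only counts as
"contained" in a patch covering >= 1% of it) shorten this phase
substantially; a wider network helps too but does not fit the single-core
budget. Second, an under-trained network fires confidently on the lumina
rings of non-cribriform glands; these false regions are far smaller than a
cribriform gland, which is precisely what the minimum-area filter removes.

## Numerical choices

* The CNN engine is written on numpy with numba kernels for the 3x3 and
  2x2-stride-2 convolutions (channels-first, fused row passes; ~10 GFLOP/s
  single-core). Gradients are analytic and verified against central finite
  differences in float64 (tolerance 1e-4 relative).
* BatchNorm uses eps 1e-5, running-statistics momentum 0.9, float32
  statistics with float64 running accumulators; inference always uses
  running statistics (deterministic).
* The loss runs in the dtype of the prediction (float32 during training)
  with float64 accumulation for the scalar; oracle tests use float64
  throughout.
* Rasterization convention: 0-based (row, col), pixel centres at integers,
  boundary pixels included (`shapely.covers` on pixel centres). Overlapping
  annotations resolve last-drawn-wins with a logged warning.
* All randomness flows from integer seeds through `numpy` `SeedSequence`
  substreams (batching, augmentation, per-biopsy generation, ensemble
  repeats are independent streams); reruns are bit-identical, and the CLI
  chain embeds a configuration hash in every artifact.
* Ties in checkpoint selection go to the earliest checkpoint; ties in fold
  packing to the lowest fold index.

## Known limitations

* The desk-scale network is small; its receptive field (~60 um) suffices
  for the synthetic caricatures but not necessarily for real glands.
* Specificity-weighted selection (alpha <= 0.4) can prefer the untrained
  initial checkpoint early in training, because an untrained network is
  highly specific; with enough iterations the Dice term dominates. This
  mirrors the intended behaviour of V but makes very short runs degenerate.
* The whole-slide (NDPI) reading path is out of scope; real images must be
  supplied as PNG/TIFF at (or resampled to) the working resolution, for
  which an area-averaging factor-4 downsampler is provided.
* `biopsy_roc` requires at least one positive and one negative biopsy; AUC
  is undefined otherwise and the CLI reports null.
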