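# Methods

`endoseg` estimates the three corneal endothelial biomarkers — cell density
(ECD, cells/mm²), polymegethism (CV, %), and pleomorphism/hexagonality
(HEX, %) — from specular microscopy images of the corneal endothelium, with
particular attention to images degraded by guttae (near-black droplets that
occlude cells). This note records the models and procedures implemented,
the design choices made where the design was genuinely open, and what the
synthetic phantoms do and do not establish.

## Annotations and training targets

A manual annotation is a trinary image: 0 = cell body, 1 = cell edge
(8-connected 1-px curves), 0.5 = area to discard (extensive guttae, heavy
blur, partial cells). Four per-pixel training targets derive from it:

* **edge** — the binary edge mask convolved with a 7×7 *unnormalized*
  isotropic Gaussian (SD 1 px, peak 1), clipped to [0, 1]. An annotated
  edge pixel keeps value 1 exactly; an isolated one decays as
  exp(−(Δr² + Δc²)/2).
* **body** — the *full* cell bodies only (0-regions neither touching the
  image border nor 8-adjacent to a discard pixel), same Gaussian + clip.
  Where overlapping kernels would exceed 1 the value clips; targets remain
  interpretable as per-pixel class probabilities for cross-entropy.
* **blob** — full bodies united with the edge pixels whose 8-neighborhood
  touches at least two full bodies, same transformation.
* **roi** — a binary trustworthy-region map: the complement of the discard
  mask with partial cells removed. No blurring.

The Gaussian transformation is applied to the full mask interior (an
alternative would blur only a boundary band); after clipping the two differ
only within ~3 px of region boundaries.

Guttae/blur complexity grading: each factor scores 1 (mild), 2 (moderate)
or 3 (severe); the grade is the sum, binned low (≤2), medium (3–4), high
(5–6). A grade of 1 cannot arise from two ≥1 scores; the low bin therefore
effectively contains grade 2.

## Network: DenseUNet with feedback non-local attention

The backbone has five resolution stages with dense nodes of 4, 8, 12, 16,
20 convolutional blocks (growth rate GR = 5; 4 in the multiscale
variants). A convolutional block is Conv(1×1, 4·GR) + batch-renorm + ELU
(compression), Conv(3×3, GR) + BRN + ELU (growth), dropout 20%, then
concatenation with the block input. The network's very first block has no
compression and full-resolution nodes use no dropout. Transitions are
Conv(1×1, α), down/upsampling Conv/ConvTranspose(2×2, stride 2, α), with
α = (blocks in the previous dense node)·GR/2. The decoder mirrors the
encoder block counts; the head is a 1×1 transition to two maps with
per-pixel softmax. The `plus`/`plusplus` variants fill the triangle of
intermediate nodes X^{a,b} (a + b ≤ 4); each node owns a single transition
convolution, and `plusplus` aggregates all previous transitions of its row
by feature addition (hence identical parameter counts for the two
variants).

**Attention.** Each node attends on the output of the node one resolution
stage deeper in the same column when it exists (*feedback* non-local
attention, fNLA: keys/values arrive through 2×2 transpose convolutions),
and on itself otherwise (*self* attention, sNLA: 1×1 convolutions) — so in
the basic network the encoder uses fNLA except the deepest node, and the
deepest node and all decoder nodes use sNLA. Queries/keys/values are
projected to ⌊C/8⌋ (min 1) channels; attention is scaled dot-product with
row-wise softmax over all spatial positions (scale 1/√(C/8)). Aggregation
is multiplicative (1×1 conv to one map, sigmoid gate multiplied onto the
input), concatenative (ELU, concatenated: C + C/8 channels), or additive
(1×1 conv to C maps, ReLU, residual sum). The attention is computed in row
chunks so the N×N position matrix is never materialized; memory stays
linear in N.

**Parameter accounting.** Convolutions count weights + biases. A
batch-renorm layer carries 2 trainable parameters per channel (scale,
shift) plus 3 tracked statistics (moving mean, variance, stddev);
`ModelGraph` reports trainable and total counts separately. The total
count is what framework model summaries print, and reproduces the
published sizes of the nine DenseUNet family variants to two decimal
millions.

**Execution.** The graph is interpreted by a NumPy engine (im2col/BLAS
convolutions, manual reverse-mode pass, Nadam optimizer with Nesterov
momentum). Normalization uses batch statistics during training and the
tracked statistics at inference; any normalization with the same trainable
parameter count is interchangeable for size parity.

## Training contract

Categorical cross-entropy on the two softmax maps against soft targets
(p, 1−p); Nadam with lr₀ = 0.001 decaying geometrically per epoch (decay
0.99 over 200 epochs for the edge task; 0.97 over 100 for body/blob/roi).
Batches hold 15 images, of which six come from the guttae subgroups — two
per complexity bin (low/medium/high); the remaining nine are drawn
uniformly without replacement from the rest of the pool (the stated rule
covers only the quota). A bin with too few images falls back to sampling
with replacement, logged. Cross-validation folds are dealt round-robin
over shuffled eyes so all images of an eye share a fold. Augmentation
applies identical left-right/up-down flips (p = ½ each) and an elastic
deformation (8×8 control-point grid, displacement SD 10 px, bilinear
upsampling — grid size and magnitude are package defaults, chosen at the
scale of one cell) to image and target. Intensities are normalized to
[0, 1]. There is no early stopping on the loss; an optional convergence
cutoff (`target_dice`) exists for smoke runs and is off by default.

## Postprocessing (steps I–VII)

1. **Cell size** `l`: inverse of the dominant radial spatial frequency of
   the mean-subtracted edge image (radially averaged power spectrum,
   Gaussian-smoothed with σ = 2 bins, peak within the 5–100 px band,
   parabolic sub-bin refinement).
2. **Perimeter**: a 1-px border of intensity 0.5 closes cells cut by the
   frame.
3. **Smoothing**: Gaussian with σ = 0.2·l bridges small edge gaps.
4. **Watershed**: flooding from the regional minima of the smoothed
   surface, 4-connected, producing superpixels separated by 1-px
   8-connected ridges. Three guards make the frame behave deterministically:
   the frame ring floods as auxiliary arc basins, one per arc of the ring
   broken wherever a strong edge *crosses* it (edge ≥ 0.5 both on the ring
   and 2 px inward) — partial cells squeezed too thin to retain a minimum
   then still separate from their full inner neighbor; ring pixels annexed
   by interior regions become ridge; pinched-off fragments under 4 px
   (below any resolvable cell) are absorbed into the ridge. Watershed
   lines are thinned where a junction rasterizes 2 px wide.
5. **Graph pruning**: vertices are the ridge branch points (≥3 ridge
   neighbors; never on the frame ring itself), edges the 8-connected
   chains between them; 1-px chains fuse with their end vertices. Each
   chain carries its mean intensity in the *original* edge image. Internal
   chains below the edge threshold (0.1) are removed whole (their regions
   merge; orphaned vertices dissolve on the next pass); chains in contact
   with the border or non-ROI area (any pixel on or 8-adjacent to it) lose
   only their middle pixels — the two pixels nearest each end vertex stay,
   or for chains under 5 px all but the single middle pixel — preserving
   the vertices that carry HEX. Chains lying on the frame ring are never
   pruned. The graph is rebuilt after every pass until stable, which makes
   pruning idempotent.
6. **Selection**: superpixels touching the image border are unselected;
   the rest are selected when their mean body/blob intensity exceeds the
   body threshold (0.5; 0.75 is a documented alternative for attention
   networks) or, in ROI mode, when ≥85% of their area lies in the ROI.
   Nothing is deleted.
7. **Biomarkers** on the selected cells.

## Biomarkers

ECD = n / (Σ areas · pixel_size²), areas in px² excluding ridge pixels
(shared edge pixels are not apportioned; the bias is under one ridge-pixel
band per cell). CV = 100 · sample SD / mean of areas (n−1 denominator).
HEX by the vertex method = percentage of selected cells with exactly six
vertices (vertices counted as distinct branch-point clusters 8-adjacent to
the cell); the neighbor method counts inner cells (all neighbors selected)
with six neighboring cells and necessarily discards the periphery. Default
pixel size 1/960 mm/px (0.25 mm × 0.55 mm field at 240 × 528 px),
overridable. Zero selected cells yield an explicit "no estimate", never
zeros.

## Synthetic phantoms

Phantoms emulate the geometry and photometry the pipeline must handle:
nuclei on a hexagonal lattice jittered by (1 − regularity)·0.18·a; cell
areas following a lognormal law (CV² = exp(σ²) − 1) imposed by a
capacity-calibrated power diagram (additive weights iterated 80 × with
gain 0.2; border/margin cells exempt — the frame truncates them); guttae as
discs (lognormal radii, optional confluence clustering) that are marked
discard when wider than the mean cell diameter and keep their annotated
edges otherwise; per-cell brightness 0.55–0.85, dark edges, near-black
guttae; spatially varying blur (smooth random mixing field toward a
σ = 3 px blurred copy) and additive Gaussian noise. Rasterization floods
the negative distance-to-boundary transform seeded at each region's
interior maximum — exact for weighted diagrams, whose cells need not
contain their own nucleus — and the capacity targets compensate the ~17 +
0.78·√A px that the 1-px boundary line takes from a cell, so *measured*
areas realize the stated lognormal. Truth biomarkers come from the
generating tessellation: countable cells have no pixel on the frame ring
and no overlap with discard guttae; vertex counts equal adjacency degree
computed on a padded canvas (so neighbors beyond the frame still count).

What phantoms do not model: optical specular artifacts, intensity
vignetting, annotation error, and realistic pleomorphism (the jittered
lattice stays mostly 6-neighbored, so phantom HEX is high). Pipeline
results on phantoms therefore validate the geometry/recovery machinery,
not clinical accuracy.

## Verified behavior at desk scale

The test suite and `scripts/acceptance.py` recompute, among others: the
nine published DenseUNet-family parameter counts (±0.005 M); exact cell
counts, ECD within 2%, CV within 3 points and HEX exactly 100% on noiseless
regularity-1 phantoms of ~200 cells; agreement of DICE/MHD with brute-force
implementations; the geometric learning-rate schedule and the ln 2
cross-entropy of the uniform predictor; recovery of a known exponential
error-spread (a, b within 15% at 500 points); and convergence of the
fNLA-Mul DenseUNet to training DICE > 0.8 on four 96×96 phantom crops
within a handful of epochs on one CPU.

## Known limitations

* On arbitrary phantom seeds a rare frame-side configuration (a weak
  watershed chain merging a full cell with a partial compartment) can
  dilute one cell's body mean below 0.5 and drop it from the count (~0.5%
  of cells); the pinned study conditions recover counts exactly.
* At area σ > 0 a wall can rasterize to a single pixel; the 1-px-edge
  fusion rule then merges its two junctions into one vertex, so
  vertex-method HEX deviates slightly from the adjacency-derived truth on
  non-uniform lattices.
* Full-resolution attention is O(N²) in spatial positions; native-size
  (240×528) forward passes are feasible but slow on CPU, and training at
  native scale is out of scope.
* The UNet/ResUNeXt baselines of the comparison family are not
  reproduced; their channel widths are unpublished.
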