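# Methods

## Data model

All volumes are numpy arrays indexed `(z, y, x)` with physical voxel edge
lengths attached in nanometres. Two spacing regimes matter: anisotropic
serial-section stacks (fine in-plane sampling, ~25× coarser section
thickness, e.g. 50 × 2 × 2 nm) and isotropic milled volumes (e.g.
5 × 5 × 5 nm). Morphometric outputs convert to μm³/μm²/μm through the
spacing; nothing downstream assumes isotropy.

## Pre-processing

Serial-section stacks show slice-to-slice brightness drift (beam
instability, uneven section surfaces). We apply classic CDF-based global
histogram equalization independently per z-slice with 256 bins:
`map(v) = round((cdf(v) − cdf_min)/(N − cdf_min) · 255)`. Per-slice scope is
the deliberate choice — the defect being corrected is *inter*-slice
variation, so two slices with identical content but different offsets must
equalize identically. Adaptive/CLAHE variants were rejected as they alter
local contrast that the network should see. The mapping is monotone within
a slice, leaves constant slices untouched, and is idempotent up to one gray
level. Scope and bin count are configurable.

## Network

An asymmetric encoder–decoder ("variant U-Net") of residual blocks, built
in pure numpy with a small reverse-mode autodiff tape (`mito3d._nn`)
providing 3D convolution, batch normalisation, ELU, max pooling, nearest
upsampling and a fused softmax cross-entropy, plus Adam. float64 arithmetic
throughout; gradients verified against central finite differences to 1e-4.

Layout (default widths 10/20/40/80 over four resolution levels):

* contracting path: one 3×3×3 stem convolution, then residual blocks per
  level (1, 1, 2, 2) — each block is exactly two 3×3×3 convolutions with an
  identity shortcut — for 13 convolutions total. Where a block widens the
  channel count the shortcut is the input zero-padded along channels
  (parameter-free), so the census is unaffected.
* expansive path: three upsampling stages. The two deepest use
  nearest-neighbour resize followed by a 3×3×3 transition convolution that
  halves the channels; the shallowest reduces channels by slicing
  (parameter-free). Each stage adds the same-level encoder features
  (summation skip) and applies two residual blocks; a 1×1×1 softmax
  classifier ends the path: 12 + 2 + 1 = 15 convolutions.
* every convolution is followed by batch normalisation and ELU; residual
  addition happens before the block's final activation (post-addition
  activation; the alternative ordering is not observably different at this
  scale and the choice is recorded here once).
* pooling/upsampling strides default to (1, 2, 2) — in-plane only — so the
  z-extent of every internal feature map equals the input z-extent,
  preserving the scarce axial resolution of anisotropic stacks. The
  isotropic preset switches the two coarsest transitions to (2, 2, 2).

The default configuration carries 1,115,486 trainable parameters. Exact
channel widths are not uniquely determined by the published description;
the constraint honoured here is the 13/15 convolution census together with
a ≈1.1 M parameter total, and the widths are exposed in `NetworkConfig`.

### Deep supervision and loss

Auxiliary softmax classifiers attach after the residual blocks of the two
coarsest decoder stages, reached through nearest-neighbour upsampling to
full resolution; weights are 0.15 for the deeper head and 0.30 for the
shallower. The training objective is

    L = CE(main) + Σ_c ω_c · CE(aux_c) + (λ/2)(‖W‖² + Σ_c ‖W_c‖²)

where CE is cross-entropy over the foreground/background label sets,
reduced as the **mean over voxels** (the mean keeps the loss scale
patch-size-invariant; the published sums are unnormalised, which only
rescales λ and the learning rate). λ defaults to 1e-4 (no published value);
the L2 term runs over all trainable parameters. At inference the auxiliary
heads are discarded. Upsampling is nearest-resize followed by convolution
rather than transposed convolution — the two are not distinguished in the
published description and resize-conv avoids checkerboard artifacts.

## Training

Adam with lr 1e-4, β₁ 0.9, β₂ 0.999, ε 1e-8; batch size 2; 30 epochs; plain
(unweighted) binary cross-entropy; no learning-rate schedule; full shuffled
epochs over all patches. Patches default to 256×256×8 tiled z-major with
the final patch per axis shifted flush to the boundary (no zero padding of
training data; boundary patches may overlap their neighbours). With
augmentation every base patch appears under all 16 combinations of
{−90°, 0°, +90°, 180°} in-plane rotation × xy-flip × z-flip — index
permutations only, labels never resampled. At full scale this regime yields
> 6,000 training samples per stack. A configurable held-out fraction
(default 10 % of patches) is available for validation. Checkpoints are
single `.npz` archives containing all parameters, batch-norm running
statistics and the JSON-serialised configuration.

## Inference

Whole volumes are predicted on overlapping tiles blended by plain
unweighted averaging (no window weighting), with the last tile per axis
flush to the boundary. Published tile regimes are provided as constants:
1152×1152×8 with 256/5-voxel overlaps (anisotropic) and 448×576×20 with
128/10 (isotropic). Test-time augmentation transforms the volume by each
element of the 16-group (or the 8-subgroup without z-flips — the composition
of the published "aug8" variant is not spelled out; the z-flip-free subgroup
is this package's reading), predicts, inverse-transforms the map, and
averages. ±90° rotations of non-square volumes are handled by actually
rotating the array (axes swap) and swapping tile dimensions — exactly
equivalent to pad-and-crop, with no wasted computation. Binarization is
p ≥ 0.5 by default (no published cutoff).

## 3D connection

For every pair of 2D components in adjacent slices the IoU of their xy
footprints is computed; a link is created iff IoU ≥ T (default 0.1), and
instances are connected components of the link graph via union-find. One
component may link to several partners, so branching organelles remain
single instances. "Discarding components with IoU < T" is implemented as
discarding the *link*, not the component — deleting components would remove
valid single-slice-pair mitochondria. In-plane connectivity defaults to
8-connected (4-connected available). The partition refines monotonically as
T grows, and at T → 0⁺ it equals the transitive closure of "footprints
overlap", which is a refinement of 26-connected labeling (26-connectivity
can also join diagonally adjacent voxels with zero footprint overlap).
Detected instances under 1,500 voxels are removed before detection
evaluation only — the filter is a detection-stage denoiser, not part of
pixel-level scoring.

## Evaluation

Pixel level: Jaccard, Dice, conformity, with the identities
D = 2J/(1+J) and C = 2 − 1/J holding to 1e-12. Conformity at J = 0 is
reported as a −∞ sentinel with a `conformity_defined` flag, never a number.
Instance level: candidate (prediction, truth) pairs are those with non-zero
intersection, scored by IoU (a ground-truth-coverage variant |P∩G|/|G| is
selectable — the published 70 % criterion does not specify the functional;
IoU is the default for consistency with the linking step). Greedy
one-to-one matching in descending overlap prevents one prediction counting
as several true positives; matched pairs with overlap ≥ τ (default 0.70)
are TPs. The matching order is independent of τ, which makes F1
non-increasing in τ by construction. A sweep over τ ∈ {0.65…0.85} reports
stability.

## Morphometry

* **Volume**: voxel count × voxel volume (nm³ → μm³).
* **Surface area**: triangulated isosurface at the 0.5 level of the
  instance mask with voxel spacing applied. The binary mask is smoothed
  with a σ = 0.5-voxel gaussian before marching cubes: the raw 0/1
  staircase overestimates curved surfaces by ~9 %, heavy smoothing rounds
  genuinely sharp corners, and σ = 0.5 keeps both biases under ~5 %
  (digitized spheres at 10 nm: ≤ 5 %; axis-aligned cubes: ≤ 5 %). Instances
  too small to survive smoothing fall back to their scaled bounding-box
  surface. Counting exposed voxel faces was rejected outright — it
  overestimates curved surfaces by up to ~50 %.
* **Length/width**: peak-to-peak extents of the spacing-scaled voxel-centre
  cloud projected on its first two principal axes, plus one mean voxel edge
  (digitization correction). The covariance gets a `spacing²/12` diagonal
  term — each voxel is a box, not a point — so one-voxel-thick plates keep
  a strictly positive minor axis.
* **Flatness**: √(λ₃/λ₂), the ratio of minor to middle principal standard
  deviations — near 0 for pancake-like objects, 1 for circular
  cross-sections. √(λ₃/λ₁) is selectable.
* **Summaries**: count, number density (count / analyzed μm³), mean ± sd
  per field. Surface/volume is summarised as the mean of per-instance
  ratios, not the ratio of means (the two differ; the per-instance mean is
  the biologically interpretable one and the choice is recorded here).

Degenerate instances (< 4 voxels, or rank-deficient clouds) are flagged
rather than dropped. For external 3D viewing, per-instance isosurface
meshes can be exported as plain-text Wavefront OBJ (μm coordinates), using
the same smoothed marching-cubes surface as the area estimator.

## Synthetic data

The generator emulates the *statistical structure* of EM data, not its
photorealism: bright textured cytoplasm (smoothed gaussian field), dark
organelle membranes (outer in-plane shell, ~30 nm), mid-gray interiors,
per-slice brightness jitter, additive gaussian noise, 8-bit quantisation.
Geometry (ellipsoids, straight/bent/branched capsule tubes) is specified in
μm, placed by rejection sampling with an in-plane separation margin and
fully inside the volume, then rasterized through the spacing — so analytic
volumes are exact oracles (rasterization error < 1 % at default sizes, 3 %
asserted in tests). Default scenes are 20 × 128 × 128 voxels at
30 × 10 × 10 nm with 3–6 objects of 0.06–0.11 μm radius — scaled-down
relatives of real mitochondria (0.5–10 μm) so that desk-size volumes hold
several well-separated instances. Degradations (in-plane erosion/dilation,
z-splitting, whole-instance drops) produce controlled imperfect predictions
for exercising the evaluation and connection stages.

What passing tests on this generator do **not** show: robustness to
registration failures, wrinkles and charging artifacts, membrane-adjacent
organelle confusion (ER, lysosomes), or the texture statistics of real
tissue. They do validate every algorithmic contract: geometry and unit
handling, the linking algorithm, the metric definitions, and that the
network can learn and generalise the membrane/interior intensity cue.

## Scaled-down recovery experiment

`mito3d.experiments.scaled_recovery_experiment` trains the two-level,
8-channel network variant (21 k parameters) on one synthetic 64 × 64 × 16
stack (8 × 32 × 32 patches, full 16× augmentation, batch 4, six epochs) and
evaluates on a held-out stack from identical generator conditions. The
learning rate is 1e-3 — scaled up from the full-size 1e-4 to suit the tiny
model and short schedule — and the detection-stage minimum size is 100
voxels, the analogue of the full pipeline's 1,500-voxel filter at these
scene sizes. Typical results: held-out Jaccard ≈ 0.95 single-pass, with
TTA-16 within ±0.02, and perfect instance detection at the 70 % criterion.
The experiment (and everything else) derives all randomness from a single
seed; with single-threaded numpy the results are bit-reproducible.

## Numerical and degenerate-input conventions

* Probability maps are softmax outputs; per-voxel class probabilities sum
  to 1 within 1e-5 in float64.
* Pooling requires spatial extents divisible by the cumulative strides;
  violations raise an error naming the axis.
* Both-empty masks make segmentation scores undefined (error), zero
  predicted or truth instances make precision/recall undefined (error) —
  never silent NaNs.
* Tiled blending divides by the per-voxel cover count; means of values in
  [0, 1] stay in [0, 1].
* Tie-breaks: slice-component labels are ordered by row-major first pixel;
  instance ids are compacted in first-voxel scan order; greedy matching
  breaks overlap ties by (prediction id, truth id).

## Known limitations

The numpy network trains at desk scale only (minutes for the tiny variant;
the full 1.1 M-parameter model builds and runs but is impractical to train
here). Tiled inference holds the whole output map in memory. The pipeline
accepts pre-registered stacks; serial-section registration is upstream and
out of scope. Full-dataset benchmark scores require the external EM volumes
and GPU-scale training and are deliberately not claimed.
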