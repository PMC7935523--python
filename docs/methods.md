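# Methods

## The question the pipeline operationalizes

Convolutional classifiers can separate two shape categories either from
*local* evidence — edge orientations, corner angles, whether neighboring
sides are parallel — or from *global* properties of the whole figure that
survive continuous deformation: the presence of a hole, the connectivity of
the figure's parts, or whether one object lies inside another.  The pipeline
measures which kind of evidence a classifier actually extracted by training
it on one category pair and then scoring it, without any further training,
on a second pair that shares only the feature of interest.  Strong
performance on the never-seen pair indicates the shared feature was learned;
chance performance indicates the classifier keyed on something else.

## Stimulus generation

All stimuli are built as exact vector geometry first and rasterized second,
so every category-defining predicate can be verified on coordinates before
any pixel exists.

**Categories.** Twenty-four categories cover four quadrilateral families
(square, rectangle, trapezoid, parallelogram — the local-feature tasks),
solid and ring (annular) versions of disks, triangles, and squares, their
"irregular" harmonically-perturbed counterparts (the hole tasks), connected
and disassembled outline triangles (the connectivity tasks), and dots placed
inside or outside circle and square outlines (the containment tasks).  The
task table distinguishes the filled triangle/square of the hole experiments
from the quadrilaterals of the local-feature experiments, so those carry a
`-solid` suffix in the registry.  Circles are dense regular 90-gons, which
keeps one polygonal pipeline end to end and stays within 0.1% of the true
disk area.

**Sampling ranges.** The geometric parameters are sampled per image:

| parameter | default | rationale |
|---|---|---|
| canvas | 256 px, dark-on-light | matches the task-table thumbnails |
| square side | U[100, 140] canvas units | fills ~half the canvas at scale 1 |
| rectangle aspect | U[1.3, 2.5] | no rectangle is within tolerance of a square |
| parallelogram angle | U[50°, 80°] | at least 10° from a right angle |
| trapezoid top/bottom ratio | U[0.45, 0.75] | legs provably non-parallel |
| annulus hole ratio | U[0.3, 0.6] | hole visible at every scale |
| irregularity | amplitude 0.15, harmonics 2–6 | smooth, topology-preserving |
| disassembly displacement | max(0.25 × circumradius, 1.2 × gap) | separated but attributable parts |
| stroke width | 3 px | survives downscaling to 64 px |
| rotation / scale / translation | U[0°, 360°) / U[0.5, 1.0] / uniform in-canvas | the per-image variation |
| tolerances | τ_ang = 0.5°, τ_len = 0.5% of canvas | far below sampling ranges, above float noise |

Rejection sampling retries up to 1000 times per instance and then fails
loudly; infeasible configurations are a bug, not something to paper over.

**Transforms.** Placement is a similarity transform (rotate about the shape
centroid, scale, translate), applied to vertices only.  Stroke widths stay
in canvas pixels: scaling a 3 px stroke by 0.5 and then resizing to a 64 px
model input would thin it below one pixel and change the rendered topology,
destroying the invariant the transform is required to preserve.  For the
same reason the disassembled categories demand a centerline gap of
(3 × stroke)/scale at generation time, so the *rendered* gap between
segments never falls below two stroke widths.

**Rasterization.** Shapes are drawn 4× supersampled and area-downsampled
(antialiasing without seam artifacts).  Outlines are drawn as a polygon
difference — dilate the region by half the stroke, fill, then restore the
eroded interior — because stroking edge-by-edge leaves joint gaps at sharp
vertices.  Light and dark regions are morphologically opened by 1.25 px
before drawing: tips thinner than the raster resolution otherwise
discretize into isolated single-pixel components under the 8/4
connectivity convention and corrupt the topology labels.  This truncates
sub-pixel shape tips; it does not move any boundary that is thick enough
to render.

**Topology oracle.** Component counts use 8-connected foreground; holes are
4-connected background components that do not reach the image border (the
standard complementary pair, which makes hole counting paradox-free).
Containment removes the dot's own connected component and asks whether the
background region containing the dot centroid reaches the border.

## Experiment protocol

Twelve tasks in six groups (A 3, B 3, C 2, D 2, E 1, F 1).  Defaults follow
the study conditions throughout: 540 images per category; the learning pair
is split 459/81 (85/15) per category; the classifier trains for 20 epochs;
after every epoch it is scored on the 81+81 held-out validation images
(learning accuracy) and on all 540+540 images of the transfer pair
(transfer accuracy), which never enter a training batch.  Class mapping
follows column correspondence: transfer class 0 is scored as learning
class 0.  Epoch-1 accuracy is measured after the first full training epoch,
not at initialization.  The task table prints A.3 with the same category
pairs as A.1 (the original variation between them appears to be stylistic
and is not specified); the registry encodes the pairs exactly as printed.

## Transfer statistics

With accuracy in percent and epochs e = 1..k,

    HAUC(k) = Σ_{e=1..k} (accuracy(e) − 50)
    TFI(k)  = 100 · HAUC_transfer(k) / HAUC_learn(k)

The discrete sum is the default integration rule because it degenerates at
k = 1 to the single-epoch ratio (transfer₁ − 50)/(learning₁ − 50) × 100,
which is how per-epoch index rows are defined; a trapezoidal rule is
available behind a flag.  HAUC of a below-chance curve is negative.  When
HAUC_learn ≤ 0 the index is undefined and raised as an explicit error —
never clipped — because the statistic presupposes that learning succeeded.

The companion regression is OLS of transfer accuracy on learning accuracy
across epochs; R is the signed Pearson correlation (an absolute-value flag
exists because the convention is ambiguous in published tables, which show
positive R alongside negative slopes).  When the predictor variance is
below 1e-9 percent² — learning pinned at a constant, typically 100% — the
regression is reported as not applicable rather than fit.

## Reference classifier

No deep-learning framework is assumed: the bundled classifier is a compact
convolutional network implemented directly on NumPy with numba-compiled
3×3 convolution kernels.  Architecture: 64×64×3 input, three conv blocks
(16/32/64 channels, ReLU, 2×2 max pool), one dense layer of 128, two-way
softmax; SGD with learning rate 0.01, momentum 0.9, batch size 32; He
initialization from a seed, float32 throughout, deterministic for a fixed
seed.  Input presets for the four benchmark architectures (227/224/224/299)
are provided so externally trained adapters can plug into the same
protocol contract.

Trained from scratch on disk-vs-ring at these conditions the network
exceeds 95% validation accuracy within 20 epochs for at least 4 of 5
seeds; on the C.1 transfer pair (solid triangle vs. triangle-ring) it
reaches transfer accuracies near 88–90%, i.e., the hole invariant
transfers strongly even for a small from-scratch model.  A from-scratch
64×64 network is not a stand-in for fine-tuned ImageNet-scale models:
published index values for those models depend on pretrained features and
are outside what this package recomputes.

## What the generator does and does not emulate

The generator reproduces the stated study conditions — category count,
images per category, transform variation, split fractions, epoch budget.
It does not emulate photographic nuisance structure (texture, lighting,
occlusion, background clutter), anti-aliased rendering differences of the
original MATLAB pipeline, or the unstated numeric shape parameters, which
are this package's own documented choices.  Passing tests therefore
demonstrate correctness of the pipeline and the achievability of the
learning tasks at desk scale, not pixel-identity with the original stimuli.

## Degenerate inputs and numerical choices

* Accuracy curves must lie in [0, 100]; epoch indices are validated as
  consecutive from 1 on log ingestion.
* `make_annulus` re-samples the outer size until boundary clearance is
  stroke-safe (≥ 4 canvas units) and errors if the hole ratio makes that
  impossible (e.g., 0.99).
* `place_dot` demands the dot keep 2 stroke widths of clearance from the
  outline on either side; `disassemble` with zero displacement and no part
  rotation fails the gap check by construction.
* Tied maxima in 2×2 pooling share the gradient equally; ties are measure
  zero for trained activations but common in all-zero padding regions.
* Per-image seeds are `sha256(master_seed:category:index) mod 2^31`, so any
  image is reproducible independently of generation order.

## Problem sizes used in the checked runs

The bundled verification runs use 50 seeds per category for the topology
suite, 1000 random curves for the metric-oracle equivalence, and the full
540-per-class disk/ring task with 5 training seeds for the learning check;
the dataset-bookkeeping check runs a 5-image-per-category smoke generation,
with the full 24 × 540 generation exercised through the same code path.
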