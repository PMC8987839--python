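# Methods

## Pipeline model

The package estimates streetscape greenery in three nested units:

* **patch** — a 32 × 32 px RGB tile, the unit of classifier *training*,
  cut from annotated rectangles at 16 px stride (50% overlap). Partial
  windows at rectangle edges are discarded, never padded: padding would
  fabricate pixels and bias edge tiles. The closed-form tile count per
  rectangle, `max(0,(W−p)//s+1) · max(0,(H−p)//s+1)`, is verified
  against brute-force window enumeration in the tests.
* **cell** — a 32 × 32 px square in the *non-overlapping* inference grid
  (20 × 20 over a 640 × 640 image), the unit of classification and of
  GVI. Overlap is deliberately asymmetric between training and
  inference: overlap multiplies training data, while the survey grid
  must partition the image exactly. Remainder pixels beyond the last
  full cell are truncated, consistent with the chopping rule.
* **image / district** — GVI of an image is `100 · positives / cells`,
  kept at full float precision internally and formatted to two decimals
  only at I/O boundaries. District GVI is the unweighted pooled mean
  over all of a district's images (no intermediate per-point averaging
  of the four camera headings), and districts under the minimum image
  count (default 10) are excluded from mapping.

The label model is strictly binary — greenery vs. everything else;
vegetation types and conditions are deliberately not distinguished,
matching the resolution of 640 px street imagery.

## The patch classifier

A LeNet-class convolutional network implemented directly in NumPy
(im2col convolutions, analytic backprop verified against numerical
gradients in development): two valid 3 × 3 convolution blocks (32 then
64 filters, each ReLU + 2 × 2 max-pool), a 128-unit dense ReLU layer
with inverted dropout 0.5, and a 2-way softmax, trained with minibatch
Adam on cross-entropy. All of these are constructor parameters of
`PatchCNNClassifier`, which follows the scikit-learn estimator contract
(`fit`/`predict`/`predict_proba`, `get_params`, trailing-underscore
fitted attributes) and therefore composes with sklearn pipelines and
model selection.

Training defaults and rationale:

| parameter | default | why |
|---|---|---|
| `epochs` | 30 | the survey training regime; the synthetic problems converge in 1–3 |
| `batch_size` | 32 | standard minibatch size for this model scale |
| `validation_fraction` | 0.2 | stratified held-out split tracked per epoch |
| `learning_rate` | `None` → 1e-3 | Adam's published default; the resolved value is echoed in the model sidecar |
| `decision_threshold` | 0.5 | symmetric operating point on the greenery probability; exposed because surveys may prefer precision over recall |
| `class_weight` | `None` | annotation sets are naturally imbalanced toward background; no reweighting by default, `"balanced"` available |
| `dropout` | 0.5 | regularizes the dense layer; disabled automatically at inference |

Training-set class imbalance is accepted as-is by default because the
imbalance is informative: background really is more common than
greenery in street scenes.

Why a convolutional network and not a cheaper estimator: the defining
hard case of greenery surveys is *flat artificial green* — identical
mean color to vegetation, different texture. A multilayer perceptron on
raw pixels cannot use spatial structure (permuting pixels changes
nothing it can see before the first nonlinearity sums them), and indeed
fails at chance on texture-only separation; local convolution + ReLU +
pooling computes exactly the local-contrast statistics that separate
canopy texture from flat paint. The texture-capacity property (held-out
accuracy ≥ 0.9 on patches whose classes share mean color and differ
only in texture) is asserted in the test suite.

Determinism: weight initialization, the stratified split, epoch
shuffling and dropout all draw from one generator seeded by
`random_state`, so a fixed seed reproduces a training run on a fixed
thread configuration; inference is dropout-free and deterministic, and
a saved/reloaded model reproduces probabilities to 1e-6 (float32 + BLAS
reassociation bound the drift below that). Per-epoch training accuracy
and loss are minibatch averages over the epoch (the convention of the
major deep-learning frameworks); validation metrics are full-split
passes.

## The color band-difference baseline

A pixel is greenery iff `G − R > δ` and `G − B > δ` with channels scaled
to [0, 1]. δ defaults to 0.05; we fix the [0, 1] scale because 0.05 on a
0–255 scale would be below quantization noise. The comparison is strict,
so boundary differences of exactly δ are negative. An optional
4-connectivity despeckling filter (`min_region_px`) exists but defaults
off — shadows and artificial green survive such filtering anyway, which
is the documented weakness of spectral rules; the baseline is kept in
its plainest form so the comparison against the patch classifier is
fair. The baseline's pixel mask is reduced to the same 32 px cell grid
as the classifier via the identical occupancy rule, making the two
methods directly comparable cell-for-cell.

## Evaluation protocol

Predictions and references pair by image id (order-free); shapes must
match per pair; every cell position contributes one count to a pooled
confusion table. Overall accuracy, precision and recall follow the
standard formulas. Ratios with empty denominators are reported as
`None` rather than 0 — on small synthetic scenes an all-negative
prediction is possible, and a silent zero would corrupt comparisons.
The occupancy rule that defines a positive reference cell is a strict
majority (fraction > 0.5): a cell exactly half covered is negative.

## The synthetic scene generator

`random_street_scene` composes a 640 × 640 canvas from axis-aligned
regions: a sky band (vertical blue→white gradient), a building band and
a road band (low-frequency gray fields), then vegetation patches
(multiplicative Gaussian luminance noise of amplitude 0.25 plus a
mid-frequency blotch field — a canopy-like texture), optional shadowed
vegetation (the same texture with luminance scaled by a factor drawn
from [0.3, 0.6]) and near-uniform artificial green (amplitude 0.015).
Ground truth is geometric: the greenery mask is the union of vegetation
and shadow-vegetation regions under last-writer-wins compositing, never
derived from rendered colors, so it is independent of rendering noise.
Images are composited in float and quantized to 8 bits once.

The texture amplitudes were chosen for *separability*, not realism:
vegetation texture must be learnable and artificial green must defeat a
spectral rule while remaining distinguishable by texture. Passing tests
on these scenes therefore demonstrate that the pipeline's machinery —
chopping arithmetic, training, grid inference, occupancy evaluation,
the baseline's failure mode — works end to end; they do not certify
accuracy on real street imagery, where vegetation texture statistics,
lighting, blur and perspective are far richer. Blurred-image removal is
correspondingly out of scope: real surveys curate those by hand, and
the manifest filter exposes an explicit exclude-list for that purpose
(plus automatic rules for byte-identical duplicates and blank frames,
the two failure modes a street-imagery API produces mechanically).

The annotation generator stands in for the human rater by rejection
sampling rectangles against the ground-truth mask at a purity of 0.9
(positives ≥ 90% greenery, negatives ≤ 10%); human rectangles are
imperfect in ways this does not emulate. When ground-truth masks are
available, chopped tiles can additionally be screened by true occupancy
(the automated analog of a rater discarding tiles less than half
covered by their target); real annotations are trusted as labeled.

## Study conditions for the end-to-end suite

The module-scoped end-to-end study trains on 12 scenes × (3 greenery +
5 background) rectangles with sides drawn from 48–288 px — about 96
rectangles yielding roughly 5,000 patches after occupancy screening —
for 10 epochs, then evaluates on 4 held-out scenes (1,600 cells)
against ground-truth occupancy grids, alongside the color baseline at
δ = 0.05 on the artificial-green cells. These sizes were fixed once as
a desk-scale study design; under them the pipeline reaches cell-level
accuracy ≈ 0.99 and an artificial-green false-positive rate near zero
while the color baseline calls essentially every artificial-green cell
greenery.

## Numerical choices and degenerate inputs

* Coordinates are 0-based half-open everywhere; tiling arithmetic has
  no off-by-one ambiguity.
* Patch pixels are scaled to [0, 1] once, at patch creation; uint8
  inputs are rescaled on entry everywhere else too.
* Ties: occupancy exactly at the threshold is negative (strict `>`);
  the classifier's decision threshold is inclusive (`≥`), irrelevant in
  practice because softmax probabilities are continuous.
* Degenerate inputs fail loudly with typed errors: empty or
  single-class patch sets, images smaller than one cell, zero-cell
  grids, mismatched evaluation pairs, infeasible annotation requests
  (the error names the offending class), rectangles outside their
  image.
* Model serialization is NumPy `.npz` weights plus a JSON sidecar
  (configuration, resolved learning rate, full training history);
  loading reconstructs the estimator and its predictions exactly.

## Known limitations

* Synthetic scenes are rectangle compositions; real greenery is
  amorphous, occluded and perspective-distorted. Accuracy numbers from
  the synthetic suite are upper bounds on the machinery, not field
  performance.
* The classifier is texture-sensitive but trained per survey; no
  transfer learning or augmentation is provided.
* Duplicate detection is byte-exact only — appropriate for API-returned
  identical panoramas, blind to re-encoded near-duplicates.
* GeoJSON export attaches district means to supplied polygons; it does
  no geometry validation beyond structural checks and no cartography.
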