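# Methods

This note records the scientific and numerical choices behind `dbtnet`: what
the models and procedures assume, which parameters matter, what the synthetic
phantoms do and do not emulate, and where the design was genuinely open.

## Pseudo-color enhancement

The enhancement operates in the 8-bit HSV convention (hue stored in
[0, 179] as half-degrees) so that the hue shift's mod-180 wrap is exact
integer arithmetic. The three channel operations —
`H' = (H + ΔH) mod 180`, `S' = min(αS, 255)`, `V' = min(βV, 255)` — are
applied in the order hue → saturation → value; the order is pinned for
reproducibility even though the operations act on disjoint channels and
therefore commute. Model-facing patches are floats in [0, 1]; colorspace
operations run on an 8-bit integer view (multiply by 255, round half up), and
RGB↔HSV conversions delegate to scikit-image.

A grayscale image replicated to R=G=B has zero saturation and undefined hue,
so the hue and saturation adjustments alone cannot produce visible color.
Two colorization readings are therefore implemented and selectable:

* `replicate` — the literal reading; the hue shift acts on a degenerate hue
  channel and the enhancement reduces mostly to the brightness scaling;
* `intensity_to_hue` (default) — intensity drives the hue channel
  (H = round(I·179), S = 255, V = round(I·255)), which yields a genuinely
  colored intermediate and is the only reading under which the enhancement
  changes the chromatic content of the patch.

Neither reading is asserted to be canonical; both are tested. Note that the
default brightness scale β = 15 drives every pixel at or above 17/255 of full
scale to the 255 ceiling — the scaling is implemented literally, clipping
included, and flagged here rather than "corrected".

The histogram-equalization baseline is the classic 8-bit lookup
`round(255·(cdf − cdf_min)/(n − cdf_min))`; a constant image is returned
unchanged.

## Preprocessing

Bounding boxes are 0-based `(x, y, width, height)` with half-open extents,
matching the BCS-DBT annotation CSV dialect. Right-lateral volumes are
mirrored about the vertical axis (boxes remapped by `x' = W − x − w`) so
breast tissue always sits on the left; a missing laterality tag falls back to
an intensity-centroid heuristic with a warning.

The ROI crop expands the annotated box by 10 px on each of the four sides
(20 px per dimension), clips to image bounds, min-max normalizes **per crop**
(the plausible alternative, per-volume normalization, is configurable but not
the default — crop-local contrast is what the classifier should see), and
resizes to 224×224 with bilinear interpolation, anti-aliased on downscale.

The Z-window takes 10 contiguous slices around the annotated center slice
with a −5/+4 split, shifted (not truncated) at volume edges so the window
keeps its full length whenever the volume allows. The 10-slice choice is
anchored to the smallest lesions being ≈10 mm thick at 1 mm slice spacing
under an approximately spherical lesion assumption. Prediction-time selection
takes the 2m+1 slices symmetric about the center slice (m ∈ {1, 2, 3};
default 1, which performed best in the image-level comparisons this design
follows).

Training-time augmentation rotates by an angle drawn uniformly from
±[10°, 30°] (direction sign uniform, corners zero-filled) and shifts by
integer offsets up to 10% of the side. Augmentation acts on the grayscale
patch *before* enhancement so color statistics stay consistent.

## The dual-branch classifier

Backbones are grouped into shallow (MobileNetV2, AlexNet, ResNet18) and deep
(ResNet50, ResNeXt50, DenseNet121, DenseNet201) categories by depth and
parameter count; the assignment is read from the registry table, never
recomputed, and the config rejects a backbone placed in the wrong slot. The
classification heads of the published architectures are removed; only the
feature-extraction stacks are used. A TinyCNN pair (three/four conv blocks
with batch normalization, 32/64 final channels) provides a desk-scale pair
with the same interface for phantom experiments and tests.

Each branch's final feature map is adaptively average-pooled (default output
1×1, i.e. a global feature vector — the simplest reading of "unify spatial
dimensions") and flattened to v_s, v_d. Linear projections map both into a
shared d-dimensional space; d defaults to 256 and is configurable, as no
single canonical value exists. Two fusion variants are built:

* `concat_raw` (default): the classifier consumes z = [v_d; v_s]
  (length d_d + d_s), and the projections feed **only** the similarity loss;
* `concat_projected`: the classifier consumes the concatenated projections
  (length 2d).

Both variants are first-class because the two descriptions of this
architecture family genuinely disagree on what the classifier should consume;
the default follows the reading in which the projections exist for the
similarity constraint alone.

The joint loss is `L = (1/N) Σ (L_BCE + λ·L_Sim)` with
`L_Sim = mean_k (f̂_s,k − f̂_d,k)²`. The reduction over the projection
dimension is the mean so that λ's scale does not depend on d (`sum` is
available). λ defaults to 0.3 with the preset grid {0, 0.1, 0.3, 0.5}.
Probabilities are clamped 1e−7 from the boundary inside the BCE. The
similarity gradient flows into both branches (no stop-gradient), the literal
reading of the objective.

## Neural-network core

No deep-learning framework is assumed: `dbtnet.nn` implements convolution
(strided, padded, grouped/depthwise via an im2col view and einsum), max/avg/
adaptive-average pooling, batch normalization, linear layers, residual and
densely-connected blocks, with hand-derived backward passes, plus SGD and
Adam. Every layer's analytic gradient is verified against central finite
differences in the test suite. Initialization is a uniform fan-in scheme
driven by a single run-level seed; all computation is float64 CPU, so
identical seeds and data give bit-identical loss trajectories. Pretrained
weights are not bundled; checkpoints (config + all arrays) round-trip through
compressed `.npz` files.

## Voting and evaluation

Majority voting takes the mode of slice labels thresholded at (inclusive)
0.5; ties — possible when an even number of slices is aggregated — resolve
toward malignant, the sensitivity-favoring choice consistent with screening
practice, and the policy is explicit and configurable. Average voting
thresholds the mean probability at 0.5, boundary inclusive. Image-level AUC
uses the mean slice probability.

Metrics with empty denominators (e.g. sensitivity with no positives) are
reported as `nan` with a warning rather than silently zeroed. AUC is the
rank-based Mann–Whitney statistic with midrank ties (scikit-learn). The
McNemar test uses χ² = (b−c)²/(b+c) on the discordant counts with the 1-df
upper tail; the continuity correction is off by default and available as a
flag. Cross-validation folds partition patients, never slices, stratified by
class; the evaluation harness supports both a fixed stratified patient split
(default, 30% test) and patient-level 5-fold CV with mean ± SD reporting.

## Synthetic phantoms

The generator emulates the statistical structure the pipeline assumes from
screening DBT collections: grayscale volumes with parameterized voxel spacing,
one annotated lesion per patient with center slice and tight bounding box,
lesion footprints sampled from area ~ log-uniform[100, 3000] mm² with aspect
ratio U[0.6, 1] and widths clipped to [5, 80] mm, and four views (L/R, CC/MLO)
with native laterality so orientation standardization is exercised. The
malignancy signal is geometric: benign margins carry low-frequency radial
perturbations (amplitude 0.03), malignant margins high-frequency spiculated
ones (amplitude 0.18), applied coherently across slices of an ellipsoidal
intensity blob (+0.30 contrast, softened 1 px) on a correlated-noise
background with a laterality intensity gradient. The radial profile is
normalized so the realized extent never exceeds the sampled footprint, keeping
annotated boxes inside the stated width range.

Desk-scale defaults are 64 slices of 256×256 px at 0.4 mm XY / 1 mm Z — the
native 0.085 mm in-plane grid of real DBT would need >1000 px to hold an
80 mm lesion; all size logic runs through the spacing, so the generator scales.
A `separability_check` guards task solvability: the margin-irregularity
statistic perimeter²/area of the center-slice lesion mask must separate the
classes with AUC > 0.9 under default conditions (it reaches ≈0.99 at
n = 100).

What the phantoms do **not** emulate: tomosynthesis reconstruction artifacts
and anisotropic blur, real parenchymal texture, calcifications, biopsy clips,
multi-lesion cases, and intensity-based malignancy cues. Passing tests
therefore demonstrate that the pipeline's machinery — enhancement, geometry,
training dynamics, voting, statistics — is correct and that the architecture
can learn a morphology-based discrimination, not that it reaches any
particular performance on clinical data.

## Problem sizes and numerical choices

The default study set is 100 phantom patients (one 10-slice case each,
~70/30 patient-stratified train/test split); the TinyCNN dual-branch model is
trained for 10 epochs with Adam at 3×10⁻⁴ (the published schedule's learning
rate; the 150-epoch default applies to full-scale runs) and batch size 32.
Degenerate inputs are handled explicitly: zero-dynamic-range crops normalize
to zeros with a warning, constant images pass through histogram equalization
unchanged, an all-constant attention map normalizes to uniform, and empty
batches, single-class AUC inputs and zero-discordance McNemar tables raise
errors rather than returning conventionals.

## Known limitations

* The numpy training loop is orders of magnitude slower than a GPU framework;
  the published-scale backbones (ResNet50, DenseNet201, …) are constructible
  and differentiable but realistically only usable for forward passes and
  architecture experiments at this scale.
* `pretrained` loads local checkpoints only; no ImageNet weights are shipped,
  so transfer-learning workflows require externally converted weights.
* Vision-transformer backbones are out of scope; the registry is extensible
  but only CNN families are provided.
* The fixed −5/+4 window split and the malignant tie-break are declared
  conventions, not inferred ones.
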