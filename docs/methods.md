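# Methods

This note documents the models, parameter choices and numerical conventions
behind `wetblue`, and what the synthetic benchmarks do and do not demonstrate
about real skins.

## Imaging and tiling

Photographs are assumed to show a single skin on a dark table. Grayscale
conversion uses the ITU-R BT.601 luma weights (Pillow mode `"L"`).
Segmentation is a plain intensity threshold (default 30 of 255 — the
dark-background rig puts leather far above it) followed by keeping only the
largest 8-connected component, which suppresses glare specks and dust on the
table. The threshold is a parameter, not an estimate; Otsu-style adaptive
thresholding was deliberately not used because the acquisition geometry makes
the fixed threshold reliable and auditable.

Tiling is non-overlapping with stride `T`, anchored at the top-left corner of
the foreground bounding box, so every map cell corresponds to exactly one
image window. Windows never extend past the image and are never padded. A
cell counts as leather only when at least `min_fg_fraction = 0.9` of its
pixels are foreground; border windows mixing background would otherwise
contaminate the texture statistics. Coordinates are 0-based and row-major
with half-open pixel intervals; annotation `x`/`y` are window-center pixel
coordinates.

## Texture descriptors

**GLCM / Haralick.** Intensities are uniformly quantized to `levels = 32`
bins (256/8 — coarse enough that a 51×51 window populates a 32×32 matrix
densely). Co-occurrences are accumulated at distance 1 for the four standard
directions (0°, 45°, 90°, 135°), symmetrized and normalized to sum to one,
and the 13 Haralick measures f1–f13 are computed per matrix and **averaged**
over directions (keeping the descriptor at length 13 and approximately
rotation-insensitive; concatenation is the obvious alternative and was not
chosen because the grading stage treats the descriptor as a single texture
summary). The 14th measure (maximal correlation coefficient) is excluded for
its well-known numerical instability. Degenerate denominators — correlation
on a constant window, the information measures when a marginal entropy is
zero — are defined as 0 rather than raised, so constant windows yield a
finite descriptor (ASM 1, everything else 0-ish). Entropies use natural
logarithms. One caveat worth recording: a uniform intensity shift by a whole
quantization bin translates both GLCM marginals, which leaves 12 of the 13
measures invariant but moves the *sum average* (f6) by exactly twice the bin
shift; the invariance test asserts exactly that.

**LBP.** `P = 8` samples at radius 1 by default, with three variants:
`uniform` (non-rotation-invariant uniform patterns; 59 bins at P = 8),
`rotation_invariant` (minimal circular rotation of the raw code; 36 bins at
P = 8) and `uniform_rotation_invariant` (P + 2 bins). Codes are computed only
for pixels with a complete neighborhood (an R-pixel border is cropped) and
pooled into a histogram normalized to sum to one.

## Window classifier

`WindowDefectClassifier` wraps one of seven families behind a single
sklearn-style estimator. Scale-sensitive families (perceptron, logistic
regression, KNN, MLP, SVM) get a train-set standardization step. Iterative
families stop at 2000 iterations or an error tolerance of 1e-5. The default
configuration — GLCM features on 51-pixel windows into an RBF SVM with
`C = 10` — is the bank's strongest combination; the MLP default is 65
logistic hidden units with initial learning rate 0.5 (sklearn's SGD solver
offers inverse-scaling decay rather than a strictly linear schedule; that is
the closest available and is what the `linear`/`exponential` decay flags map
to).

Training is class-balanced: `balanced_split` draws an equal seeded sample of
each class for training (balance avoids majority-class bias in the binary
decision) and sends every remaining row to the test set. Model comparison
uses stratified 10-fold cross-validation; stratification is a deliberate
strengthening of plain equal-size folds because it stabilizes the balanced
design at small fold sizes.

**Rejection.** A window is *rejected* when its posterior for the normal
class lies within `band/2` of 0.5. Families without native posteriors (SVM,
perceptron) get a Platt calibration — a logistic map fitted on the training
margins — so the band always acts on a posterior scale; widening the band can
only convert labelled windows into rejections, never the reverse. In the
defect map, rejected windows count as defects: the conservative choice for
downstream grading, since an uncertain window should not enlarge a
"defect-free" region.

## Region analysis

"Defect-free convex region" is implemented as the **maximal axis-aligned
all-ones rectangle** of the defect map, the standard dynamic-programming
reading of the problem (true convex polygon extraction is undefined on a
binary grid of this kind). The algorithm builds a per-row histogram of
consecutive ones and scans it with a monotonic stack — O(rows·cols) — and is
oracle-tested against exhaustive rectangle enumeration. Ties on area break
deterministically: smallest top row, then smallest left column, then largest
height. Recursion extracts `k = 5` regions, zeroing each before the next
search, stopping early when no free cell remains.

The seven attributes are measured in window cells (multiply by `T²` for
pixels via `units="pixels"`). When fewer than `k` regions exist the area
list is padded with zeros before computing the smallest-region area `a5` and
the population standard deviation `a7`, keeping the attribute vector total
and `a7` well defined on heavily defective skins; `a4` and `a6` are defined
as 0 when the map has no free cell at all. The percentage wording of the
smallest-region attribute is ambiguous in common usage; here `a5` is the raw
(padded) smallest area and `a6` its percentage of `a1`.

## Quality grading

Only skins graded identically by two independent experts enter training
(`filter_coincident`); `expert_agreement` reports the full 7×7
cross-tabulation and its diagonal percentage. `undersample_quality` takes
`floor(0.75 × smallest class)` per level — with a smallest class of 8 that is
6 per level, a 42-skin balanced training set — and tests on the remainder.
The default grader is Gaussian naive Bayes with standard variance smoothing:
with a few dozen training skins and 7 attributes, the conditional-
independence bias is a feature, not a bug. Defect centrality is *not* an
explicit feature; it reaches the grader only through region geometry (central
defects fragment the free area much more than edge defects), mirroring how
graders weight defect location implicitly.

`qualify_sample` composes the full chain deterministically — segment → tile →
classify windows → extract regions → attributes → grade — and returns every
intermediate (mask, grid, defect map, regions, attributes) for audit and
overlay rendering. Stage failures propagate tagged with the stage name.

## Synthetic data

The generator emulates the acquisition setting, not leather itself: an
elliptical blob on a dark background (background strictly below the
segmentation threshold, blob strictly above it, so segmentation and tiling
reproduce the ground-truth grid exactly), filled with *smoothed Gaussian
noise* — mean plateau, pre-smoothing noise SD, Gaussian kernel SD. Defaults:
base texture (mean 130, noise 25, smoothing 1.2), defect texture (mean 95,
noise 60, smoothing 0.4), a 612×816 image whose blob yields roughly 90
windows at `T = 51`. This family was chosen because its GLCM/LBP statistics
shift monotonically with the noise-scale offset (the "separability dial",
asserted in tests), giving a controllable margin between classes; the default
margin is several pooled SDs of GLCM contrast, i.e. an *easy* instance.

Defect patches are `T`-sized squares aligned to window cells, so the
ground-truth defect map is exact. Quality levels follow the defective-window
fraction: level 1 < 10%, then 10-point bands up to level 5, level 6 at
50–65%, level 7 above 65% — a 7-level interpolation of the common 5-level
tannery banding, since no numeric 7-level banding standard exists; it is a
synthetic stand-in and labelled as such. Placement follows grading practice:
edge placement for levels 1–2, uniform for 3–5, central for 6–7. Corpus
generation jitters blob axes by ±8% so the attribute scales vary between
skins.

**What passing means.** The synthetic benchmarks show that the pipeline
machinery is correct and that, given a texture margin of ≥ 2 pooled SDs, the
default classifier and grader recover planted ground truth (detection
accuracy ≥ 0.90 at 1000 windows/class; grading within one level for ≥ 90% of
test skins). They do *not* show that real wet-blue defects — scars, tick
bites, holes with complex morphology and illumination effects — are equally
separable; on real corpora the texture margin, not the machinery, is the
binding constraint.

## Problem sizes and determinism

Default benchmark sizes — 1000 windows per class for detection, a 350-skin
corpus (ground-truth maps only, no pixel rendering) for grading, all binary
maps up to 4×4 plus 500 random 10×12 maps for the rectangle oracle — were
chosen as the smallest sizes at which the measured rates are stable across
seeds. Every stochastic step (splits, classifier initialisation, generator)
is driven by an explicit seed, and identical seeds reproduce splits, CV
reports, defect maps and grades bit-for-bit; the acceptance script derives
all of its seeds from a single `--seed`.

## Known limitations

- The segmentation assumes the dark-background rig; natural-background
  photographs need a different foreground model.
- Non-overlapping tiling quantizes defect positions to the window grid; a
  defect straddling a window border dilutes into two windows.
- The maximal-rectangle reading of "convex region" ignores non-rectangular
  free areas; a large L-shaped free region scores as two smaller rectangles.
- The grader is only as good as stage 1: systematic window misclassification
  biases every attribute (the stages are strictly sequential by design).
- LBP multi-resolution concatenation is supported via repeated calls but has
  no first-class config.
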