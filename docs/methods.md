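# Methods

This note documents the models and procedures implemented in `mossquad`,
the parameters that matter, the numerical conventions, and what the
synthetic-data tests do and do not demonstrate.

## Geometric frame

All geometry lives in a local meter frame: origin at the raster's
top-left corner, x rightward, y downward, square pixels of side
`pixel_size` (default 0.0005 m, the rectification resolution used for
quadrat photographs). There is no CRS and no control-point
georeferencing: the quadrat-interior polygon supplied at ingest anchors
the frame. A pixel belongs to a polygon iff its center lies inside it,
which makes rasterization exact for axis-aligned shapes and convergent
(O(pixel size)) for curved ones. Nearest-neighbor resampling maps each
output pixel center to the input pixel containing it, so resampled
rasters contain only values present in the source — a requirement for
classification on raw digital numbers. Accuracy sampling uses a regular
point grid at 0.005 m spacing (one point per cell center,
`floor(extent/spacing)` per axis).

Mask polygons are consumed as GeoJSON (one file per layer, or one file
with a `layer` property). Layer names are restricted to a fixed schema;
overlaps resolve by fixed precedence (frame > water > snow > wet moss >
macrolichen > crustose lichen > rock), chosen so that the more
transient/ambiguous covers win and output is deterministic.

## Segmentation

The segmenter is the published region-merging formulation that underlies
commercial multiresolution segmentation. Objects start as single pixels;
a candidate merge of objects 1 and 2 into m is scored by

    f = (1 − w_shape) · Δh_color + w_shape · Δh_shape
    Δh_color  = Σ_bands (n_m σ_m − n_1 σ_1 − n_2 σ_2)          (band weights 1)
    Δh_shape  = w_cmpct · Δh_cmpct + (1 − w_cmpct) · Δh_smooth
    Δh_cmpct  = l_m √n_m − l_1 √n_1 − l_2 √n_2
    Δh_smooth = n_m l_m / b_m − n_1 l_1 / b_1 − n_2 l_2 / b_2

with n the pixel count, σ the per-band standard deviation, l the
perimeter in pixel edges and b the bounding-box perimeter. A merge is
admitted iff `f < scale²` (the squared-scale threshold is the standard
convention and makes the scale parameter comparable to per-band digital
numbers). Merging uses local mutual best fitting — A merges with B only
if each is the other's cheapest neighbor — with ties broken toward the
smaller object id and ascending-id treatment order per sweep, so results
are bit-reproducible. Connectivity is 4-neighbor throughout, matching
the pixel-edge border-length bookkeeping. Thematic masks are hard
constraints: candidate edges never cross a mask boundary, so manually
digitized covers are preserved as object boundaries.

Defaults (scale 27, shape 0.1, compactness 0.5) are the reference
configuration for rectified quadrat imagery. Because the commercial
implementation's internals are proprietary, identical scales will not
reproduce identical objects across implementations; the scale-selection
procedure, not any particular scale value, is the portable part.

Scale selection (`esp_curve`) records, per scale, the mean over objects
of the within-object standard deviation of the brightness band (local
variance, LV) and its percent rate of change (ROC). LV is defined per
object level — the definition that yields a scale-indexed curve — rather
than as a fixed moving-window statistic; the two are sometimes conflated
in descriptions of the procedure. ROC peaks (strict local maxima;
plateaus report their smallest scale) mark candidate object levels.

## Spectral features and indices

All rule features are brightness-invariant functions of object mean
band values (computed from the means, not averaged over per-pixel
indices — the OBIA convention; the two orders differ and the choice is
recorded in output metadata). Band ratios PbR_X = X/(R+G+B) are
undefined (NaN) for black pixels; NaN never satisfies a rule condition.
The HSI transform is the standard arccos/bi-conic variant
(I = (R+G+B)/3, S = 1 − min/I, hue from the arccos formulation), chosen
because it is reproducible and cross-checkable against independent
implementations; a documented inverse supports round-trip testing. The
saturation-based death index is undefined below a saturation guard of
1e-6 — near-achromatic objects are routed to the intensity rules
instead of producing unstable quotients.

Threshold candidates come from exact Fisher–Jenks natural breaks
(dynamic program minimizing within-class sum of squared deviations; ties
toward the lower break value). The exact DP is O(k n²) and is applied up
to 20,000 values; longer inputs are reduced to 20,000 evenly spaced
order statistics first, which is deterministic and changes breaks only
at the resolution of the discarded quantile gaps. The goodness of
variance fit is GVF = 1 − SSD_within/SSD_total.

## Rule classification

Classification is staged: (1) masked objects take their mask class
unconditionally and can never be changed by any later stage; (2)
threshold rules run in stage order, first match wins, over objects still
unclassified; (3) context rules iterate to a fixpoint (default bound 10
passes). Each threshold rule is a conjunction of conditions
(feature, < or ≥, threshold) — conjunctions are needed because shadow
and bright-rock detection combine intensity and luminance, and moribund
detection combines the death index with saturation and intensity
bounds.

The shipped default stage order mirrors the narrative of the original
workflow: moribund by high death1 (with saturation < 0.30, green ratio
< 0.40 and intensity in [0.16, 0.50) so that shadows, bright rock and
desaturated healthy turf are excluded), residual moribund by low death2,
stressed by stress ≥ 1.40, healthy by stress < 1.40 and green ratio
≥ 0.40, shadow by intensity < 0.16, snow by intensity ≥ 0.85, rock by
intensity ≥ 0.50. The numeric thresholds are calibrated between
natural-breaks clusters of the synthetic generator's object features
(the same procedure a user follows on real imagery with
`mossquad calibrate`); they are config-driven and not expected to
transfer to real photographs unchanged.

Context rules: a shadow object sharing strictly more than 0.5 of its
border with one moss health class takes that class (the relative border
denominator includes image-boundary edges, counted as "outside"); an
object under 25 px (6.25 mm² at 0.0005 m pixels) enclosed by healthy
moss becomes rock — applied to snow-labeled objects (bright white blobs
inside turf are wind-blown rocks, not snow) and to unclassified ones.
"Enclosed" requires more than half the border shared with the enclosing
class. Unclassified is a legal terminal class and is reported, never
redistributed. Manual corrections (polygon + class) are applied last,
idempotently, with per-pixel provenance (`mask`/`rule`/`context_rule`/
`manual_correction`) and a correction log that feeds the run manifest.

## Accuracy assessment

The error matrix is oriented rows = prediction, columns = reference, and
normalized to joint proportions (percent-mode input is accepted).
Overall accuracy is 100 · trace(p); Cohen's κ is (p_o − p_e)/(1 − p_e)
with p_e = Σ p_i+ p_+i. Conditional (per-class) κ defaults to the
row-conditional "user's" form κ_i = (p_ii/p_i+ − p_+i)/(1 − p_+i); this
convention was fixed by verifying that it reproduces all
well-conditioned per-class values of a published validation matrix after
2-dp rounding (the column-conditional form is exposed via `by="col"`).
Omission error for class i is 100·(1 − p_ii/p_+i), commission
100·(1 − p_ii/p_i+); the identities
accuracy = 100 − Σ p_i+·commission_i = 100 − Σ p_+i·omission_i are
checked numerically in the tests. Classes with tiny marginals inherit
the rounding noise of 2-dp printed matrices, so only well-conditioned
cells are asserted against published values.

## Change statistics

Per cover class, quadrats are blocks and years treatments. The Friedman
statistic is computed in its tie-corrected form

    Q = (k−1) Σ_j (R_j − b(k+1)/2)² / (Σ_ij r_ij² − b k (k+1)²/4)

(ties always corrected — cover panels contain exact zeros), referred to
the χ²_{k−1} upper tail. The χ² tail is an approximation: against the
exact within-block permutation distribution it is accurate in the
rejection region but can deviate mid-range for small b (the permutation
distribution is coarse there); the test suite pins agreement to within
0.01 in the rejection region and the type-I error to [0.03, 0.07] at
α = 0.05 under the null. Post-hoc pairwise comparisons use the Dunn-type
statistic z = (R̄_a − R̄_b)/√(k(k+1)/(6b)) with two-sided normal p-values
and Bonferroni correction over k(k−1)/2 pairs, plus a compact letter
display for plotting. Blocks with any missing year are removed
(complete-case), since the test requires complete blocks; removals are
logged.

## Synthetic generator

The generator emulates the color structure the classifier assumes:
contiguous irregular patches from a random-priority multi-source flood
fill (seeded growth rather than Voronoi, producing the ragged turf
boundaries the shape terms must handle), class assignment by
largest-patch-to-largest-deficit greedy with local improvement, then a
carving step that moves connected sub-regions between classes until
realized cover is within 0.5 % of each target (so realized fractions
track requests to well under the ±2-point contract). Colors are drawn
per connected class region from per-class RGB models (means follow the
qualitative field descriptions — bright green/olive healthy moss,
red/brown stressed, gray/black moribund, near-white snow, near-black
shadow — with patch-mean SD 8–10 and per-pixel noise SD 4, chosen as
realistic within-turf variation relative to the ~50-digital-number
between-class contrasts). An optional contiguous shadow region darkens
the image by a flat ×0.22 multiplier; optional sub-25-px bright blobs
inside healthy patches emulate wind-blown rocks. All randomness flows
from one integer seed through SeedSequence spawning; identical seeds
give bit-identical output.

Default conditions: 96 × 96 px rasters (a quadrat window at a problem
size where the full pipeline runs in well under a second per quadrat),
patch scale 12 px, composition healthy 0.45 / stressed 0.25 / moribund
0.25 / rock 0.05.

What the closure test shows — and does not. Classifying 20 default
synthetic quadrats with the shipped ruleset recovers per-class cover
within 5 percentage points (in practice within fractions of a point)
for classes ≥ 10 % cover. This validates the plumbing: segmentation
respects class boundaries, object features behave as designed,
thresholds sit between the generated clusters, cover accounting is
exact. It does not demonstrate field accuracy: the generator has no
health gradients within a patch, no specular reflection from wet moss,
no illumination field beyond the flat shadow multiplier, no mixed
boundary pixels from optical blur, and no camera-to-camera color shifts.
Real imagery requires recalibrated thresholds and will show genuinely
ambiguous objects.

## Known limitations

- Shapefile mask input is not supported; masks are GeoJSON only.
- Segmentation is single-level; there is no hierarchical object linking.
- No variance or confidence intervals for κ; no multi-rater agreement
  modeling (consensus building is upstream of this tool).
- The Friedman χ² tail is approximate at very small block counts; for
  b < 6 consider the permutation p-value directly.
- Macrolichen-dominated imagery is out of scope: black/gray/white
  lichens are not separable from rock on RGB spectra alone, which is why
  lichen cover enters through manual masks.
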