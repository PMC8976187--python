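# Methods

## Segmentation model

The segmentation pipeline assumes Romanowsky-type staining: WBC nuclei take
up a basophilic purple stain while erythrocytes and plasma remain pale red
to pink. In HSV space this maps the two populations to well-separated hue
bands, so the problem reduces to thresholding a 1-D hue histogram rather
than clustering in RGB.

Hue is stored in half-degree units, range [0, 180), so all three HSV planes
share one [0, 255] depth (pure red 0, green 60, blue 120). Planes are kept
as floats; quantization to integer bins happens only where a histogram or an
8-bit file requires it, which keeps the RGB→HSV→RGB round trip within one
intensity level per channel.

The cascade runs `n_passes` (default 3) rounds of:

1. Gaussian smoothing of the hue plane (separable, normalized, reflected
   borders; smoothing is cumulative across rounds, i.e. the filter is
   literally applied three times);
2. Otsu threshold selection over the histogram of pixels still *active*
   (round 1: all pixels; later rounds: survivors of the previous round —
   restricting the histogram is what makes later thresholds differ from the
   first on the same plane);
3. binarization at the selected threshold and intersection with the active
   set.

Otsu selection returns the smallest `t` maximizing
`σ_b²(t) = w₀ w₁ (μ₀ − μ₁)²` with class 0 = pixels ≤ t. Ties break toward
the smallest threshold; a constant plane returns its constant with variance
0 rather than raising, so blank fields degrade gracefully.

A 13×13 square opening with two iterations follows; "two iterations" is
interpreted as *staged* (erode twice, then dilate twice — equivalent to
opening by the element dilated by itself), with a `repeated` full-open mode
and an elliptical element available as config switches. An optional
`min_object_area` post-filter (default 0, i.e. off) is provided for
robustness. Connectivity is 8-connected foreground throughout; coordinates
are 0-based (row, col).

### Keep-side rule and degeneracy guard

Each round must decide which side of its threshold survives. The default
`auto` rule keeps the **higher-mean-hue** side in round 1: nuclei are the
high-hue minority against the low-hue background. For later rounds `auto`
switches to **majority retention**: after round 1 the active set is the
nucleus plus contaminant remnants (RBC fragments, boundary blends), and the
round's job is to *remove* the minority population. The switch matters
because hue is circular: an RGB blend between a purple nucleus and a pink
background sweeps through the magenta sector, so the blur halo around a cell
carries hues *above* the nucleus band, and "keep the higher side" applied
blindly in round 2 would keep the halo ring and discard the nucleus.
Explicit per-round tags (`above`, `below`, `higher`, `majority`) override
`auto`.

A round is *degenerate* when its best split separates the class means by
less than `min_class_separation` (default 10 hue units) or achieves zero
between-class variance. The scale was fixed from the generator's hue
statistics: within-class hue jitter under realistic noise is ~1–5 units,
genuine between-population gaps are ≥ 25. A degenerate **first** round means
the field has no distinct high-hue population at all — no WBC — and yields
an empty mask (this is what makes a blank field or an RBC-only field come
back empty instead of half-foreground, since Otsu always produces *some*
split). A degenerate later round is a no-op: nothing is left to remove.

### Contours

Outer boundaries are ordered pixel polygons produced by Moore-neighbor
tracing with a state-recurrence stopping rule, one polygon per 8-connected
component, holes filled first. Tracing is implemented here because no
available library returns *ordered, in-bounds pixel* boundaries (sub-pixel
iso-contours do not satisfy that contract). Single-pixel components
degenerate to a repeated vertex. Overlay drawing connects consecutive
vertices (adjacent by construction), so exactly the boundary pixels change.

## Evaluation metrics

Pixel accuracy, SSIM and Dice compare predicted vs. ground-truth masks;
accuracy/precision/recall derive from TP/TN/FP/FN counts. Counts are reals
because image-level tallies averaged over runs may be fractional. Choices:

* SSIM: 7×7 uniform window, K1=0.01, K2=0.03, mean aggregation (delegated to
  scikit-image). Dynamic range defaults to 1 for masks and 255 for channels.
* Dice of two empty masks is 1.0 with a warning (perfect agreement on
  "nothing to segment"); zero-denominator rates are NaN with a warning,
  never a silent 0 and never an exception.
* Comparisons against printed 4-decimal values use round-half-away-from-zero
  (`round_half_away`), matching how such tables are conventionally printed.
* Segmentation "accuracy" is pixel-level — the only definition compatible
  with mask comparison.

## Classifier head

Images are resized to 150×150 (bilinear) and mapped to (−1, 1) by
`v ↦ v/127.5 − 1`, the input convention of common pretrained backbones. The
head is global average pooling followed by one sigmoid unit: `d + 1`
trainable parameters (2049 at the canonical depth 2048). Training minimizes
binary cross-entropy (healthy = 1, ALL = 0) by full-batch gradient descent —
the problem is convex in the head parameters, so a fixed-step deterministic
optimizer (default learning rate 0.05, 300 epochs) suffices and is exactly
reproducible; no optimizer/batch-size convention is inherited, these are
this package's own choices. Data are shuffled by the config seed and split
train/validation/test (default 208/26/26, scaled proportionally for other
dataset sizes; the test portion is never touched during training). The
final classifier is the epoch with the highest validation accuracy, ties
broken by lowest validation loss, then earliest epoch. A probability
strictly over 0.5 is labelled healthy; exactly 0.5 falls to ALL.

The backbone is deliberately not bundled. The extractor contract is any
callable `image → FeatureMap` of fixed depth; the included toy extractor
(15×15×3 mean pooling followed by a seeded Gaussian random projection) is a
deterministic stand-in that exercises the full head pipeline and is labelled
as such — it is not a learned feature extractor and carries no claim about
real-data performance. Augmentation transforms (horizontal/vertical flip,
quarter rotation, seeded translation with zero fill) are provided as
deterministic operations.

## Synthetic smear generator

Scenes emulate single-WBC smear crops: a 257×257 canvas, pale pink-tan
background, 15 elliptical RBCs with lighter centers, and one WBC —
*healthy*: round cell, compact round nucleus at 0.6× cell radius; *ALL*:
lobed irregular boundary with a lobed nucleus at 0.85× radius (higher
nucleus-to-cell ratio). Degradations — multiplicative illumination gradient
(default 0.15), Gaussian blur (σ = 1.0), additive Gaussian sensor noise
(σ = 4 intensity levels) — apply to the image only; the mask is the exact
pre-degradation union of rendered WBC interiors. RBCs may overlap each
other and be overpainted by WBCs; WBCs never overlap each other, with a
bounded retry (200 placements) before a generation error.

The default palette places background/RBC hues at ≈ 9–17 half-degrees and
WBC cytoplasm/nucleus hues at ≈ 127–135, far from both each other and the
circular hue wrap, so noise cannot flip a population across 0/180 and the
hue histogram is genuinely bimodal — the property the thresholding cascade
assumes and that the generator's property tests assert. Cytoplasm and
nucleus hues are deliberately within a few units of each other so a
degenerate third round does not bisect the cell. Defaults (1 WBC, 15 RBCs,
mild blur/noise) define the standard test condition; the evaluation studies
use 20 scenes per condition, sized to run in seconds while averaging over
shape, placement and seed variation.

What the generator does **not** model: staining chemistry and stain
variability, touching/overlapping WBCs, platelets and debris, focus
gradients, and the long-tailed illumination artifacts of real microscopy.
Passing the synthetic-recovery suite therefore demonstrates correctness of
the algorithmic chain under the stated assumptions (hue-separable
populations), not clinical-grade performance on real smears — the published
headline numbers on the gated real-image dataset are not reproducible
without that dataset and a pretrained backbone, and are not claimed here.

## Numerical details

* Thresholding compares the *rounded* smoothed hue (the same values the
  histogram binned), keeping histogram and binarization consistent.
* Hue values that round to exactly 180 wrap to 0 (red is red).
* Gradient-descent BCE clips probabilities at 1e-12 for the loss only.
* Mask serialization: 8-bit PNG {0, 255}; nonzero reads as foreground;
  lossy formats refused on write, accepted on read for images.
* Erosion treats pixels outside the border as background (objects touching
  the frame shrink), matching the usual strict-opening convention.

## Known limitations

* Masked-histogram Otsu on later rounds assumes the surviving set still
  contains ≥ 2 populations or triggers the degeneracy guard; pathological
  palettes violating hue separation (e.g. magenta backgrounds near the wrap)
  would need the per-round override tags.
* The majority keep-rule presumes the WBC is the largest surviving
  component population after round 1; fields dominated by non-WBC purple
  artifacts would mislead it.
* `rotate90` swaps dimensions for non-square images.
* SSIM on masks uses dynamic range 1; values are not numerically comparable
  to SSIM on 8-bit channels.
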