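# Methods

## The measurement

The package quantifies DNA damage per cell from two-channel fluorescence
batches. The unit of analysis is the *retained nucleus*: a connected
component of the thresholded marker channel whose pixel area falls in a
user window. For each retained nucleus the damage channel contributes a
set of foci — connected components of a locally thresholded mask,
restricted to that nucleus's pixels and at least `foci_area_min` px large —
summarised as a count, a mean area, and a total area. Both the mean focus
size and the total damaged area per cell are reported because group
statistics in this field are formed over either.

Zero-foci nuclei are reported as rows with count 0 and mean 0 (a sentinel,
documented here and in the CSV contract): omitting undamaged cells would
bias every group mean upward. Images are processed independently, and a
degenerate image (blank, constant, or entirely below the cut-off) yields
zero nuclei with a logged warning rather than an exception, so a single
bad frame cannot abort a batch.

## Nucleus detection

Marker images are floored at a user cut-off `intensity_cutoff` — pixels
below it are excluded both from the Otsu histogram and from the
foreground — because the cut-off's role is to remove the background mode
before Otsu splits the remaining mass. Otsu's criterion is evaluated for
all 256 candidate thresholds using exact integer arithmetic: maximising
ω₀ω₁(μ₀−μ₁)² is equivalent to maximising (S₀W₁ − S₁W₀)²/(W₀W₁) over class
pixel counts W and intensity sums S, and candidates are compared by
cross-multiplication of Python integers. Ties break to the smallest
threshold. This removes all floating-point sensitivity from the threshold
choice.

One boundary case is resolved in favour of marker-based selection: when a
positive cut-off leaves a single occupied intensity bin (a uniformly
bright marker class over a darker background, common with transduction
markers and exact in synthetic scenes), the cut-off itself is the
separation and the floored pixels are returned as foreground. A truly
constant image, with no background class, still yields an empty mask.

Components are labelled (8-connectivity by default; 4 available) and gated
to `[marker_area_min, marker_area_max]` px. An optional
`exclude_edge_nuclei` flag drops components whose bounding box touches the
image border; it is off by default, matching the convention of removing
edge cells by visual inspection of the output images.

## Focus detection

The damage channel is binarized with an adaptive Gaussian-C threshold:
pixel *p* is foreground iff `I(p) > round(m(p)) − C`, where `m(p)` is the
Gaussian-weighted mean of the `block_size × block_size` neighbourhood
(σ = 0.3·((block−1)/2 − 1) + 0.8, weights normalised to 1, mirror-reflected
borders without edge repeat). Two numerical choices are deliberate:

* **The local mean is rounded to the nearest integer (half-up).** This is
  the 8-bit convention of the operator family this operator belongs to,
  and it makes the mask an exact function of the input: without rounding,
  the comparison on flat regions with C = 0 sits on a floating-point knife
  edge and the result would depend on summation order.
* **The sign convention is `I > m − C`.** Raising C therefore *grows* the
  foreground; a flat region is entirely foreground for C > 0 and entirely
  background for C ≤ 0. For punctum detection on a flat or low-texture
  background, C should be zero or negative (a negative C demands a pixel
  exceed its local mean by |C|). On real, textured images small positive
  C values behave conventionally. The per-experiment calibration of C and
  of the background cut-off mirrors how such cut-offs are established per
  dataset in practice.

The mask is computed once over the whole image and then intersected with
each nucleus: thresholding per bounding box would create block artifacts
at box borders. Components are labelled inside each nucleus (so damage
spilling across the gap between two nuclei is split and attributed to
each), filtered by `foci_area_min`, and damage outside every retained
nucleus is ignored.

Component labelling itself is a two-pass run-based union-find: rows are
reduced to runs of foreground, runs are unioned with overlapping runs of
the previous row (one-column tolerance under 8-connectivity), and final
labels are issued in raster order of each component's first pixel. The
numbering is thus deterministic, which the output images and the
`nucleus_id` column rely on.

## Parameters

| parameter            | default | meaning                                            |
| -------------------- | ------- | -------------------------------------------------- |
| `intensity_cutoff`   | 0       | background floor (intensity) before Otsu            |
| `marker_area_min/max`| 1/10⁹   | retained-nucleus area window (px)                  |
| `foci_area_min`      | 1       | minimum focus area (px); 1 keeps everything        |
| `connectivity`       | 8       | pixel adjacency for components                     |
| `block_size`         | 11      | adaptive-threshold window (odd px)                 |
| `c_offset`           | 2       | adaptive-threshold offset (intensity)              |
| `exclude_edge_nuclei`| off     | drop border-touching nuclei                        |

The suggested cut-off printed by `suggest` is computed from the pooled
histogram as |μ\_excl − μ\_all|, where μ\_all is the mean intensity of all
pixels and μ\_excl the mean excluding the dominant (modal) bin. The
quantity is one reading of "distance between background mode and signal";
it is a starting point to be checked against the histogram plot, and the
operation is isolated so the formula can be replaced without touching
callers.

## Synthetic scenes

The generator emulates the study's inputs at the level that matters to the
algorithm: elliptical nuclei (aspect ratio 0.65–1, random orientation) of
exact rasterized area 1000–2500 px in a 512×512 frame, uniform marker
intensity 180 over background 10, and 0–12 hard-disk foci of radius 1–3 px
at intensity 200 per nucleus. Nuclei keep ≥ 2 px of clear background
between each other and foci keep ≥ 2 px between each other, so no two
objects merge under 8-connectivity; a clump mode (`allow_overlap`) removes
the nucleus-separation constraint to test that size gating rejects merged
components. Pan-nuclear damage (whole-nucleus fill) is available as a
mode; its ground truth is a single blob covering the nucleus. Gaussian
noise of chosen σ is added to the damage channel only, then rounded and
clipped; the marker channel is rendered noise-free. All sampling uses
numpy's PCG64 generator from a single integer seed, so scenes and
renderings are bit-identical across platforms.

What the generator does **not** emulate: point-spread blur, intensity
gradients and vignetting, textured chromatin background, focus intensity
variation, and non-Gaussian camera noise. Exact recovery on these scenes
therefore demonstrates the correctness of the segmentation/measurement
machinery — thresholds, components, gating, bookkeeping — not robustness
to real optics; on real images the cut-off and C must be calibrated per
experiment and results inspected via the output images.

Matched-parameter analyses of synthetic scenes use `c_offset = 0` at σ = 0
(any positive C floods the perfectly flat background) and
`c_offset = −25` at σ = 5 (a 5σ margin above the local mean, making a
false foreground pixel a ≈ 3·10⁻⁷ event per pixel while 190-unit focus
contrast passes unharmed). These follow from the noise model, not from
fitting.

## Problem sizes and verification

The test suite verifies the operators against independent brute-force
oracles — an exhaustive 256-candidate Otsu sweep in exact rational
arithmetic, a per-pixel double-loop adaptive threshold, and a BFS
flood-fill labeller — on hundreds of seeded random images (32×32 to
64×64), and the whole pipeline against generator ground truth on 20
scenes of 512×512 px with 5–10 nuclei each, noise-free and at σ = 5.
Batch-level properties (16-fold duplication leaving the group mean
bitwise unchanged, byte-identical CSVs across reruns, size-gating
exactness, monotonicity in `foci_area_min` and the cut-off) run on
reduced frames (160–320 px) chosen so the full suite completes in well
under a minute per property while still exercising multi-nucleus scenes.
`scripts/acceptance.py` recomputes the same quantities from scratch at
those sizes from a single command-line seed.

## Known limitations

* Clumped nuclei are rejected by the area gate, not split; there is no
  watershed stage.
* Pan-nuclear damage is recovered as one blob only when its texture
  differs from its surroundings; on a perfectly flat fill the adaptive
  operator detects the rim, not the interior — a structural property of
  local-mean thresholding. Quantifying pan-nuclear cells is best done via
  the total-area column with calibrated C on real (textured) data.
* Marker/damage image pairing is positional after a lexicographic filename
  sort (a warning is logged when basenames differ); there is no
  content-based matching.
* Inputs above 8 bits are linearly rescaled to 8 bits at load; all
  thresholds live on the 0–255 scale.
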