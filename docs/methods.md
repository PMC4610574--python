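# Methods

## Detection model

The detector assumes the acquisition protocol: a single grapevine
inflorescence around flowering (BBCH ~55–57), photographed in daylight
against dark, achromatic cardboard, in focus and not overexposed except
in the specular highlights themselves. Under that protocol each flower
button is quasi-spherical and glossy, so it carries exactly one
dominant specular highlight; the pipeline counts flowers by counting
highlight-shaped regional maxima of the CIE 1976 L\* channel and then
pruning statistically implausible candidates.

### Downscaling

Images above `target_megapixels` (default 2.0 Mpx) are resized by a
single linear factor `sqrt(target_px / current_px)` with anti-aliased
area resampling, so the aspect ratio is preserved and the output never
exceeds the target beyond a rounding pixel. Smaller images pass through
untouched; the pipeline never upscales. All detection happens at the
analyzed scale; `DetectionResult.scale_factor` maps centers back
bijectively to original coordinates.

### ROI segmentation

Background = (L\* ≤ T) ∧ (chroma ≤ C), everything else is foreground;
connected specks under `min_foreground_fraction` of the frame (default
0.01%) are then dropped. C defaults to 15 (the cardboard is
achromatic; flower tissue, even dim, rarely is — and dim *and*
achromatic pixels are safe to discard either way). T is, by default,
the triangle (histogram-shape) threshold on L\*. The triangle rule was
chosen over Otsu deliberately: the L\* histogram of a protocol photo
has one dominant, very tight background peak near L\* ≈ 3 and a broad
foreground spread; Otsu then tends to place the cut *inside* the
foreground spread (measured on a 28%-coverage scene: Otsu 36.5, cutting
dimly lit organ pixels at L\* 23–36), while the triangle rule lands
just past the background peak's foot. In automatic mode the threshold
is floored at L\* = 10: the protocol guarantees the background is
darker than that, and a frame whose foreground never rises above it has
no segmentable inflorescence — segmentation then fails with an error
instructing re-acquisition rather than returning an empty ROI.
A fixed threshold can be configured instead
(`background_lightness_threshold`).

Both criteria scale with exposure (a uniform gain moves the histogram
and its triangle threshold together, and scales chroma the same way),
which is what makes the segmentation "invariant to light conditions";
the test suite checks mask stability under a 0.7 gain.

### Regional maxima

A candidate is a connected set (8-connectivity by default) of
equal-valued ROI pixels whose ROI-adjacent neighbours are all strictly
lower. Pixels outside the ROI are ignored when judging neighbours, so
plateaus on the ROI boundary are kept — boundary flowers are real. Two
degenerate cases are excluded: a plateau covering the whole ROI (a
constant region carries no peak information) and plateaus smaller than
`min_candidate_area` (default 1, i.e. no cut; raising it to 2–3 is a
useful guard on very noisy sensors). An optional h-maxima depth
(`h_maxima`, default 0 = off) suppresses shallow peaks by morphological
reconstruction before component analysis.

The implementation (built on `skimage.morphology.local_maxima` over a
ROI-masked raster) is cross-checked in the tests against an independent
brute-force oracle that flood-fills every plateau and inspects all its
neighbours, with exact plateau-set equality on hundreds of random maps,
and is invariant under strictly increasing remappings of the lightness
values — regional maxima depend only on the ordering of values, a
property the tests verify directly.

### Statistical post-filters

*Size*: candidates with area above `median + k·MAD` (raw median
absolute deviation, `size_filter_k` default 3) are removed. Only an
upper fence is applied — the filter exists to remove blobs larger than
a flower highlight (reflections on leaves, merged glints), not small
ones. When every area is identical, MAD = 0 and the fence degenerates
to `median + k`, so a homogeneous population is never pruned. The fence
is estimated once from the incoming population (single pass); the
filter is deliberately not idempotent under re-application, and a test
pins the single-pass behavior of the pipeline.

*Shape*: the elongation of each candidate is the axis ratio of the
ellipse with the same second moments as its pixel set; candidates above
`elongation_threshold` (default 2.0) are removed as elongated glints.
Degenerate moment matrices are handled explicitly: regions of ≤ 3
pixels are pinned to elongation 1 (a 1–3 pixel set carries no usable
anisotropy evidence) and larger single-file regions get a half-pixel
quadrature term (+1/12 per eigenvalue, the second moment of a unit
pixel) so a zero minor axis never divides; a 1×10 pixel line still
scores elongation ≈ 10 and is removed.

Filter order is size → shape, applied sequentially without
re-estimation between stages.

## Matching and metrics

Detections are matched to gold-standard centers greedily in increasing
distance order within a radius; ties are broken by index order so the
result is deterministic, and permutation tests confirm the TP/FP/FN
counts do not depend on detection order. Redundant detections of an
already-claimed flower are false positives. Greedy matching is provably
optimal when truth points are separated by more than twice the radius
(each detection can then reach at most one truth), which the tests
assert exactly in that regime against an optimal bipartite matching
oracle.

The default matching radius is half the median nearest-neighbour
distance among the truth centers of the image: it adapts to flower
scale, is comfortably larger than the systematic offset between a
highlight and its flower's geometric center (≈ 0.4 × flower radius
toward the light), and stays below the spacing at which neighbouring
flowers would be confused. With fewer than two truth points the rule is
undefined and a 5 px fallback applies. Undefined metrics (no truths, or
no detections) are carried as missing and skipped in per-set averaging,
never coerced to zero; set-level R̄C / P̄C are unweighted per-image
means, not pooled counts.

## Synthetic scenes

The generator renders, per scene: a uniform sRGB background at L\* = 3;
`distractor_count` elongated saturated streaks (stem-glint stand-ins,
aspect ≥ 3, painted first); `n_flowers` orthographic Lambertian spheres
(ambient 0.30, greenish-white albedo) each with one Gaussian specular
spot (σ = 2.2 px, amplitude 150·`highlight_gain`) offset toward a fixed
oblique light; a multiplicative horizontal illumination ramp of
relative span `illumination_gradient`; per-pixel Gaussian sensor noise
(`noise_sigma`); sensor clipping to [0, 255]; a mild Gaussian firmware
blur (`camera_blur_sigma` = 0.6) emulating demosaicing/JPEG smoothing;
and 8-bit quantization. All randomness flows from one seed; identical
parameters give bit-identical scenes, which is why no fixture images
are stored anywhere.

Two rendering choices matter for realism of the *detection problem*:

- Highlights and glints are bright enough to saturate the sensor, as
  real specular reflections facing the sun are. Saturation produces
  flat plateaus that survive noise — without it, quantized sensor noise
  fragments every smooth peak into many spurious maxima, which is not
  what protocol-compliant field photos look like after in-camera
  processing.
- The specular spot size is governed by the light source's angular size
  and surface gloss, not the organ radius, so plateau areas form the
  tight unimodal population the size fence presumes.

A fraction `crowding` of flowers is attached in overlapping contact
(0.6–0.9 of the radius sum) to previously placed flowers, emulating
compact clusters: a later-drawn neighbour can occlude its host's
highlight, typically leaving a crescent-shaped edge maximum that the
shape filter then (correctly) discards — the mechanism by which
compactness costs recall here. All pairwise center distances still
respect `min_center_separation`.

Default difficulty — frozen after a one-time calibration and not
revisited — is a 1080×1440 frame (~1.6 Mpx, i.e. at the analysis
resolution), 40–60 flowers of radius 9–13 px, crowding 0.15, a 20%
illumination ramp, noise σ = 2 and 3 distractors.

**What the benchmark does not show.** The generator has no leaves, no
out-of-focus blur, no 3-D cluster occlusion beyond disc overlap, no
cultivar-specific morphology and no exposure failures; flowers are
perfect spheres with exactly one highlight. Passing the synthetic
bounds therefore demonstrates that the algorithm and its default
parameters behave correctly on protocol-compliant scenes of realistic
geometry and noise — not that the same figures would be obtained on any
particular field data set.

## Benchmark figures

`scripts/acceptance.py` (and the mirror tests in
`tests/test_acceptance.py`) render 30 seeded default-difficulty scenes,
run the default pipeline, and report mean per-image recall and
precision. 30 images keeps the full recomputation around half a minute
on one CPU while bounding the standard error of the means well below
the margins involved. Difficulty monotonicity (recall non-increasing in
crowding and in noise) is asserted over 20 seeds per level with a 0.01
allowance between adjacent levels, since the per-level means carry
roughly ±0.5% sampling jitter at that replication.

## Known limitations

- The ROI criterion presumes the protocol; scenes on bright or
  chromatic backgrounds will segment poorly (by design, the tool
  refuses frames with no dark-background structure rather than
  guessing).
- The size fence assumes highlights of one characteristic scale; a
  scene mixing very near and very far flowers would widen the area
  distribution and weaken the fence.
- Elongation cannot separate a circular non-flower glint from a flower;
  such distractors survive the filters.
- Counting stops at the 2-D image: estimating the true 3-D flower
  number per inflorescence requires a separate calibration and is out
  of scope.
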