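"""Flower detection in inflorescence photographs.

The detector exploits the acquisition protocol — one inflorescence
photographed against dark, achromatic cardboard — and the near-spherical
geometry of individual grapevine flowers, each of which reflects light as
a single bright, quasi-circular highlight.  The pipeline has three
stages:

1. *Pre-processing*: the image is downscaled to at most ~2 Mpx and the
   inflorescence is segmented from the dark background (region of
   interest, ROI) using a lightness/chroma criterion that is robust to
   exposure changes.
2. *Analysis*: flower candidates are the connected components that are
   regional maxima of the CIE 1976 L* (lightness) channel inside the
   ROI — the operational signature of one specular highlight per flower.
3. *Post-processing*: two statistical filters remove candidates that are
   not flowers: a robust size fence (``median + k·MAD``) removes
   oversized blobs, and a moment-ellipse elongation cut removes
   elongated glints (stems, rachis edges).

Surviving candidates are counted as flowers; their centroids are the
reported flower centers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import color as skcolor
from skimage import morphology as skmorph
from skimage import transform as sktransform
from skimage.filters import threshold_triangle
from skimage.measure import label as sklabel

from .config import PipelineConfig

__all__ = [
    "InvalidInputError",
    "SegmentationError",
    "ROIMask",
    "CandidateRegion",
    "DetectionResult",
    "downscale_image",
    "to_lightness",
    "segment_roi",
    "find_regional_maxima",
    "filter_by_size",
    "filter_by_shape",
    "count_flowers",
    "annotate_image",
]

# In automatic threshold mode, pixels at or below this L* are always
# background: the protocol guarantees dark cardboard, and a photo whose
# foreground never rises above it carries no inflorescence to segment.
_MIN_AUTO_LIGHTNESS = 10.0


class InvalidInputError(ValueError):
    """Raised when an input image or argument violates a precondition."""


class SegmentationError(RuntimeError):
    """Raised when no inflorescence foreground can be segmented.

    The remedy is re-acquisition: the photograph must show the
    inflorescence against dark cardboard, in focus and not underexposed.
    """


@dataclass(frozen=True, eq=False)
class ROIMask:
    """Boolean inflorescence mask with the same shape as its image."""

    mask: np.ndarray

    @property
    def coverage_fraction(self) -> float:
        return float(self.mask.mean())


@dataclass(frozen=True, eq=False)
class CandidateRegion:
    """One connected regional-maximum plateau and its shape descriptors.

    ``major_axis``/``minor_axis`` are the axes of the ellipse with the
    same second moments as the pixel set (the regionprops convention,
    4·sqrt(eigenvalue)); ``elongation`` is their ratio, pinned to 1 for
    degenerate regions of up to 3 pixels and otherwise computed with a
    half-pixel quadrature term so a zero moment never divides.
    """

    pixels: np.ndarray  # (n, 2) int array of (row, col)
    area: int
    centroid: tuple[float, float]
    major_axis: float
    minor_axis: float
    elongation: float


@dataclass(frozen=True)
class DetectionResult:
    """Outcome of the full pipeline on one image.

    Centers and stage counts refer to the analyzed (possibly downscaled)
    image; ``scale_factor`` (analyzed pixels per original pixel) maps
    them back to original coordinates.
    """

    centers: list[tuple[float, float]]
    count: int
    n_raw_candidates: int
    n_after_size_filter: int
    n_after_shape_filter: int
    scale_factor: float
    analyzed_shape: tuple[int, int]

    def centers_original_scale(self) -> list[tuple[float, float]]:
        """Detected centers mapped back to original-image coordinates."""
        s = self.scale_factor
        return [(r / s, c / s) for r, c in self.centers]


def _validate_rgb(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise InvalidInputError(f"expected H×W×3 RGB array, got shape {image.shape}")
    if image.shape[0] < 1 or image.shape[1] < 1 or image.size == 0:
        raise InvalidInputError("empty image")
    if image.dtype != np.uint8:
        if np.issubdtype(image.dtype, np.integer) and image.min() >= 0 and image.max() <= 255:
            image = image.astype(np.uint8)
        else:
            raise InvalidInputError("RGB image must hold 8-bit channel values in [0, 255]")
    return image


def downscale_image(
    image: np.ndarray, target_megapixels: float = 2.0
) -> tuple[np.ndarray, float]:
    """Downscale ``image`` so its area is at most ``target_megapixels``.

    The linear scale factor is ``sqrt(target_px / current_px)`` so the
    aspect ratio is preserved; resampling is anti-aliased area
    averaging.  Images already at or below the target pass through
    unchanged — the function never upscales.

    Returns
    -------
    (resized_image, scale_factor)
        ``scale_factor`` is analyzed pixels per original pixel (1.0 when
        unchanged).
    """
    image = _validate_rgb(image)
    if target_megapixels <= 0:
        raise InvalidInputError("target_megapixels must be > 0")
    h, w = image.shape[:2]
    target_px = target_megapixels * 1e6
    if h * w <= target_px:
        return image, 1.0
    scale = float(np.sqrt(target_px / (h * w)))
    new_h = max(1, int(h * scale))
    new_w = max(1, int(w * scale))
    resized = sktransform.resize(
        image, (new_h, new_w), anti_aliasing=True, preserve_range=True
    )
    return np.clip(np.rint(resized), 0, 255).astype(np.uint8), scale


def _rgb_to_lab(image: np.ndarray) -> np.ndarray:
    # sRGB with D65 white — the default tagging of phone JPEGs.
    return skcolor.rgb2lab(image)


def to_lightness(image: np.ndarray) -> np.ndarray:
    """CIE 1976 L* channel (0–100) of an sRGB image under D65."""
    return _rgb_to_lab(_validate_rgb(image))[..., 0]


def segment_roi(
    image: np.ndarray,
    config: PipelineConfig | None = None,
    *,
    lab: np.ndarray | None = None,
) -> ROIMask:
    """Segment the inflorescence from the dark cardboard background.

    Background pixels are both dark (L* at or below an automatic
    bimodal-histogram threshold, or the configured fixed threshold) and
    achromatic (chroma sqrt(a*² + b*²) at or below the configured
    ceiling); everything else is foreground.  The dual criterion
    tolerates exposure/gain changes: dimming the scene moves both the
    histogram and the automatic threshold.  Foreground specks smaller
    than ``min_foreground_fraction`` of the image area are removed.

    Raises
    ------
    SegmentationError
        If every pixel is classified as background.
    """
    config = config or PipelineConfig()
    image = _validate_rgb(image)
    if lab is None:
        lab = _rgb_to_lab(image)
    lightness = lab[..., 0]
    chroma = np.hypot(lab[..., 1], lab[..., 2])

    if config.background_lightness_threshold is not None:
        threshold = float(config.background_lightness_threshold)
    else:
        # triangle (histogram-shape) threshold: with a dominant dark
        # background peak it lands just past the peak's foot, keeping
        # even dimly lit organ pixels, where Otsu would split the broad
        # foreground mode instead
        try:
            threshold = float(threshold_triangle(lightness))
        except ValueError:  # constant image: nothing to separate
            threshold = float(lightness.max())
        threshold = max(threshold, _MIN_AUTO_LIGHTNESS)

    background = (lightness <= threshold) & (chroma <= config.background_chroma_ceiling)
    foreground = ~background
    min_size = max(1, int(np.ceil(config.min_foreground_fraction * lightness.size)))
    if min_size > 1:
        foreground = skmorph.remove_small_objects(
            foreground, max_size=min_size - 1, connectivity=2 if config.connectivity == 8 else 1
        )
    if not foreground.any():
        raise SegmentationError(
            "no inflorescence found: every pixel classified as background; "
            "re-acquire the photo against dark cardboard with the "
            "inflorescence in frame"
        )
    return ROIMask(mask=foreground)


def _shape_descriptors(coords: np.ndarray) -> tuple[tuple[float, float], float, float, float]:
    """Centroid, moment-ellipse axes and elongation of a pixel set."""
    centroid = (float(coords[:, 0].mean()), float(coords[:, 1].mean()))
    n = coords.shape[0]
    if n == 1:
        return centroid, 0.0, 0.0, 1.0
    centered = coords - coords.mean(axis=0)
    cov = centered.T @ centered / n
    eigvals = np.linalg.eigvalsh(cov)  # ascending
    lam_min, lam_max = float(eigvals[0]), float(eigvals[1])
    if lam_min < 1e-9:
        if n <= 3:
            return centroid, 4.0 * np.sqrt(lam_max), 0.0, 1.0
        # half-pixel quadrature: each pixel occupies a unit square whose
        # own second moment is 1/12, so a one-pixel-wide region still has
        # finite width
        lam_min += 1.0 / 12.0
        lam_max += 1.0 / 12.0
    major = 4.0 * float(np.sqrt(lam_max))
    minor = 4.0 * float(np.sqrt(lam_min))
    return centroid, major, minor, float(np.sqrt(lam_max / lam_min))


def find_regional_maxima(
    lightness: np.ndarray,
    roi: ROIMask | np.ndarray,
    config: PipelineConfig | None = None,
) -> list[CandidateRegion]:
    """Connected regional-maxima plateaus of ``lightness`` inside the ROI.

    A candidate is a connected set of equal-valued ROI pixels whose ROI
    neighbours (under the configured connectivity) are all strictly
    lower; pixels outside the ROI are ignored, so plateaus touching the
    ROI boundary are kept.  A plateau covering the entire ROI is
    degenerate (a constant region carries no peak) and is discarded, as
    are plateaus smaller than ``min_candidate_area``.  With
    ``h_maxima > 0``, maxima shallower than that depth are suppressed
    first (off by default).
    """
    config = config or PipelineConfig()
    mask = roi.mask if isinstance(roi, ROIMask) else np.asarray(roi, dtype=bool)
    lightness = np.asarray(lightness, dtype=float)
    if lightness.shape != mask.shape:
        raise InvalidInputError(
            f"lightness shape {lightness.shape} != ROI shape {mask.shape}"
        )
    if not mask.any():
        return []
    conn = 2 if config.connectivity == 8 else 1
    # sink everything outside the ROI below the valid L* range so ROI
    # plateaus never see a higher non-ROI neighbour
    fill = float(lightness[mask].min()) - 1.0
    work = np.where(mask, lightness, fill)
    if config.h_maxima > 0:
        maxima = skmorph.h_maxima(work, config.h_maxima, footprint=None) > 0
    else:
        maxima = skmorph.local_maxima(work, connectivity=conn, allow_borders=True)
    maxima &= mask
    labels, n_labels = sklabel(maxima, connectivity=conn, return_num=True)
    roi_area = int(mask.sum())
    candidates: list[CandidateRegion] = []
    for lab_id in range(1, n_labels + 1):
        coords = np.argwhere(labels == lab_id)
        area = coords.shape[0]
        if area < config.min_candidate_area or area == roi_area:
            continue
        centroid, major, minor, elong = _shape_descriptors(coords)
        candidates.append(
            CandidateRegion(
                pixels=coords,
                area=area,
                centroid=centroid,
                major_axis=major,
                minor_axis=minor,
                elongation=elong,
            )
        )
    return candidates


def filter_by_size(
    candidates: list[CandidateRegion], config: PipelineConfig | None = None
) -> list[CandidateRegion]:
    """Remove candidates larger than a robust upper size fence.

    The fence is ``median(areas) + k · MAD(areas)`` with the raw
    (unscaled) median absolute deviation; when every area is identical
    (MAD = 0) the fence degenerates to ``median + k`` so a homogeneous
    population is never pruned.  Only an upper cut is applied — the
    filter targets blobs larger than a flower highlight.  Single pass:
    the fence is estimated once from the incoming population, never
    re-estimated from survivors.
    """
    config = config or PipelineConfig()
    if not candidates:
        return []
    areas = np.array([c.area for c in candidates], dtype=float)
    med = float(np.median(areas))
    mad = float(np.median(np.abs(areas - med)))
    fence = med + config.size_filter_k * (mad if mad > 0 else 1.0)
    return [c for c in candidates if c.area <= fence]


def filter_by_shape(
    candidates: list[CandidateRegion], config: PipelineConfig | None = None
) -> list[CandidateRegion]:
    """Remove elongated candidates.

    A flower highlight is quasi-circular; glints along stems and rachis
    edges are not.  Candidates whose moment-ellipse elongation exceeds
    the threshold are dropped; degenerate tiny regions carry elongation
    1 and are always retained.
    """
    config = config or PipelineConfig()
    return [c for c in candidates if c.elongation <= config.elongation_threshold]


def count_flowers(image: np.ndarray, config: PipelineConfig | None = None) -> DetectionResult:
    """Run the full detection pipeline and count flowers.

    Composes downscaling, ROI segmentation, lightness extraction,
    regional-maxima candidate detection and the size and shape filters.
    Deterministic: a fixed image and config always yield a bit-identical
    result.  An image in which every candidate is filtered out yields a
    count of zero, not an error; a photo with no segmentable foreground
    raises :class:`SegmentationError`.
    """
    config = config or PipelineConfig()
    image = _validate_rgb(image)
    analyzed, scale = downscale_image(image, config.target_megapixels)
    lab = _rgb_to_lab(analyzed)
    roi = segment_roi(analyzed, config, lab=lab)
    raw = find_regional_maxima(lab[..., 0], roi, config)
    sized = filter_by_size(raw, config)
    shaped = filter_by_shape(sized, config)
    return DetectionResult(
        centers=[c.centroid for c in shaped],
        count=len(shaped),
        n_raw_candidates=len(raw),
        n_after_size_filter=len(sized),
        n_after_shape_filter=len(shaped),
        scale_factor=scale,
        analyzed_shape=analyzed.shape[:2],
    )


def annotate_image(
    image: np.ndarray,
    result: DetectionResult,
    *,
    arm_length: int = 8,
    color: tuple[int, int, int] = (255, 0, 0),
) -> np.ndarray:
    """Draw a red cross at each detected flower center.

    Crosses are drawn on a copy of the ORIGINAL-resolution image;
    centers are mapped back through the result's scale factor.  Pixels
    outside the crosses are untouched.
    """
    image = _validate_rgb(image)
    out = image.copy()
    h, w = out.shape[:2]
    for r, c in result.centers_original_scale():
        ri, ci = int(round(r)), int(round(c))
        if not (0 <= ri < h and 0 <= ci < w):
            raise InvalidInputError(f"center ({r:.1f}, {c:.1f}) outside image bounds")
        r0, r1 = max(0, ri - arm_length), min(h, ri + arm_length + 1)
        c0, c1 = max(0, ci - arm_length), min(w, ci + arm_length + 1)
        out[r0:r1, ci] = color
        out[ri, c0:c1] = color
    return out
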