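"""Seeded synthetic inflorescence scenes with ground truth.

Real evaluation images (field photographs with manually labelled flower
centers) are not distributable, so this module renders controlled
stand-ins that reproduce the acquisition protocol the detector assumes:
a near-black, low-chroma cardboard background and dozens-to-hundreds of
quasi-spherical flowers, each shaded as a Lambertian sphere carrying one
specular highlight offset toward the light.  Difficulty knobs emulate
the factors that degrade field performance: contact crowding of flower
buttons (compact cultivars), illumination gradients, sensor noise, and
elongated bright distractors standing in for stem and rachis glints.

Every scene is a pure function of its :class:`SceneParams` (the seed
included), so fixtures are reproducible bit-for-bit and never stored.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage import color as skcolor

__all__ = [
    "PlacementError",
    "SceneParams",
    "GroundTruth",
    "generate_scene",
    "generate_benchmark_set",
]


class PlacementError(RuntimeError):
    """Raised when the requested flowers cannot be placed in the frame."""


@dataclass(frozen=True)
class SceneParams:
    """Parameters of one synthetic scene.

    The defaults define the standard benchmark difficulty: a ~1.6 Mpx
    frame with 50 flowers of 9–14 px radius, 15% of them in contact
    clusters, a 20% corner-to-corner illumination ramp, mild sensor
    noise and three stem-glint distractors.

    ``min_center_separation`` is a hard lower bound on every pairwise
    center distance (contact clusters included); free-standing flowers
    are additionally kept from touching.  ``camera_blur_sigma`` models
    the mild low-pass of demosaicing and JPEG compression applied by
    real camera firmware after the sensor noise.
    """

    image_size: tuple[int, int] = (1080, 1440)
    n_flowers: int = 50
    flower_radius_range: tuple[float, float] = (9.0, 14.0)
    min_center_separation: float = 14.0
    crowding: float = 0.15
    background_lightness: float = 3.0
    highlight_gain: float = 1.0
    illumination_gradient: float = 0.2
    noise_sigma: float = 2.0
    distractor_count: int = 3
    camera_blur_sigma: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        rmin, rmax = self.flower_radius_range
        if rmin > rmax or rmin <= 0:
            raise ValueError("flower_radius_range must satisfy 0 < min <= max")
        if self.n_flowers < 0 or self.distractor_count < 0:
            raise ValueError("counts must be >= 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if not 0 <= self.crowding <= 1:
            raise ValueError("crowding must lie in [0, 1]")

    def replace(self, **changes) -> "SceneParams":
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True, eq=False)
class GroundTruth:
    """Gold-standard annotation for one synthetic scene."""

    centers: list[tuple[float, float]]
    flower_mask: np.ndarray
    params_used: SceneParams


def _lab_grey_to_srgb(lightness: float) -> np.ndarray:
    """8-bit sRGB grey with the requested CIE L* (achromatic)."""
    rgb = skcolor.lab2rgb(np.array([[[lightness, 0.0, 0.0]]]))[0, 0]
    return np.clip(rgb * 255.0, 0, 255)


def _place_flowers(
    params: SceneParams, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Sample flower centers and radii honouring the separation rules.

    Free-standing flowers keep clear of each other (no disc contact);
    crowded flowers are attached in contact with a previously placed
    flower.  All pairs respect ``min_center_separation``.
    """
    h, w = params.image_size
    n = params.n_flowers
    if n == 0:
        return np.empty((0, 2)), np.empty(0)
    rmin, rmax = params.flower_radius_range
    margin = rmax + 3.0
    if h - 2 * margin <= 0 or w - 2 * margin <= 0:
        raise PlacementError("image too small for the flower radius range")
    # crude capacity check before attempting rejection sampling
    sep_free = max(params.min_center_separation, 2.0 * rmax + 2.0)
    if n * (sep_free / 2.0) ** 2 * np.pi > 0.7 * (h - 2 * margin) * (w - 2 * margin):
        raise PlacementError(
            f"cannot place {n} flowers at separation {sep_free:.0f}px "
            f"in a {h}x{w} frame"
        )
    n_crowd = int(round(params.crowding * n))
    n_free = max(n - n_crowd, 1 if n else 0)  # a cluster needs a seed flower
    centers: list[np.ndarray] = []
    radii: list[float] = []

    def min_dist(p: np.ndarray) -> float:
        if not centers:
            return np.inf
        return float(np.min(np.linalg.norm(np.array(centers) - p, axis=1)))

    attempts = 0
    while len(centers) < n_free:
        attempts += 1
        if attempts > 200 * n:
            raise PlacementError("free-flower separation constraint unsatisfiable")
        p = rng.uniform([margin, margin], [h - margin, w - margin])
        if min_dist(p) >= sep_free:
            centers.append(p)
            radii.append(float(rng.uniform(rmin, rmax)))
    attempts = 0
    while len(centers) < n:
        attempts += 1
        if attempts > 500 * max(1, n_crowd):
            raise PlacementError("contact-cluster separation constraint unsatisfiable")
        host = rng.integers(0, len(centers))
        r_new = float(rng.uniform(rmin, rmax))
        theta = rng.uniform(0, 2 * np.pi)
        # overlapping contact, as in compact clusters: the later-drawn
        # flower can occlude its host's highlight
        contact = float(rng.uniform(0.6, 0.9))
        dist = max((radii[host] + r_new) * contact, params.min_center_separation)
        p = centers[host] + dist * np.array([np.sin(theta), np.cos(theta)])
        if not (margin <= p[0] <= h - margin and margin <= p[1] <= w - margin):
            continue
        others = [c for i, c in enumerate(centers) if i != host]
        if others and float(
            np.min(np.linalg.norm(np.array(others) - p, axis=1))
        ) < params.min_center_separation:
            continue
        centers.append(p)
        radii.append(r_new)
    return np.array(centers), np.array(radii)


def _render_flower(
    canvas: np.ndarray,
    mask: np.ndarray,
    center: np.ndarray,
    radius: float,
    light: np.ndarray,
    highlight_gain: float,
) -> None:
    """Paint one shaded quasi-sphere with a specular highlight in place."""
    h, w = canvas.shape[:2]
    r0 = max(0, int(np.floor(center[0] - radius)))
    r1 = min(h, int(np.ceil(center[0] + radius)) + 1)
    c0 = max(0, int(np.floor(center[1] - radius)))
    c1 = min(w, int(np.ceil(center[1] + radius)) + 1)
    rows = np.arange(r0, r1)[:, None] - center[0]
    cols = np.arange(c0, c1)[None, :] - center[1]
    d2 = rows**2 + cols**2
    inside = d2 <= radius**2
    if not inside.any():
        return
    # orthographic sphere: surface normal at each pixel
    z = np.sqrt(np.maximum(radius**2 - d2, 0.0))
    nr, nc, nz = rows / radius, cols / radius, z / radius
    shading = np.clip(nr * light[0] + nc * light[1] + nz * light[2], 0.0, 1.0)
    ambient = 0.30
    albedo = np.array([205.0, 215.0, 188.0])  # greenish-white flower button
    body = (ambient + (1.0 - ambient) * shading)[..., None] * albedo
    # specular highlight where the normal points at the light; bright
    # enough to saturate the 8-bit sensor at its core, as real flower
    # glints do when facing the sun (the clip happens at sensor read-out)
    hl_r = center[0] + radius * light[0]
    hl_c = center[1] + radius * light[1]
    # spot size is set by the source's angular size and the waxy gloss
    # of the organ surface, not by the organ radius
    sigma = 2.2
    spec = 150.0 * highlight_gain * np.exp(
        -(((rows + center[0]) - hl_r) ** 2 + ((cols + center[1]) - hl_c) ** 2)
        / (2.0 * sigma**2)
    )
    patch = canvas[r0:r1, c0:c1]
    patch[inside] = body[inside] + spec[inside][:, None]
    mask[r0:r1, c0:c1] |= inside


def _render_distractor(canvas: np.ndarray, rng: np.random.Generator) -> None:
    """Paint one elongated bright streak (stem glint stand-in).

    Constant intensity along the streak axis with a Gaussian cross
    profile, saturating the sensor at its core so its ridge is a long
    thin plateau — exactly the configuration the statistical post
    filters exist to reject (aspect >= 3).
    """
    h, w = canvas.shape[:2]
    length = float(rng.uniform(45, 80))
    half_width = float(rng.uniform(1.6, 2.4))
    theta = float(rng.uniform(0, np.pi))
    cr = float(rng.uniform(0.1 * h, 0.9 * h))
    cc = float(rng.uniform(0.1 * w, 0.9 * w))
    axis = np.array([np.sin(theta), np.cos(theta)])
    r0 = max(0, int(cr - length)); r1 = min(h, int(cr + length) + 1)
    c0 = max(0, int(cc - length)); c1 = min(w, int(cc + length) + 1)
    rows = np.arange(r0, r1)[:, None] - cr
    cols = np.arange(c0, c1)[None, :] - cc
    along = rows * axis[0] + cols * axis[1]
    across = -rows * axis[1] + cols * axis[0]
    # flat saturated core with Gaussian shoulders: a specular glint on a
    # cylindrical stem saturates along a band, not just a hairline
    d = np.maximum(np.abs(across) - half_width, 0.0)
    profile = 300.0 * np.exp(-(d**2) / (2 * 1.5**2))
    profile[np.abs(along) > length / 2] = 0.0
    streak = profile[..., None] * np.array([1.0, 1.0, 0.93])
    patch = canvas[r0:r1, c0:c1]
    np.maximum(patch, streak, out=patch)


def generate_scene(params: SceneParams) -> tuple[np.ndarray, GroundTruth]:
    """Render one synthetic inflorescence photograph plus its truth.

    Returns the 8-bit RGB image and a :class:`GroundTruth` whose centers
    are the flower disc centers (row, col) and whose ``flower_mask``
    marks every flower pixel.  Identical params (seed included) yield a
    bit-identical image.
    """
    rng = np.random.default_rng(params.seed)
    h, w = params.image_size
    bg = _lab_grey_to_srgb(params.background_lightness)
    canvas = np.ones((h, w, 3), dtype=float) * bg
    mask = np.zeros((h, w), dtype=bool)

    # fixed oblique light, tilted toward the camera
    light = np.array([-0.35, 0.25, 1.0])
    light /= np.linalg.norm(light)

    for _ in range(params.distractor_count):
        _render_distractor(canvas, rng)

    centers, radii = _place_flowers(params, rng)
    for center, radius in zip(centers, radii):
        _render_flower(canvas, mask, center, radius, light, params.highlight_gain)

    if params.illumination_gradient > 0:
        ramp = 1.0 + params.illumination_gradient * (
            np.arange(w) / max(w - 1, 1) - 0.5
        )
        canvas *= ramp[None, :, None]

    if params.noise_sigma > 0:
        canvas += rng.normal(0.0, params.noise_sigma, canvas.shape)
    # sensor read-out clips at full well; firmware low-pass follows it,
    # so saturated highlight cores stay flat plateaus as in real JPEGs
    canvas = np.clip(canvas, 0.0, 255.0)
    if params.camera_blur_sigma > 0:
        canvas = gaussian_filter(canvas, sigma=(params.camera_blur_sigma,) * 2 + (0,))

    image = np.clip(np.rint(canvas), 0, 255).astype(np.uint8)
    truth = GroundTruth(
        centers=[(float(r), float(c)) for r, c in centers],
        flower_mask=mask,
        params_used=params,
    )
    return image, truth


def generate_benchmark_set(
    n_images: int,
    params: SceneParams | None = None,
    seed: int = 0,
    count_range: tuple[int, int] = (40, 60),
) -> list[tuple[np.ndarray, GroundTruth]]:
    """Generate a reproducible benchmark set of scenes.

    Per-image seeds and flower counts (uniform over ``count_range``)
    are drawn deterministically from the master ``seed``; everything
    else follows ``params``.
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    params = params or SceneParams()
    master = np.random.default_rng(seed)
    scenes = []
    for _ in range(n_images):
        child_seed = int(master.integers(0, 2**31 - 1))
        n_flowers = int(master.integers(count_range[0], count_range[1] + 1))
        scenes.append(
            generate_scene(params.replace(seed=child_seed, n_flowers=n_flowers))
        )
    return scenes
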