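"""Red/blue/white stain segmentation and percent-collagen measurement.

The classification chain is: sRGB -> CIE L*a*b* -> two-cluster k-means on
the (a*, b*) chroma plane -> cluster-to-class rule (smaller b* centroid is
the collagen "blue" cluster) -> uniform lightness mask overriding cluster
labels with "white" -> morphological closing of the red and blue regions ->
pixel counts.  Percent collagen is the blue area divided by the area of the
entire image (white included) unless ``tissue_denominator`` is set.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
from scipy import ndimage
from skimage import color as skcolor

__all__ = [
    "RgbImage",
    "LabImage",
    "ClusterModel",
    "ClassMask",
    "CollagenMeasurement",
    "SegmentationConfig",
    "RED",
    "BLUE",
    "WHITE",
    "rgb_to_lab",
    "cluster_ab",
    "label_clusters",
    "lightness_mask",
    "close_regions",
    "disk_footprint",
    "segment_image",
    "render_overlay",
]

# ClassMask label codes
RED = 0
BLUE = 1
WHITE = 2

CLASS_NAMES = {RED: "red", BLUE: "blue", WHITE: "white"}

# Overlay tint colours (sRGB) per class code.
_OVERLAY_COLOURS = {
    RED: (220, 40, 40),
    BLUE: (40, 70, 220),
    WHITE: (245, 245, 245),
}


@dataclass(frozen=True)
class RgbImage:
    """8-bit sRGB raster with an optional physical pixel size (um/px)."""

    pixels: np.ndarray
    pixel_size: Optional[float] = None

    def __post_init__(self):
        px = self.pixels
        if not isinstance(px, np.ndarray):
            raise TypeError("pixels must be a numpy array")
        if px.ndim != 3 or px.shape[2] not in (3, 4):
            raise ValueError(
                f"expected an H x W x 3 RGB (or H x W x 4 RGBA) array, got shape {px.shape}"
            )
        if px.dtype != np.uint8:
            raise ValueError(f"expected 8-bit (uint8) pixel data, got dtype {px.dtype}")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("image must have at least one pixel")
        if px.shape[2] == 4:  # RGBA accepted, alpha dropped
            object.__setattr__(self, "pixels", np.ascontiguousarray(px[:, :, :3]))

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[0], self.pixels.shape[1]


@dataclass(frozen=True)
class LabImage:
    """CIE L*a*b* planes (D65, 2 degree observer)."""

    L: np.ndarray
    a: np.ndarray
    b: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.L.shape


@dataclass
class ClusterModel:
    """Two-centroid k-means model over the (a*, b*) plane.

    ``class_map`` maps cluster index -> "red" / "blue"; it is filled by
    :func:`label_clusters`.  ``degenerate`` flags the single-effective-cluster
    case (all chroma values identical).
    """

    centroids: np.ndarray          # (2, 2) array of (a*, b*)
    assignment: np.ndarray         # H x W int array over {0, 1}
    inertia: float
    degenerate: bool = False
    class_map: Optional[dict[int, str]] = None


@dataclass(frozen=True)
class ClassMask:
    """Per-pixel labels over {red, blue, white} (codes RED/BLUE/WHITE)."""

    labels: np.ndarray

    def counts(self) -> dict[str, int]:
        return {
            "red": int(np.count_nonzero(self.labels == RED)),
            "blue": int(np.count_nonzero(self.labels == BLUE)),
            "white": int(np.count_nonzero(self.labels == WHITE)),
        }


@dataclass(frozen=True)
class CollagenMeasurement:
    blue_px: int
    red_px: int
    white_px: int
    total_px: int
    percent_collagen: float
    degenerate: bool = False
    config_hash: str = ""

    def __post_init__(self):
        if self.blue_px + self.red_px + self.white_px != self.total_px:
            raise ValueError("class pixel counts must sum to total_px")


@dataclass(frozen=True)
class SegmentationConfig:
    """Every tunable of the chain, with the documented defaults.

    lightness_threshold: pixels with L* above it are masked white (default 85).
    closing_radius_px: disk radius for morphological closing (default 3).
    mask_before_cluster: cluster only non-white pixels (non-default variant).
    tissue_denominator: divide by (total - white) instead of the entire image.
    """

    lightness_threshold: float = 85.0
    closing_radius_px: int = 3
    kmeans_seed: int = 0
    kmeans_restarts: int = 5
    kmeans_tol: float = 1e-6
    mask_before_cluster: bool = False
    tissue_denominator: bool = False

    def __post_init__(self):
        if not (0.0 < self.lightness_threshold <= 100.0):
            raise ValueError("lightness_threshold must be in (0, 100]")
        if self.closing_radius_px < 1:
            raise ValueError("closing_radius_px must be a positive integer")
        if self.kmeans_restarts < 1:
            raise ValueError("kmeans_restarts must be a positive integer")
        if self.kmeans_tol <= 0:
            raise ValueError("kmeans_tol must be positive")

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def rgb_to_lab(img: RgbImage) -> LabImage:
    """Convert 8-bit sRGB to CIE L*a*b* (D65 white point, 2 degree observer)."""
    lab = skcolor.rgb2lab(img.pixels)
    return LabImage(L=lab[:, :, 0], a=lab[:, :, 1], b=lab[:, :, 2])


def _kmeans_two(points: np.ndarray, seed: int, restarts: int, tol: float,
                max_iter: int = 300) -> tuple[np.ndarray, np.ndarray, float]:
    """Deterministic Lloyd k-means with k=2 and k-means++ seeding.

    Returns (centroids, labels, inertia) of the best restart by within-cluster
    sum of squares.
    """
    n = points.shape[0]
    rng = np.random.default_rng(seed)
    best: tuple[float, np.ndarray, np.ndarray] | None = None
    for _ in range(restarts):
        # k-means++ for k=2: uniform first centre, second picked with
        # probability proportional to squared distance from the first.
        i0 = int(rng.integers(n))
        c0 = points[i0]
        d2 = np.einsum("ij,ij->i", points - c0, points - c0)
        total = d2.sum()
        if total == 0.0:
            centroids = np.stack([c0, c0])
            labels = np.zeros(n, dtype=np.int8)
            return centroids, labels, 0.0
        i1 = int(rng.choice(n, p=d2 / total))
        centroids = np.stack([c0, points[i1]]).astype(np.float64)

        prev_inertia = np.inf
        for _ in range(max_iter):
            d0 = np.einsum("ij,ij->i", points - centroids[0], points - centroids[0])
            d1 = np.einsum("ij,ij->i", points - centroids[1], points - centroids[1])
            labels = (d1 < d0).astype(np.int8)
            inertia = float(np.where(labels == 1, d1, d0).sum())
            for k in (0, 1):
                sel = labels == k
                if sel.any():
                    centroids[k] = points[sel].mean(axis=0)
            if prev_inertia - inertia <= tol * max(inertia, np.finfo(float).tiny):
                break
            prev_inertia = inertia
        if best is None or inertia < best[0]:
            best = (inertia, centroids.copy(), labels.copy())
    assert best is not None
    return best[1], best[2], best[0]


def cluster_ab(lab: LabImage, cfg: SegmentationConfig,
               include: Optional[np.ndarray] = None) -> ClusterModel:
    """k=2 k-means over the per-pixel (a*, b*) values.

    ``include`` optionally restricts the pixels fed to the clustering (used by
    the mask-before-cluster variant); excluded pixels are still assigned to
    their nearest centroid afterwards.
    """
    h, w = lab.shape
    if h * w < 2:
        raise ValueError("clustering needs at least 2 pixels")
    ab = np.stack([lab.a.ravel(), lab.b.ravel()], axis=1).astype(np.float64)
    fit_points = ab if include is None else ab[include.ravel()]
    if fit_points.shape[0] < 2:
        fit_points = ab

    if np.all(fit_points == fit_points[0]):
        centroids = np.stack([fit_points[0], fit_points[0]])
        assignment = np.zeros((h, w), dtype=np.int8)
        return ClusterModel(centroids=centroids, assignment=assignment,
                            inertia=0.0, degenerate=True)

    centroids, _, inertia = _kmeans_two(
        fit_points, cfg.kmeans_seed, cfg.kmeans_restarts, cfg.kmeans_tol
    )
    degenerate = bool(np.allclose(centroids[0], centroids[1]))
    # Assign every pixel (including any excluded from the fit).
    d0 = np.einsum("ij,ij->i", ab - centroids[0], ab - centroids[0])
    d1 = np.einsum("ij,ij->i", ab - centroids[1], ab - centroids[1])
    assignment = (d1 < d0).astype(np.int8).reshape(h, w)
    if degenerate:
        assignment = np.zeros((h, w), dtype=np.int8)
    return ClusterModel(centroids=centroids, assignment=assignment,
                        inertia=inertia, degenerate=degenerate)


def label_clusters(model: ClusterModel) -> ClusterModel:
    """Fill ``class_map``: the centroid with smaller b* is blue (collagen);
    a tie on b* is broken by assigning the larger a* centroid to red."""
    c = model.centroids
    if model.degenerate:
        # Single effective cluster: classify it by its own chroma. A centroid
        # with negative b* reads blue, otherwise red (same rule as the
        # two-cluster case applied against a neutral reference).
        cls = "blue" if c[0][1] < 0 else "red"
        other = "red" if cls == "blue" else "blue"
        model.class_map = {0: cls, 1: other}
        return model
    b0, b1 = c[0][1], c[1][1]
    if b0 < b1:
        blue_idx = 0
    elif b1 < b0:
        blue_idx = 1
    else:  # tie on b*: larger a* is red
        blue_idx = 0 if c[0][0] < c[1][0] else 1
    model.class_map = {blue_idx: "blue", 1 - blue_idx: "red"}
    return model


def lightness_mask(lab: LabImage, cfg: SegmentationConfig) -> np.ndarray:
    """Boolean mask of high-lightness ("white") pixels: L* > threshold."""
    return lab.L > cfg.lightness_threshold


def disk_footprint(radius: int) -> np.ndarray:
    """Disk structuring element: offsets with x^2 + y^2 <= r^2."""
    yy, xx = np.mgrid[-radius:radius + 1, -radius:radius + 1]
    return (yy * yy + xx * xx) <= radius * radius


def close_regions(mask: np.ndarray, cfg: SegmentationConfig) -> np.ndarray:
    """Morphological closing (dilation then erosion) with a disk of
    ``closing_radius_px``.

    Border convention: outside the image counts as background for the
    dilation and as foreground for the erosion, so closing never removes
    foreground at the frame edge (closing is extensive).
    """
    if mask.dtype != bool:
        raise ValueError("close_regions expects a boolean mask")
    fp = disk_footprint(cfg.closing_radius_px)
    dilated = ndimage.binary_dilation(mask, structure=fp, border_value=0)
    return ndimage.binary_erosion(dilated, structure=fp, border_value=1)


def _apply_closing(labels: np.ndarray, cfg: SegmentationConfig) -> np.ndarray:
    """Close the red and the blue regions independently; pixels claimed by
    both closings keep their pre-closing label, as do pixels claimed by
    neither.  Only white pixels claimed by exactly one closing flip."""
    red = labels == RED
    blue = labels == BLUE
    red_c = close_regions(red, cfg)
    blue_c = close_regions(blue, cfg)
    out = labels.copy()
    white = labels == WHITE
    out[white & red_c & ~blue_c] = RED
    out[white & blue_c & ~red_c] = BLUE
    return out


def segment_image(img: RgbImage, cfg: SegmentationConfig) -> tuple[ClassMask, CollagenMeasurement]:
    """Full chain on one image; returns the class mask and the measurement.

    The denominator of percent collagen is the entire image (white pixels
    included); set ``cfg.tissue_denominator`` to divide by the non-white
    area instead.
    """
    lab = rgb_to_lab(img)
    white = lightness_mask(lab, cfg)
    include = ~white if cfg.mask_before_cluster else None
    model = label_clusters(cluster_ab(lab, cfg, include=include))
    assert model.class_map is not None

    labels = np.empty(lab.shape, dtype=np.uint8)
    for idx, cls in model.class_map.items():
        labels[model.assignment == idx] = RED if cls == "red" else BLUE
    labels[white] = WHITE
    labels = _apply_closing(labels, cfg)

    mask = ClassMask(labels=labels)
    c = mask.counts()
    total = labels.size
    denom = (total - c["white"]) if cfg.tissue_denominator else total
    percent = 100.0 * c["blue"] / denom if denom > 0 else 0.0
    meas = CollagenMeasurement(
        blue_px=c["blue"], red_px=c["red"], white_px=c["white"], total_px=total,
        percent_collagen=percent, degenerate=model.degenerate,
        config_hash=cfg.hash(),
    )
    return mask, meas


def render_overlay(img: RgbImage, mask: ClassMask, alpha: float = 0.45) -> np.ndarray:
    """Translucent class colouring over the original image, with a legend
    strip (one swatch + pixel count per class) appended below.

    Returns an 8-bit RGB array; its top ``img.shape`` block is the blended
    overlay.
    """
    h, w = img.shape
    if mask.labels.shape != (h, w):
        raise ValueError(
            f"mask shape {mask.labels.shape} does not match image shape {(h, w)}"
        )
    tint = np.zeros((h, w, 3), dtype=np.float64)
    for code, colour in _OVERLAY_COLOURS.items():
        tint[mask.labels == code] = colour
    blended = ((1.0 - alpha) * img.pixels.astype(np.float64) + alpha * tint)
    blended = np.clip(np.rint(blended), 0, 255).astype(np.uint8)

    strip_h = 14
    legend = np.full((strip_h, w, 3), 255, dtype=np.uint8)
    x = 2
    swatch = 10
    for code, _name, _count in overlay_legend(mask):
        if x + swatch >= w:
            break
        legend[2:2 + swatch, x:x + swatch] = _OVERLAY_COLOURS[code]
        x += swatch + 4
    return np.concatenate([blended, legend], axis=0)


def overlay_legend(mask: ClassMask) -> list[tuple[int, str, int]]:
    """Legend entries for :func:`render_overlay`: (class code, name, pixel
    count) for every class present in the mask (non-zero count only)."""
    counts = mask.counts()
    return [
        (code, CLASS_NAMES[code], counts[CLASS_NAMES[code]])
        for code in (RED, BLUE, WHITE)
        if counts[CLASS_NAMES[code]] > 0
    ]
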