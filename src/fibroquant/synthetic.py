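"""Synthetic trichrome-like muscle cross-sections with exact ground truth.

A section is built as a jittered-grid Voronoi mosaic of polygonal myofibers
clipped to a central tissue rectangle, separated by collagen bands whose
width is solved by bisection to hit a target area fraction.  One nucleus is
placed per fiber, centrally or peripherally according to ``cnf_rate``.
Class-mean L*a*b* colours plus Gaussian noise are converted to 8-bit sRGB.

Everything is deterministic given the spec (including its seed): the same
spec yields bit-identical rasters and ground truth.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import shapely
from scipy.spatial import cKDTree
from shapely.geometry import MultiPoint, Point, Polygon, box
from shapely.ops import voronoi_diagram
from skimage import color as skcolor

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "Nucleus",
    "GroupSpec",
    "CohortImage",
    "DEFAULT_STAIN_MODEL",
    "LABEL_MUSCLE",
    "LABEL_COLLAGEN",
    "LABEL_NUCLEUS",
    "LABEL_BACKGROUND",
    "LABEL_CODES",
    "generate_image",
    "generate_cohort",
    "InfeasibleFractionError",
]

# Ground-truth label codes (single-channel PNG values)
LABEL_MUSCLE = 0
LABEL_COLLAGEN = 1
LABEL_NUCLEUS = 2
LABEL_BACKGROUND = 3

LABEL_CODES = {
    "muscle": LABEL_MUSCLE,
    "collagen": LABEL_COLLAGEN,
    "nucleus": LABEL_NUCLEUS,
    "background": LABEL_BACKGROUND,
}

# Class-mean L*a*b* colours approximating trichrome appearance: red muscle,
# blue collagen, dark nuclei, near-white background.
DEFAULT_STAIN_MODEL: dict[str, tuple[float, float, float]] = {
    "muscle": (55.0, 45.0, 15.0),
    "collagen": (60.0, 10.0, -35.0),
    "nucleus": (25.0, 15.0, -20.0),
    "background": (97.0, 0.0, 0.0),
}


class InfeasibleFractionError(ValueError):
    """The collagen band width cannot reach the requested area fraction."""

    def __init__(self, target: float, low: float, high: float):
        self.achievable = (low, high)
        super().__init__(
            f"target collagen fraction {target:.4f} is outside the achievable "
            f"range [{low:.4f}, {high:.4f}] for this geometry"
        )


@dataclass(frozen=True)
class SyntheticSpec:
    width_px: int = 512
    height_px: int = 512
    n_fibers: int = 80
    target_collagen_fraction: float = 0.10
    background_fraction: float = 0.10
    cnf_rate: float = 0.0
    stain_model: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_STAIN_MODEL)
    )
    colour_noise_sd: float = 2.0
    seed: int = 0
    nucleus_radius_px: int = 3
    central_band_frac: float = 0.25  # must match the centrality predicate's band

    def __post_init__(self):
        if self.width_px < 1 or self.height_px < 1:
            raise ValueError("image dimensions must be positive")
        if self.n_fibers < 1:
            raise ValueError("n_fibers must be positive")
        if not (0.0 <= self.target_collagen_fraction <= 1.0):
            raise ValueError("target_collagen_fraction must be in [0, 1]")
        if not (0.0 <= self.background_fraction < 1.0):
            raise ValueError("background_fraction must be in [0, 1)")
        if self.target_collagen_fraction + self.background_fraction >= 1.0:
            raise ValueError(
                "target_collagen_fraction + background_fraction must be < 1"
            )
        if not (0.0 <= self.cnf_rate <= 1.0):
            raise ValueError("cnf_rate must be in [0, 1]")
        if self.colour_noise_sd < 0:
            raise ValueError("colour_noise_sd must be non-negative")
        for cls in ("muscle", "collagen", "nucleus", "background"):
            if cls not in self.stain_model:
                raise ValueError(f"stain_model missing class {cls!r}")
            if not np.all(np.isfinite(self.stain_model[cls])):
                raise ValueError(f"stain_model colour for {cls!r} is not finite")


@dataclass(frozen=True)
class Nucleus:
    point: tuple[float, float]
    fiber_id: int
    is_central: bool


@dataclass
class GroundTruth:
    """Exact per-pixel labels and geometry for one synthetic section."""

    label_mask: np.ndarray                 # H x W uint8 over LABEL_* codes
    fiber_polygons: dict[int, Polygon]     # fiber_id -> shrunken fiber polygon
    nuclei: list[Nucleus]
    true_collagen_fraction: float
    band_width_px: float

    def class_fractions(self) -> dict[str, float]:
        total = self.label_mask.size
        return {
            name: float(np.count_nonzero(self.label_mask == code)) / total
            for name, code in LABEL_CODES.items()
        }


def _fiber_seeds(spec: SyntheticSpec, tissue: tuple[float, float, float, float],
                 rng: np.random.Generator) -> np.ndarray:
    """Jittered-grid seed points inside the tissue rectangle."""
    x0, y0, x1, y1 = tissue
    tw, th = x1 - x0, y1 - y0
    aspect = tw / th
    ncols = max(1, int(round(np.sqrt(spec.n_fibers * aspect))))
    nrows = int(np.ceil(spec.n_fibers / ncols))
    pitch_x, pitch_y = tw / ncols, th / nrows
    pts = []
    for r in range(nrows):
        for c in range(ncols):
            cx = x0 + (c + 0.5) * pitch_x
            cy = y0 + (r + 0.5) * pitch_y
            jx = rng.uniform(-0.35, 0.35) * pitch_x
            jy = rng.uniform(-0.35, 0.35) * pitch_y
            pts.append((cx + jx, cy + jy))
    pts = np.asarray(pts)
    if len(pts) > spec.n_fibers:
        keep = rng.permutation(len(pts))[: spec.n_fibers]
        pts = pts[np.sort(keep)]
    return pts


def _voronoi_cells(seeds: np.ndarray, tissue_poly: Polygon) -> dict[int, Polygon]:
    """Voronoi cell of each seed, clipped to the tissue rectangle, keyed by
    seed index (voronoi_diagram does not preserve input order)."""
    diagram = voronoi_diagram(MultiPoint([Point(p) for p in seeds]),
                              envelope=tissue_poly.buffer(10.0))
    cells: dict[int, Polygon] = {}
    raw = list(diagram.geoms)
    tree = shapely.STRtree(raw)
    for i, p in enumerate(seeds):
        pt = Point(p)
        for j in tree.query(pt):
            if raw[j].covers(pt):
                cell = raw[j].intersection(tissue_poly)
                if not cell.is_empty and cell.geom_type == "Polygon":
                    cells[i] = cell
                break
    return cells


def _voronoi_adjacency(seeds: np.ndarray) -> dict[int, list[int]]:
    """Voronoi neighbour lists; falls back to all-pairs for tiny or
    degenerate seed sets."""
    from scipy.spatial import Voronoi, QhullError

    n = len(seeds)
    if n < 4:
        return {i: [j for j in range(n) if j != i] for i in range(n)}
    try:
        vor = Voronoi(seeds)
    except QhullError:
        return {i: [j for j in range(n) if j != i] for i in range(n)}
    adj: dict[int, list[int]] = {i: [] for i in range(n)}
    for i, j in vor.ridge_points:
        adj[int(i)].append(int(j))
        adj[int(j)].append(int(i))
    return adj


def _pixel_margins(spec: SyntheticSpec, seeds: np.ndarray,
                   tissue: tuple[float, float, float, float]
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """For every pixel centre: nearest-seed index, the distance to its Voronoi
    cell boundary (clipped by the tissue rectangle), and a tissue-membership
    mask.  Pixel centres sit at integer coordinates, origin top-left."""
    h, w = spec.height_px, spec.width_px
    xs, ys = np.meshgrid(np.arange(w, dtype=np.float64),
                         np.arange(h, dtype=np.float64))
    pix = np.stack([xs.ravel(), ys.ravel()], axis=1)

    tree = cKDTree(seeds)
    d1, nearest = tree.query(pix, k=1)

    # Exact distance to the Voronoi cell boundary: for a pixel whose nearest
    # seed is s0, the boundary consists of bisectors with s0's Voronoi
    # neighbours only.  Distance to the bisector with seed sj is
    # (|p-sj|^2 - |p-s0|^2) / (2 |sj - s0|).
    neighbours = _voronoi_adjacency(seeds)
    margin = np.full(len(pix), np.inf)
    d1sq = d1 * d1
    order = np.argsort(nearest, kind="stable")
    bounds = np.searchsorted(nearest[order], np.arange(len(seeds) + 1))
    for s0 in range(len(seeds)):
        sel = order[bounds[s0]:bounds[s0 + 1]]
        nbs = neighbours.get(s0)
        if sel.size == 0 or not nbs:
            continue
        p = pix[sel]
        best = np.full(sel.size, np.inf)
        for nb in nbs:
            delta = p - seeds[nb]
            djsq = np.einsum("ij,ij->i", delta, delta)
            gap = float(np.hypot(*(seeds[nb] - seeds[s0])))
            if gap > 0:
                np.minimum(best, (djsq - d1sq[sel]) / (2.0 * gap), out=best)
        margin[sel] = best

    x0, y0, x1, y1 = tissue
    edge = np.minimum.reduce([
        pix[:, 0] - x0, x1 - pix[:, 0], pix[:, 1] - y0, y1 - pix[:, 1]
    ])
    in_tissue = edge >= 0
    margin = np.minimum(margin, edge)
    # Sub-micron deterministic jitter breaks exact ties (whole pixel rows
    # share one tissue-edge distance) so the band-width bisection can resolve
    # the fraction to single-pixel granularity.
    jitter_rng = np.random.default_rng(spec.seed ^ 0x5EED)
    margin += jitter_rng.uniform(0.0, 1e-6, size=margin.shape)
    return (nearest.reshape(h, w), margin.reshape(h, w), in_tissue.reshape(h, w))


def _solve_band_width(margin: np.ndarray, in_tissue: np.ndarray,
                      target: float, total_px: int,
                      tol: float = 0.0049, max_iter: int = 80) -> float:
    """Bisection on the band half-width t: collagen = tissue pixels whose
    margin is <= t.  The achieved fraction is a step function of t, monotone
    non-decreasing, so bisection brackets the target."""
    tissue_margins = margin[in_tissue]

    def frac(t: float) -> float:
        return float(np.count_nonzero(tissue_margins <= t)) / total_px

    if target == 0.0:
        return 0.0
    lo, hi = 0.0, float(tissue_margins.max()) + 1.0
    f_lo, f_hi = frac(lo), frac(hi)
    if not (f_lo <= target <= f_hi):
        raise InfeasibleFractionError(target, f_lo, f_hi)
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        f_mid = frac(mid)
        if abs(f_mid - target) <= tol:
            return mid
        if f_mid < target:
            lo = mid
        else:
            hi = mid
    # Interval collapsed onto a step: return the closer endpoint.
    best = min((lo, hi), key=lambda t: abs(frac(t) - target))
    if abs(frac(best) - target) > tol:
        raise InfeasibleFractionError(target, f_lo, f_hi)
    return best


def _place_nuclei(spec: SyntheticSpec, fibers: dict[int, Polygon],
                  rng: np.random.Generator) -> list[Nucleus]:
    """One nucleus per fiber.  Central nuclei sit at the maximum-inscribed-
    circle centre; peripheral ones just inside the boundary.  Flags record
    the *realized* placement under the same band_frac the centrality
    predicate uses."""
    nuclei = []
    band = spec.central_band_frac
    for fid in sorted(fibers):
        poly = fibers[fid]
        if poly.is_empty or poly.area <= 0:
            continue
        r_eq = float(np.sqrt(poly.area / np.pi))
        want_central = bool(rng.random() < spec.cnf_rate)
        radius_line = shapely.maximum_inscribed_circle(poly)
        centre = np.asarray(radius_line.coords[0])
        inscribed_r = float(radius_line.length)
        if want_central and inscribed_r > band * r_eq * 1.01:
            point = centre
            central = True
        else:
            # Step inward from the nearest boundary point by well under the
            # band, so the centrality predicate is false by construction.
            d_in = min(0.1 * r_eq, 0.5 * inscribed_r)
            edge_pt = np.asarray(radius_line.coords[-1])
            direction = centre - edge_pt
            norm = np.linalg.norm(direction)
            if norm == 0:
                point = centre
            else:
                point = edge_pt + direction / norm * d_in
            central = False
        nuclei.append(Nucleus(point=(float(point[0]), float(point[1])),
                              fiber_id=fid, is_central=central))
    return nuclei


def _rasterize_nuclei(label_mask: np.ndarray, nearest: np.ndarray,
                      nuclei: Sequence[Nucleus], radius: int) -> None:
    """Stamp a small disk per nucleus, overwriting only muscle pixels of the
    nucleus's own fiber so collagen/background counts are untouched."""
    h, w = label_mask.shape
    for nuc in nuclei:
        cx, cy = nuc.point
        x_lo, x_hi = max(0, int(cx) - radius), min(w, int(cx) + radius + 2)
        y_lo, y_hi = max(0, int(cy) - radius), min(h, int(cy) + radius + 2)
        if x_lo >= x_hi or y_lo >= y_hi:
            continue
        ys, xs = np.mgrid[y_lo:y_hi, x_lo:x_hi]
        disk = (xs - cx) ** 2 + (ys - cy) ** 2 <= radius * radius
        patch = label_mask[y_lo:y_hi, x_lo:x_hi]
        own = nearest[y_lo:y_hi, x_lo:x_hi] == nuc.fiber_id
        patch[disk & own & (patch == LABEL_MUSCLE)] = LABEL_NUCLEUS


def _render(spec: SyntheticSpec, label_mask: np.ndarray,
            rng: np.random.Generator) -> np.ndarray:
    """Class-mean Lab colours + Gaussian noise -> clipped 8-bit sRGB."""
    h, w = label_mask.shape
    lab = np.zeros((h, w, 3), dtype=np.float64)
    for cls, code in LABEL_CODES.items():
        lab[label_mask == code] = spec.stain_model[cls]
    if spec.colour_noise_sd > 0:
        lab += rng.normal(0.0, spec.colour_noise_sd, size=lab.shape)
    rgb = skcolor.lab2rgb(lab)
    return np.clip(np.rint(rgb * 255.0), 0, 255).astype(np.uint8)


def generate_image(spec: SyntheticSpec) -> tuple[np.ndarray, GroundTruth]:
    """Generate one synthetic trichrome section and its exact ground truth.

    Returns (rgb array H x W x 3 uint8, :class:`GroundTruth`).  The achieved
    collagen fraction is within +/-0.005 of the target or an
    :class:`InfeasibleFractionError` is raised naming the achievable range.
    """
    h, w = spec.height_px, spec.width_px
    total_px = h * w
    rng = np.random.default_rng(spec.seed)

    # Tissue rectangle occupying (1 - background_fraction) of the frame.
    s = float(np.sqrt(1.0 - spec.background_fraction))
    x0, x1 = (w - 1) * (1 - s) / 2.0 - 0.5, (w - 1) * (1 + s) / 2.0 + 0.5
    y0, y1 = (h - 1) * (1 - s) / 2.0 - 0.5, (h - 1) * (1 + s) / 2.0 + 0.5
    tissue = (x0, y0, x1, y1)
    tissue_poly = box(*tissue)

    seeds = _fiber_seeds(spec, tissue, rng)
    nearest, margin, in_tissue = _pixel_margins(spec, seeds, tissue)

    band = _solve_band_width(margin, in_tissue, spec.target_collagen_fraction,
                             total_px)

    label_mask = np.full((h, w), LABEL_BACKGROUND, dtype=np.uint8)
    label_mask[in_tissue & (margin > band)] = LABEL_MUSCLE
    label_mask[in_tissue & (margin <= band)] = LABEL_COLLAGEN

    cells = _voronoi_cells(seeds, tissue_poly)
    fibers: dict[int, Polygon] = {}
    for fid, cell in cells.items():
        shrunk = cell.buffer(-band) if band > 0 else cell
        if not shrunk.is_empty and shrunk.geom_type == "Polygon" and shrunk.area > 0:
            fibers[fid] = shrunk

    nuclei = _place_nuclei(spec, fibers, rng)
    _rasterize_nuclei(label_mask, nearest, nuclei, spec.nucleus_radius_px)

    true_frac = float(np.count_nonzero(label_mask == LABEL_COLLAGEN)) / total_px
    rgb = _render(spec, label_mask, rng)
    gt = GroundTruth(label_mask=label_mask, fiber_polygons=fibers,
                     nuclei=nuclei, true_collagen_fraction=true_frac,
                     band_width_px=band)
    return rgb, gt


# ---------------------------------------------------------------------------
# Cohorts


@dataclass(frozen=True)
class GroupSpec:
    """Per-group parameters for a simulated cohort."""

    n_animals: int
    sections_per_animal: int
    target_collagen_fraction: float
    cnf_rate: float = 0.0

    def __post_init__(self):
        if self.n_animals < 1 or self.sections_per_animal < 1:
            raise ValueError("n_animals and sections_per_animal must be positive")


@dataclass(frozen=True)
class CohortImage:
    group: str
    animal: int
    section: int
    seed: int
    spec: SyntheticSpec
    image: np.ndarray
    ground_truth: GroundTruth


def derive_seed(base_seed: int, group: str, animal: int, section: int) -> int:
    """Stable per-image seed from (base seed, group, animal, section)."""
    key = f"{base_seed}|{group}|{animal}|{section}".encode()
    return int.from_bytes(hashlib.sha256(key).digest()[:8], "big") % (2 ** 63)


def generate_cohort(group_specs: Mapping[str, GroupSpec], base_seed: int = 0,
                    base_spec: Optional[SyntheticSpec] = None) -> list[CohortImage]:
    """Generate a full cohort: every (group, animal, section) image plus its
    ground truth, with deterministic per-image seeds.

    ``base_spec`` carries the shared geometry/colour parameters; each image's
    spec overrides its fraction, cnf_rate and seed.
    """
    if base_spec is None:
        base_spec = SyntheticSpec()
    seen: set[tuple[str, int, int]] = set()
    out: list[CohortImage] = []
    for group, gs in group_specs.items():
        for animal in range(1, gs.n_animals + 1):
            for section in range(1, gs.sections_per_animal + 1):
                key = (group, animal, section)
                if key in seen:
                    raise ValueError(f"duplicate cohort key {key}")
                seen.add(key)
                seed = derive_seed(base_seed, group, animal, section)
                spec = SyntheticSpec(
                    width_px=base_spec.width_px,
                    height_px=base_spec.height_px,
                    n_fibers=base_spec.n_fibers,
                    target_collagen_fraction=gs.target_collagen_fraction,
                    background_fraction=base_spec.background_fraction,
                    cnf_rate=gs.cnf_rate,
                    stain_model=base_spec.stain_model,
                    colour_noise_sd=base_spec.colour_noise_sd,
                    seed=seed,
                    nucleus_radius_px=base_spec.nucleus_radius_px,
                    central_band_frac=base_spec.central_band_frac,
                )
                img, gt = generate_image(spec)
                out.append(CohortImage(group=group, animal=animal,
                                       section=section, seed=seed, spec=spec,
                                       image=img, ground_truth=gt))
    return out
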