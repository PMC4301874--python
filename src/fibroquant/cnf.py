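"""Centrally-nucleated-fiber (CNF) scoring from fiber/nucleus annotations.

A fiber counts as centrally nucleated when at least one of its nuclei lies
deeper than ``band_frac`` times the fiber's equivalent radius from the fiber
boundary (equivalent radius = sqrt(area / pi)).  The reported metric is the
percentage of annotated fibers that are centrally nucleated.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import shapely
from shapely.geometry import Point, Polygon

__all__ = [
    "FiberAnnotation",
    "NucleusAnnotation",
    "CnfResult",
    "OverlappingFibersError",
    "assign_nuclei",
    "is_central",
    "percent_cnf",
    "DEFAULT_BAND_FRAC",
]

DEFAULT_BAND_FRAC = 0.25


class OverlappingFibersError(ValueError):
    """A nucleus point is covered by more than one fiber polygon."""

    def __init__(self, point, fiber_ids):
        self.fiber_ids = list(fiber_ids)
        super().__init__(
            f"nucleus at {tuple(point)} lies inside overlapping fibers {self.fiber_ids}"
        )


@dataclass(frozen=True)
class FiberAnnotation:
    fiber_id: int | str
    polygon: Polygon

    def __post_init__(self):
        if not self.polygon.is_valid or not self.polygon.is_simple:
            raise ValueError(f"fiber {self.fiber_id}: polygon must be simple")
        if self.polygon.area <= 0:
            raise ValueError(f"fiber {self.fiber_id}: polygon area must be > 0")


@dataclass(frozen=True)
class NucleusAnnotation:
    point: tuple[float, float]
    fiber_id: Optional[int | str] = None
    is_central: Optional[bool] = None  # carried through from ground truth if known


@dataclass(frozen=True)
class CnfResult:
    n_fibers: int
    n_central_fibers: int
    percent_cnf: float
    band_frac: float = DEFAULT_BAND_FRAC

    def __post_init__(self):
        if self.n_central_fibers > self.n_fibers:
            raise ValueError("n_central_fibers cannot exceed n_fibers")


def assign_nuclei(fibers: Sequence[FiberAnnotation],
                  nuclei: Sequence[NucleusAnnotation]) -> list[NucleusAnnotation]:
    """Assign each nucleus to the unique fiber containing it.

    Boundary points count as inside.  Nuclei outside every fiber come back
    with ``fiber_id=None``; a point inside two or more fibers raises
    :class:`OverlappingFibersError`.
    """
    polys = [f.polygon for f in fibers]
    tree = shapely.STRtree(polys)
    out: list[NucleusAnnotation] = []
    for nuc in nuclei:
        pt = Point(nuc.point)
        hits = [i for i in tree.query(pt) if polys[i].covers(pt)]
        if len(hits) > 1:
            raise OverlappingFibersError(nuc.point, [fibers[i].fiber_id for i in hits])
        fid = fibers[hits[0]].fiber_id if hits else None
        out.append(replace(nuc, fiber_id=fid))
    return out


def is_central(nucleus: NucleusAnnotation, fiber: FiberAnnotation,
               band_frac: float = DEFAULT_BAND_FRAC) -> bool:
    """Centrality predicate: boundary distance > band_frac * sqrt(area/pi).

    A point exactly on the boundary has distance 0 and is peripheral.
    """
    if not (0.0 < band_frac < 1.0):
        raise ValueError("band_frac must be in (0, 1)")
    r_eq = (fiber.polygon.area / 3.141592653589793) ** 0.5
    dist = fiber.polygon.boundary.distance(Point(nucleus.point))
    return dist > band_frac * r_eq


def percent_cnf(fibers: Sequence[FiberAnnotation],
                nuclei: Sequence[NucleusAnnotation],
                band_frac: float = DEFAULT_BAND_FRAC) -> CnfResult:
    """Percentage of fibers with at least one central nucleus.

    Nuclei without a fiber_id are assigned first; nuclei falling outside all
    fibers are excluded from the tally.
    """
    if len(fibers) == 0:
        raise ValueError("percent_cnf is undefined for zero fibers")
    by_id = {f.fiber_id: f for f in fibers}
    if len(by_id) != len(fibers):
        raise ValueError("duplicate fiber_id in annotations")
    if any(n.fiber_id is None for n in nuclei):
        nuclei = assign_nuclei(fibers, nuclei)
    central_fibers: set = set()
    for nuc in nuclei:
        if nuc.fiber_id is None or nuc.fiber_id not in by_id:
            continue
        if is_central(nuc, by_id[nuc.fiber_id], band_frac):
            central_fibers.add(nuc.fiber_id)
    n_central = len(central_fibers)
    return CnfResult(
        n_fibers=len(fibers),
        n_central_fibers=n_central,
        percent_cnf=100.0 * n_central / len(fibers),
        band_frac=band_frac,
    )
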