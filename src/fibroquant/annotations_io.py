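"""GeoJSON dialect shared by the simulator and the CNF stage.

A FeatureCollection holds Polygon features (properties: fiber_id) for fibers
and Point features (properties: fiber_id, is_central when known) for nuclei.
Coordinates are pixel coordinates: origin top-left, x rightward, y downward.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

from shapely.geometry import Polygon, mapping, shape

from .cnf import FiberAnnotation, NucleusAnnotation

__all__ = ["write_annotations", "read_annotations"]


def write_annotations(path: str | Path,
                      fibers: Sequence[FiberAnnotation],
                      nuclei: Sequence[NucleusAnnotation]) -> None:
    features = []
    for f in fibers:
        features.append({
            "type": "Feature",
            "geometry": mapping(f.polygon),
            "properties": {"fiber_id": f.fiber_id},
        })
    for n in nuclei:
        props: dict = {"fiber_id": n.fiber_id}
        if n.is_central is not None:
            props["is_central"] = bool(n.is_central)
        features.append({
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": list(n.point)},
            "properties": props,
        })
    Path(path).write_text(json.dumps(
        {"type": "FeatureCollection", "features": features}, indent=1))


def read_annotations(path: str | Path
                     ) -> tuple[list[FiberAnnotation], list[NucleusAnnotation]]:
    doc = json.loads(Path(path).read_text())
    if doc.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: not a GeoJSON FeatureCollection")
    fibers: list[FiberAnnotation] = []
    nuclei: list[NucleusAnnotation] = []
    for feat in doc.get("features", []):
        geom = feat.get("geometry", {})
        props = feat.get("properties") or {}
        if geom.get("type") == "Polygon":
            poly = shape(geom)
            if not isinstance(poly, Polygon):
                raise ValueError(f"{path}: unexpected geometry {geom.get('type')}")
            fibers.append(FiberAnnotation(fiber_id=props.get("fiber_id"),
                                          polygon=poly))
        elif geom.get("type") == "Point":
            x, y = geom["coordinates"][:2]
            nuclei.append(NucleusAnnotation(
                point=(float(x), float(y)),
                fiber_id=props.get("fiber_id"),
                is_central=props.get("is_central"),
            ))
        else:
            raise ValueError(f"{path}: unsupported geometry {geom.get('type')}")
    return fibers, nuclei
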