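"""Annotation and outcome-table I/O plus spatial containment queries.

Annotations are QuPath-style GeoJSON FeatureCollections: each feature is a
(multi)polygon with ``properties.classification.name`` naming a histology
class. Coordinates are 0-based level-0 pixels, x right / y down. Tiles are
half-open ``[x, x+224) x [y, y+224)`` boxes.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import pandas as pd
from shapely.geometry import Polygon, box, shape
from shapely.geometry.base import BaseGeometry

from .classes import HistologyClass, class_by_name

log = logging.getLogger(__name__)

TILE_SIZE = 224


class AnnotationError(ValueError):
    """Malformed or invalid annotation content."""


@dataclass
class AnnotatedRegion:
    """A labeled closed polygon contour on a slide (level-0 pixel units)."""

    region_id: str
    slide_id: str
    contour: list[tuple[float, float]]
    label: HistologyClass
    holes: list[list[tuple[float, float]]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.contour) < 3:
            raise AnnotationError(
                f"region {self.region_id!r}: polygon needs >=3 vertices, got {len(self.contour)}"
            )
        if self.polygon().area <= 0:
            raise AnnotationError(f"region {self.region_id!r}: polygon area must be > 0")

    def polygon(self) -> Polygon:
        return Polygon(self.contour, self.holes)


def read_annotations(path: str) -> list[AnnotatedRegion]:
    """Read a GeoJSON FeatureCollection of labeled polygon annotations.

    Every feature must carry polygon geometry and a classification name that
    matches a known histology class; unknown names raise an error naming all
    valid classes rather than being dropped.
    """
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise AnnotationError(f"{path}: malformed JSON: {exc}") from exc
    if doc.get("type") != "FeatureCollection":
        raise AnnotationError(f"{path}: expected a GeoJSON FeatureCollection")

    regions: list[AnnotatedRegion] = []
    for i, feat in enumerate(doc.get("features", [])):
        props = feat.get("properties", {})
        region_id = str(props.get("region_id", f"region_{i}"))
        slide_id = str(props.get("slide_id", props.get("image", "slide")))
        cls_name = (props.get("classification") or {}).get("name")
        if cls_name is None:
            raise AnnotationError(f"feature {region_id!r}: missing classification name")
        label = class_by_name(cls_name)  # raises KeyError listing valid names
        geom = feat.get("geometry", {})
        if geom.get("type") != "Polygon":
            raise AnnotationError(
                f"feature {region_id!r}: geometry type {geom.get('type')!r}, expected Polygon"
            )
        rings = geom["coordinates"]
        exterior = [tuple(map(float, pt)) for pt in rings[0]]
        # GeoJSON closes rings by repeating the first vertex; drop it.
        if len(exterior) > 1 and exterior[0] == exterior[-1]:
            exterior = exterior[:-1]
        holes = []
        for ring in rings[1:]:
            hole = [tuple(map(float, pt)) for pt in ring]
            if len(hole) > 1 and hole[0] == hole[-1]:
                hole = hole[:-1]
            holes.append(hole)
        regions.append(AnnotatedRegion(region_id, slide_id, exterior, label, holes))
    return regions


def write_annotations(regions: list[AnnotatedRegion], path: str) -> None:
    """Write regions as a GeoJSON FeatureCollection (round-trips with
    :func:`read_annotations`)."""
    features = []
    for r in regions:
        rings = [list(r.contour) + [r.contour[0]]]
        for hole in r.holes:
            rings.append(list(hole) + [hole[0]])
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Polygon", "coordinates": rings},
                "properties": {
                    "region_id": r.region_id,
                    "slide_id": r.slide_id,
                    "classification": {"name": r.label.name},
                },
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def containment_fraction(region: AnnotatedRegion, tile_box: tuple[float, float, float, float]) -> float:
    """area(polygon intersect tile) / area(tile); holes are subtracted."""
    poly: BaseGeometry = region.polygon()
    if not poly.is_valid or poly.area <= 0:
        raise AnnotationError(f"region {region.region_id!r}: degenerate polygon")
    x0, y0, x1, y1 = tile_box
    b = box(x0, y0, x1, y1)
    return poly.intersection(b).area / b.area


def region_contains_tile(
    region: AnnotatedRegion,
    tile_box: tuple[float, float, float, float],
    min_fraction: float,
) -> bool:
    """True iff the polygon covers at least ``min_fraction`` of the tile
    (inclusive at equality, with a small float guard)."""
    if not 0.0 <= min_fraction <= 1.0:
        raise ValueError("min_fraction must lie in [0, 1]")
    return containment_fraction(region, tile_box) >= min_fraction - 1e-12


@dataclass
class OutcomeTable:
    """Per-patient treatment outcome (pCR = complete response, RD = residual
    disease) for one cohort."""

    table: pd.DataFrame  # columns: patient_id, outcome
    cohort: str

    def __len__(self) -> int:
        return len(self.table)

    @property
    def counts(self) -> tuple[int, int]:
        """(n_pCR, n_RD)."""
        vc = self.table["outcome"].value_counts()
        return int(vc.get("pCR", 0)), int(vc.get("RD", 0))


VALID_OUTCOMES = frozenset({"pCR", "RD"})


def read_outcomes(path: str, cohort: str = "development") -> OutcomeTable:
    """Read the outcome CSV (header ``patient_id,outcome``)."""
    df = pd.read_csv(path, dtype=str)
    if list(df.columns[:2]) != ["patient_id", "outcome"]:
        raise ValueError(f"{path}: expected header patient_id,outcome")
    dup = df["patient_id"][df["patient_id"].duplicated()]
    if not dup.empty:
        raise ValueError(f"{path}: duplicate patient_id values: {sorted(set(dup))}")
    bad = set(df["outcome"]) - VALID_OUTCOMES
    if bad:
        raise ValueError(f"{path}: invalid outcome values {sorted(bad)}; expected pCR or RD")
    table = OutcomeTable(df[["patient_id", "outcome"]].copy(), cohort)
    n_pcr, n_rd = table.counts
    log.info("outcomes[%s]: %d patients (%d pCR, %d RD)", cohort, len(table), n_pcr, n_rd)
    return table


def write_outcomes(table: OutcomeTable, path: str) -> None:
    table.table.to_csv(path, index=False)
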