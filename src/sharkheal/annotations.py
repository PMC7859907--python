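"""Annotation geometry and scale-standardized wound measurement.

Wound extent is traced on photographs as one or more polygons (a wound may
break into disjoint sections while healing). Because photographs of the same
shark differ in pixel density, every image also carries a tracing of one
unchanging epidermal spot marking — the *anchor* — whose area and perimeter
provide a within-image relative scale. Dividing the summed wound area by the
anchor area (and likewise for perimeters) yields dimensionless ratios that
are comparable across sightings regardless of camera distance or resolution.

The first date a wound was photographed is day 0 of its healing series; all
later sightings are expressed as integer day offsets from it.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from datetime import date, datetime
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from shapely.geometry import Polygon as _ShapelyPolygon

from .errors import (
    AmbiguousDateError,
    DegenerateScaleError,
    InsufficientDataError,
    InvalidGeometryError,
)

__all__ = [
    "Polygon",
    "AnchorScale",
    "WoundAnnotation",
    "SightingMeasurement",
    "HealingSeries",
    "polygon_area",
    "polygon_perimeter",
    "normalized_extent",
    "build_series",
    "load_cases_json",
    "load_cases_csv",
    "measurements_frame",
]


@dataclass(frozen=True)
class Polygon:
    """A closed polygon in pixel coordinates (x right, y down, origin top-left).

    Vertices are implicitly closed last-to-first and may wind either way;
    area is always reported as a positive magnitude.
    """

    vertices: tuple[tuple[float, float], ...]

    def __init__(self, vertices: Iterable[Sequence[float]]):
        verts = tuple((float(x), float(y)) for x, y in vertices)
        object.__setattr__(self, "vertices", verts)
        self._validate()

    def _validate(self) -> None:
        if len(self.vertices) < 3:
            raise InvalidGeometryError(
                f"polygon needs >=3 vertices, got {len(self.vertices)}"
            )
        closed = self.vertices + (self.vertices[0],)
        for a, b in zip(closed, closed[1:]):
            if a == b:
                raise InvalidGeometryError(f"consecutive duplicate vertex {a}")
        shp = _ShapelyPolygon(self.vertices)
        if not shp.is_valid:
            raise InvalidGeometryError("self-intersecting or degenerate polygon")
        if shp.area <= 0.0:
            raise InvalidGeometryError("polygon has zero area")

    @property
    def shapely(self) -> _ShapelyPolygon:
        return _ShapelyPolygon(self.vertices)


def polygon_area(p: Polygon) -> float:
    """Absolute (orientation-independent) area of *p* in pixels²."""
    return _ShapelyPolygon(p.vertices).area


def polygon_perimeter(p: Polygon) -> float:
    """Perimeter of *p* in pixels, including the closing edge."""
    return _ShapelyPolygon(p.vertices).length


@dataclass(frozen=True)
class AnchorScale:
    """The relative-scale marking traced in one image.

    By convention the tracing is the rectangle tool's output, but any simple
    polygon is accepted; it is treated as an opaque scale.
    """

    rectangle: Polygon

    @property
    def area_px2(self) -> float:
        return polygon_area(self.rectangle)

    @property
    def perimeter_px(self) -> float:
        return polygon_perimeter(self.rectangle)


@dataclass(frozen=True)
class WoundAnnotation:
    """All tracings for one wound in one photograph."""

    shark_id: str
    injury_id: str
    sighting_date: date
    sections: tuple[Polygon, ...]
    anchor: AnchorScale
    image_id: str = ""
    dorsal_fin: Polygon | None = None

    def __post_init__(self) -> None:
        if len(self.sections) < 1:
            raise InvalidGeometryError("annotation needs >=1 wound section")

    @property
    def total_area_px2(self) -> float:
        return sum(polygon_area(s) for s in self.sections)

    @property
    def total_perimeter_px(self) -> float:
        return sum(polygon_perimeter(s) for s in self.sections)


@dataclass(frozen=True)
class SightingMeasurement:
    """Scale-standardized wound extent at one sighting."""

    day_offset: int
    area_ratio: float
    perimeter_ratio: float


@dataclass(frozen=True)
class HealingSeries:
    """Per-injury time series of normalized extents, day 0 first."""

    injury_id: str
    measurements: tuple[SightingMeasurement, ...]
    shark_id: str = ""
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.measurements)

    @property
    def day_offsets(self) -> tuple[int, ...]:
        return tuple(m.day_offset for m in self.measurements)


def normalized_extent(w: WoundAnnotation, first_date: date | None = None) -> SightingMeasurement:
    """Standardize one annotation to dimensionless area/perimeter ratios.

    ``area_ratio`` is the summed section area divided by the anchor area;
    ``perimeter_ratio`` mirrors it with perimeters. ``first_date`` anchors the
    day offset; when omitted the sighting is treated as day 0.
    """
    a = w.anchor.area_px2
    p = w.anchor.perimeter_px
    if a <= 0.0 or p <= 0.0:
        raise DegenerateScaleError(
            f"anchor area {a} / perimeter {p} cannot serve as a scale"
        )
    if first_date is None:
        offset = 0
    else:
        offset = (w.sighting_date - first_date).days
    return SightingMeasurement(
        day_offset=offset,
        area_ratio=w.total_area_px2 / a,
        perimeter_ratio=w.total_perimeter_px / p,
    )


def build_series(
    annotations: Sequence[WoundAnnotation], metadata: dict | None = None
) -> HealingSeries:
    """Assemble one injury's annotations into a day-ordered healing series.

    The earliest sighting defines day 0. Duplicate dates are rejected rather
    than averaged: sightings are dated events and two tracings on one date
    are ambiguous.
    """
    if not annotations:
        raise InsufficientDataError("no annotations")
    injury_ids = {a.injury_id for a in annotations}
    if len(injury_ids) != 1:
        raise ValueError(f"annotations span several injuries: {sorted(injury_ids)}")
    dates = [a.sighting_date for a in annotations]
    if len(set(dates)) != len(dates):
        dupes = sorted({d for d in dates if dates.count(d) > 1})
        raise AmbiguousDateError(f"duplicate sighting dates {dupes}")
    if len(dates) < 2:
        raise InsufficientDataError(
            "a healing series needs sightings on >=2 distinct dates"
        )
    ordered = sorted(annotations, key=lambda a: a.sighting_date)
    first = ordered[0].sighting_date
    measurements = tuple(normalized_extent(a, first_date=first) for a in ordered)
    return HealingSeries(
        injury_id=ordered[0].injury_id,
        measurements=measurements,
        shark_id=ordered[0].shark_id,
        metadata=dict(metadata or {}),
    )


# ---------------------------------------------------------------------------
# I/O: JSON (one document per injury case) and long-format vertex CSV
# ---------------------------------------------------------------------------

def _parse_date(s: str) -> date:
    return datetime.strptime(s, "%Y-%m-%d").date()


def _annotation_from_sighting(doc: dict, sighting: dict) -> WoundAnnotation:
    fin = sighting.get("dorsal_fin")
    return WoundAnnotation(
        shark_id=str(doc["shark_id"]),
        injury_id=str(doc["injury_id"]),
        sighting_date=_parse_date(sighting["date"]),
        sections=tuple(Polygon(v) for v in sighting["sections"]),
        anchor=AnchorScale(Polygon(sighting["anchor"])),
        image_id=str(sighting.get("image_id", "")),
        dorsal_fin=Polygon(fin) if fin else None,
    )


def load_cases_json(path: str | Path) -> dict[str, list[WoundAnnotation]]:
    """Read injury cases from a JSON file.

    The file holds a list of case documents, each with ``shark_id``,
    ``injury_id``, optional ``labels`` and a ``sightings`` list; every
    sighting carries an ISO-8601 ``date``, ``anchor`` polygon, ``sections``
    polygon list and optionally ``image_id`` and ``dorsal_fin``.
    Returns a mapping injury_id -> annotations; label dicts are attached to
    the first annotation's metadata via :func:`case_labels_json`.
    """
    docs = json.loads(Path(path).read_text())
    if isinstance(docs, dict):
        docs = [docs]
    cases: dict[str, list[WoundAnnotation]] = {}
    for doc in docs:
        anns = [_annotation_from_sighting(doc, s) for s in doc["sightings"]]
        cases[str(doc["injury_id"])] = anns
    return cases


def case_labels_json(path: str | Path) -> dict[str, dict]:
    """Return injury_id -> labels mapping from a case JSON file."""
    docs = json.loads(Path(path).read_text())
    if isinstance(docs, dict):
        docs = [docs]
    return {str(d["injury_id"]): dict(d.get("labels", {})) for d in docs}


def load_cases_csv(path: str | Path) -> dict[str, list[WoundAnnotation]]:
    """Read injury cases from a long-format vertex CSV.

    One row per vertex with columns ``injury_id, shark_id, date, image_id,
    role, x, y`` where ``role`` is ``anchor``, ``dorsal`` or ``section_<k>``.
    Vertex order within a polygon follows row order.
    """
    rows = list(csv.DictReader(open(path, newline="")))
    by_sighting: dict[tuple[str, str], dict] = {}
    for r in rows:
        key = (r["injury_id"], r["date"])
        entry = by_sighting.setdefault(
            key,
            {
                "shark_id": r.get("shark_id", ""),
                "image_id": r.get("image_id", ""),
                "polys": {},
            },
        )
        entry["polys"].setdefault(r["role"], []).append(
            (float(r["x"]), float(r["y"]))
        )
    cases: dict[str, list[WoundAnnotation]] = {}
    for (injury_id, d), entry in sorted(by_sighting.items()):
        polys = entry["polys"]
        if "anchor" not in polys:
            raise DegenerateScaleError(f"{injury_id}@{d}: no anchor polygon")
        section_roles = sorted(k for k in polys if k.startswith("section"))
        if not section_roles:
            raise InvalidGeometryError(f"{injury_id}@{d}: no wound sections")
        ann = WoundAnnotation(
            shark_id=str(entry["shark_id"]),
            injury_id=injury_id,
            sighting_date=_parse_date(d),
            sections=tuple(Polygon(polys[k]) for k in section_roles),
            anchor=AnchorScale(Polygon(polys["anchor"])),
            image_id=str(entry["image_id"]),
            dorsal_fin=Polygon(polys["dorsal"]) if "dorsal" in polys else None,
        )
        cases.setdefault(injury_id, []).append(ann)
    return cases


def measurements_frame(series_list: Iterable[HealingSeries]) -> pd.DataFrame:
    """Tidy measurement table: one row per injury sighting."""
    records = []
    for s in series_list:
        for m in s.measurements:
            records.append(
                {
                    "injury_id": s.injury_id,
                    "shark_id": s.shark_id,
                    "day_offset": m.day_offset,
                    "area_ratio": m.area_ratio,
                    "perimeter_ratio": m.perimeter_ratio,
                }
            )
    return pd.DataFrame.from_records(
        records,
        columns=["injury_id", "shark_id", "day_offset", "area_ratio", "perimeter_ratio"],
    )
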