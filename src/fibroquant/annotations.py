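"""Polygon annotations labelling training regions per tissue class.

Polygons live in pixel coordinates of a named image level; the raster
convention is half-open with origin at the top-left pixel corner, so a
pixel ``(x, y)`` belongs to a polygon iff its centre ``(x+0.5, y+0.5)``
is covered by the polygon.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np
import shapely
from shapely.geometry import Polygon, mapping, shape

from fibroquant.exceptions import FormatError, ParameterError


@dataclass(frozen=True)
class AnnotationEntry:
    image_id: str
    level: int
    polygon: Polygon
    class_label: str

    def __post_init__(self) -> None:
        if not isinstance(self.polygon, Polygon) or not self.polygon.is_valid:
            raise ParameterError(f"invalid polygon for class {self.class_label!r}")


@dataclass
class AnnotationSet:
    entries: list[AnnotationEntry] = field(default_factory=list)

    def __iter__(self) -> Iterator[AnnotationEntry]:
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def class_labels(self) -> tuple[str, ...]:
        seen: list[str] = []
        for e in self.entries:
            if e.class_label not in seen:
                seen.append(e.class_label)
        return tuple(seen)

    @property
    def image_ids(self) -> tuple[str, ...]:
        seen: list[str] = []
        for e in self.entries:
            if e.image_id not in seen:
                seen.append(e.image_id)
        return tuple(seen)

    def for_image(self, image_id: str) -> "AnnotationSet":
        return AnnotationSet([e for e in self.entries if e.image_id == image_id])

    def extend(self, other: Iterable[AnnotationEntry]) -> None:
        self.entries.extend(other)


def rasterize_polygon(polygon: Polygon, shape_hw: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Row/column indices of pixels whose centres the polygon covers."""
    h, w = shape_hw
    x0, y0, x1, y1 = polygon.bounds
    cx0 = max(0, int(np.floor(x0)))
    cy0 = max(0, int(np.floor(y0)))
    cx1 = min(w, int(np.ceil(x1)))
    cy1 = min(h, int(np.ceil(y1)))
    if cx1 <= cx0 or cy1 <= cy0:
        return np.empty(0, dtype=np.intp), np.empty(0, dtype=np.intp)
    xs, ys = np.meshgrid(
        np.arange(cx0, cx1) + 0.5, np.arange(cy0, cy1) + 0.5
    )
    inside = shapely.covers(polygon, shapely.points(xs.ravel(), ys.ravel()))
    inside = inside.reshape(ys.shape)
    ry, rx = np.nonzero(inside)
    return ry + cy0, rx + cx0


def to_geojson(annotations: AnnotationSet, path=None) -> dict:
    """Serialize as a GeoJSON FeatureCollection (property "class")."""
    features = []
    for e in annotations:
        features.append(
            {
                "type": "Feature",
                "geometry": mapping(e.polygon),
                "properties": {
                    "class": e.class_label,
                    "image_id": e.image_id,
                    "level": e.level,
                },
            }
        )
    fc = {"type": "FeatureCollection", "features": features}
    if path is not None:
        with open(path, "w") as fh:
            json.dump(fc, fh)
    return fc


def from_geojson(source) -> AnnotationSet:
    """Read an AnnotationSet from a GeoJSON dict or file path."""
    if isinstance(source, dict):
        fc = source
    else:
        with open(source) as fh:
            fc = json.load(fh)
    if fc.get("type") != "FeatureCollection":
        raise FormatError("expected a GeoJSON FeatureCollection")
    entries = []
    for feat in fc.get("features", []):
        props = feat.get("properties") or {}
        if "class" not in props:
            raise FormatError("annotation feature missing 'class' property")
        geom = shape(feat["geometry"])
        if not isinstance(geom, Polygon):
            raise FormatError(f"unsupported geometry type {geom.geom_type}")
        entries.append(
            AnnotationEntry(
                image_id=str(props.get("image_id", "")),
                level=int(props.get("level", 0)),
                polygon=geom,
                class_label=str(props["class"]),
            )
        )
    return AnnotationSet(entries)
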