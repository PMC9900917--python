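"""Labeled spatial annotations: points, circles, and polygons.

Annotations carry a coordinate frame (an overlay name or "image") and an
ordered list of labeled geometries in level-0 pixel units.  They round-trip
through a plain CSV (``label,geometry,data``), can be imported from napari's
delimited point/shape tables, and can be stamped onto an overlay: each spot
or cell receives the label of the first annotation that contains it (circles
by Euclidean distance, spatial domains by even-odd point-in-polygon with
boundary counted as inside).
"""

from __future__ import annotations

import csv
import math
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError
from .features import Overlay

__all__ = [
    "Point",
    "Circle",
    "Polygon",
    "AnnotationSet",
    "export_annotations",
    "import_annotations",
    "point_in_polygon",
    "assign_labels",
    "UNLABELED",
]

UNLABELED = ""


@dataclass(frozen=True)
class Point:
    x: float
    y: float


@dataclass(frozen=True)
class Circle:
    x: float
    y: float
    diameter_um: float

    def __post_init__(self):
        if not self.diameter_um > 0:
            raise ValidationError(f"circle diameter must be positive, got {self.diameter_um}")


@dataclass(frozen=True)
class Polygon:
    vertices: tuple[tuple[float, float], ...]

    def __post_init__(self):
        object.__setattr__(
            self, "vertices", tuple((float(x), float(y)) for x, y in self.vertices)
        )
        if len(self.vertices) < 3:
            raise ValidationError(
                f"polygon needs >= 3 vertices, got {len(self.vertices)}"
            )
        if abs(_signed_area(self.vertices)) == 0.0:
            raise ValidationError("polygon has zero area")


def _signed_area(vertices) -> float:
    area = 0.0
    n = len(vertices)
    for i in range(n):
        x1, y1 = vertices[i]
        x2, y2 = vertices[(i + 1) % n]
        area += x1 * y2 - x2 * y1
    return area / 2.0


Geometry = Point | Circle | Polygon


@dataclass
class AnnotationSet:
    """Ordered labeled geometries in one coordinate frame.

    Order matters: when annotations overlap, the first record containing a
    point wins.
    """

    coord_frame: str
    records: list[tuple[str, Geometry]]

    def __post_init__(self):
        for label, geom in self.records:
            if not label:
                raise ValidationError("annotation labels must be non-empty")
            if not isinstance(geom, (Point, Circle, Polygon)):
                raise ValidationError(f"unsupported geometry {type(geom).__name__}")


def _fmt(v: float) -> str:
    return repr(float(v))


def _geom_to_row(geom: Geometry) -> tuple[str, str]:
    if isinstance(geom, Point):
        return "point", f"{_fmt(geom.x)} {_fmt(geom.y)}"
    if isinstance(geom, Circle):
        return "circle", f"{_fmt(geom.x)} {_fmt(geom.y)} {_fmt(geom.diameter_um)}"
    return "polygon", ";".join(f"{_fmt(x)} {_fmt(y)}" for x, y in geom.vertices)


def _geom_from_row(kind: str, data: str, line_no: int) -> Geometry:
    try:
        if kind == "point":
            x, y = data.split()
            return Point(float(x), float(y))
        if kind == "circle":
            x, y, d = data.split()
            return Circle(float(x), float(y), float(d))
        if kind == "polygon":
            verts = []
            for pair in data.split(";"):
                x, y = pair.split()
                verts.append((float(x), float(y)))
            return Polygon(tuple(verts))
    except (ValueError, ValidationError) as exc:
        raise FormatError(f"line {line_no}: malformed {kind} data {data!r}: {exc}") from None
    raise FormatError(f"line {line_no}: unknown geometry kind {kind!r}")


def export_annotations(annotations: AnnotationSet, path) -> str:
    """Write the native CSV (``label,geometry,data``); import inverts it."""
    path = os.fspath(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["label", "geometry", "data"])
        for label, geom in annotations.records:
            kind, data = _geom_to_row(geom)
            writer.writerow([label, kind, data])
    return path


def import_annotations(
    path, dialect: str = "native", coord_frame: str = "image"
) -> AnnotationSet:
    """Read annotations from a CSV in one of the supported dialects.

    ``native`` inverts :func:`export_annotations`.  ``napari_points`` maps a
    points table (``axis-0`` is the row coordinate, ``axis-1`` the column, so
    they become y and x).  ``napari_shapes`` groups a shapes table by shape
    index and keeps polygon rows.
    """
    if dialect == "native":
        return _import_native(path, coord_frame)
    if dialect == "napari_points":
        return _import_napari_points(path, coord_frame)
    if dialect == "napari_shapes":
        return _import_napari_shapes(path, coord_frame)
    raise ValueError(
        f"unknown dialect {dialect!r}; expected native, napari_points or napari_shapes"
    )


def _import_native(path, coord_frame: str) -> AnnotationSet:
    records: list[tuple[str, Geometry]] = []
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != ["label", "geometry", "data"]:
            raise FormatError(
                f"native annotation CSV must start with 'label,geometry,data', got {header}"
            )
        for line_no, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 3:
                raise FormatError(f"line {line_no}: expected 3 fields, got {len(row)}")
            label, kind, data = row
            records.append((label, _geom_from_row(kind, data, line_no)))
    return AnnotationSet(coord_frame=coord_frame, records=records)


def _napari_label(row, default: str) -> str:
    for key in ("label", "name", "annotation"):
        if key in row and str(row[key]):
            return str(row[key])
    return default


def _import_napari_points(path, coord_frame: str) -> AnnotationSet:
    df = pd.read_csv(path)
    needed = {"axis-0", "axis-1"}
    if not needed <= set(df.columns):
        raise FormatError(
            f"napari points table needs columns axis-0 and axis-1, has {list(df.columns)}"
        )
    records = []
    for _, row in df.iterrows():
        label = _napari_label(row, "point")
        # napari axis order is (row, column) -> (y, x)
        records.append((label, Point(x=float(row["axis-1"]), y=float(row["axis-0"]))))
    return AnnotationSet(coord_frame=coord_frame, records=records)


def _import_napari_shapes(path, coord_frame: str) -> AnnotationSet:
    df = pd.read_csv(path)
    needed = {"index", "shape-type", "axis-0", "axis-1"}
    if not needed <= set(df.columns):
        raise FormatError(
            f"napari shapes table needs columns {sorted(needed)}, has {list(df.columns)}"
        )
    records = []
    for idx, grp in df.groupby("index", sort=True):
        kind = str(grp["shape-type"].iloc[0])
        if kind not in ("polygon", "rectangle"):
            continue  # lines/ellipses have no native counterpart
        verts = tuple(
            (float(r["axis-1"]), float(r["axis-0"])) for _, r in grp.iterrows()
        )
        label = _napari_label(grp.iloc[0], f"shape{idx}")
        records.append((label, Polygon(verts)))
    return AnnotationSet(coord_frame=coord_frame, records=records)


def _on_segment(px, py, x1, y1, x2, y2, eps) -> bool:
    cross = (x2 - x1) * (py - y1) - (y2 - y1) * (px - x1)
    seg_len = math.hypot(x2 - x1, y2 - y1)
    if seg_len == 0:
        return math.hypot(px - x1, py - y1) <= eps
    if abs(cross) / seg_len > eps:
        return False
    dot = (px - x1) * (x2 - x1) + (py - y1) * (y2 - y1)
    return -eps * seg_len <= dot <= seg_len * seg_len + eps * seg_len


def point_in_polygon(point, polygon) -> bool:
    """Even-odd (ray crossing) containment; boundary points count as inside."""
    if isinstance(polygon, Polygon):
        verts = polygon.vertices
    else:
        verts = tuple((float(x), float(y)) for x, y in polygon)
        if len(verts) < 3 or _signed_area(verts) == 0.0:
            raise ValidationError("degenerate polygon")
    if isinstance(point, Point):
        px, py = point.x, point.y
    else:
        px, py = float(point[0]), float(point[1])
    scale = max(max(abs(x), abs(y)) for x, y in verts) + 1.0
    eps = 1e-12 * scale
    n = len(verts)
    for i in range(n):
        x1, y1 = verts[i]
        x2, y2 = verts[(i + 1) % n]
        if _on_segment(px, py, x1, y1, x2, y2, eps):
            return True
    inside = False
    for i in range(n):
        x1, y1 = verts[i]
        x2, y2 = verts[(i + 1) % n]
        if (y1 > py) != (y2 > py):
            x_cross = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
            if px < x_cross:
                inside = not inside
    return inside


def assign_labels(
    overlay: Overlay,
    annotations: AnnotationSet,
    microns_per_pixel: float | None = None,
) -> pd.DataFrame:
    """Label each overlay point with the first annotation containing it.

    Circles match by Euclidean distance <= radius (diameter converted μm ->
    px through ``microns_per_pixel``); polygons by point-in-polygon.  Point
    annotations are freestanding marks and never capture overlay rows.
    Unmatched rows get the empty-string sentinel.
    """
    has_circles = any(isinstance(g, Circle) for _, g in annotations.records)
    if has_circles and microns_per_pixel is None:
        raise ValueError(
            "assigning circle annotations requires microns_per_pixel from the manifest"
        )
    labels = [UNLABELED] * overlay.n_points
    taken = np.zeros(overlay.n_points, dtype=bool)
    for label, geom in annotations.records:
        if isinstance(geom, Point):
            continue
        if isinstance(geom, Circle):
            radius_px = (geom.diameter_um / microns_per_pixel) / 2.0
            d = np.hypot(overlay.x - geom.x, overlay.y - geom.y)
            hit = (d <= radius_px) & ~taken
            for i in np.flatnonzero(hit):
                labels[i] = label
            taken |= hit
        else:
            for i in range(overlay.n_points):
                if not taken[i] and point_in_polygon(
                    (overlay.x[i], overlay.y[i]), geom
                ):
                    labels[i] = label
                    taken[i] = True
    return pd.DataFrame({"id": overlay.ids, "label": labels})
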