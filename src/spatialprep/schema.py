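"""Sample folder layout: the master JSON manifest and its validation.

A *sample folder* is a self-contained directory holding one manifest
(``sample.json``), tiled image pyramids, overlay coordinate CSVs and chunked
feature stores.  The manifest ties them together: each feature group refers
to exactly one overlay, and ``microns_per_pixel`` anchors level-0 pixels to
physical scale.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

from ._json import dump_stable
from .errors import ValidationError

MANIFEST_NAME = "sample.json"

__all__ = [
    "ImageSpec",
    "OverlaySpec",
    "FeatureGroupSpec",
    "SampleMeta",
    "write_sample_meta",
    "read_sample_meta",
    "validate_sample",
    "MANIFEST_NAME",
]


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValidationError(msg)


@dataclass(frozen=True)
class ImageSpec:
    """One tiled pyramid: file path plus the geometry needed to address it."""

    path: str
    channels: tuple[str, ...]
    width: int
    height: int
    tile_size: int
    n_levels: int
    compression: str  # "lossless" | "jpeg"
    jpeg_quality: int | None = None

    def __post_init__(self):
        object.__setattr__(self, "channels", tuple(self.channels))
        _require(bool(self.path), "ImageSpec.path must be non-empty")
        _require(len(self.channels) >= 1, "ImageSpec.channels must list at least one channel")
        _require(self.width >= 1 and self.height >= 1, "ImageSpec dimensions must be positive")
        _require(self.tile_size >= 16, f"ImageSpec.tile_size must be >= 16, got {self.tile_size}")
        _require(self.n_levels >= 1, "ImageSpec.n_levels must be >= 1")
        _require(
            self.compression in ("lossless", "jpeg"),
            f"ImageSpec.compression must be 'lossless' or 'jpeg', got {self.compression!r}",
        )
        if self.compression == "jpeg":
            _require(
                self.jpeg_quality is not None and 1 <= self.jpeg_quality <= 100,
                "ImageSpec.jpeg_quality must be 1..100 when compression is jpeg",
            )
        else:
            _require(
                self.jpeg_quality is None,
                "ImageSpec.jpeg_quality must be absent unless compression is jpeg",
            )


@dataclass(frozen=True)
class OverlaySpec:
    """A layer of points (spots or cells) stored as a coordinate CSV."""

    name: str
    path: str
    n_points: int
    geometry: str  # "point" | "circle"
    diameter_um: float | None = None

    def __post_init__(self):
        _require(bool(self.name), "OverlaySpec.name must be non-empty")
        _require(bool(self.path), "OverlaySpec.path must be non-empty")
        _require(self.n_points >= 0, "OverlaySpec.n_points must be non-negative")
        _require(
            self.geometry in ("point", "circle"),
            f"OverlaySpec.geometry must be 'point' or 'circle', got {self.geometry!r}",
        )
        if self.geometry == "circle":
            _require(
                self.diameter_um is not None and self.diameter_um > 0,
                "OverlaySpec.diameter_um must be positive for circle geometry",
            )
        else:
            _require(
                self.diameter_um is None,
                "OverlaySpec.diameter_um must be absent for point geometry",
            )


@dataclass(frozen=True)
class FeatureGroupSpec:
    """A chunked store of per-point values, attached to one overlay."""

    name: str
    overlay_name: str
    path: str
    feature_names: tuple[str, ...]
    value_kind: str  # "quantitative" | "categorical"

    def __post_init__(self):
        object.__setattr__(self, "feature_names", tuple(self.feature_names))
        _require(bool(self.name), "FeatureGroupSpec.name must be non-empty")
        _require(bool(self.overlay_name), "FeatureGroupSpec.overlay_name must be non-empty")
        _require(bool(self.path), "FeatureGroupSpec.path must be non-empty")
        _require(
            all(self.feature_names),
            f"FeatureGroupSpec {self.name!r}: feature names must be non-empty",
        )
        _require(
            len(set(self.feature_names)) == len(self.feature_names),
            f"FeatureGroupSpec {self.name!r}: feature names must be unique",
        )
        _require(
            self.value_kind in ("quantitative", "categorical"),
            f"FeatureGroupSpec.value_kind must be 'quantitative' or 'categorical',"
            f" got {self.value_kind!r}",
        )


@dataclass(frozen=True)
class SampleMeta:
    """The master manifest for one sample folder."""

    name: str
    microns_per_pixel: float
    images: tuple[ImageSpec, ...] = ()
    overlays: tuple[OverlaySpec, ...] = ()
    feature_groups: tuple[FeatureGroupSpec, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "images", tuple(self.images))
        object.__setattr__(self, "overlays", tuple(self.overlays))
        object.__setattr__(self, "feature_groups", tuple(self.feature_groups))
        _require(bool(self.name), "SampleMeta.name must be non-empty")
        _require(
            self.microns_per_pixel > 0,
            f"SampleMeta.microns_per_pixel must be > 0, got {self.microns_per_pixel}",
        )
        overlay_names = [o.name for o in self.overlays]
        _require(
            len(set(overlay_names)) == len(overlay_names),
            "SampleMeta.overlays must have unique names",
        )
        for fg in self.feature_groups:
            _require(
                overlay_names.count(fg.overlay_name) == 1,
                f"feature group {fg.name!r} references overlay {fg.overlay_name!r}, "
                f"which does not match exactly one overlay",
            )


def _meta_to_dict(meta: SampleMeta) -> dict:
    def img(i: ImageSpec) -> dict:
        d = {
            "path": i.path,
            "channels": list(i.channels),
            "width": i.width,
            "height": i.height,
            "tile_size": i.tile_size,
            "n_levels": i.n_levels,
            "compression": i.compression,
        }
        if i.jpeg_quality is not None:
            d["jpeg_quality"] = i.jpeg_quality
        return d

    def ovl(o: OverlaySpec) -> dict:
        d = {"name": o.name, "path": o.path, "n_points": o.n_points, "geometry": o.geometry}
        if o.diameter_um is not None:
            d["diameter_um"] = float(o.diameter_um)
        return d

    def fg(g: FeatureGroupSpec) -> dict:
        return {
            "name": g.name,
            "overlay_name": g.overlay_name,
            "path": g.path,
            "feature_names": list(g.feature_names),
            "value_kind": g.value_kind,
        }

    return {
        "name": meta.name,
        "microns_per_pixel": float(meta.microns_per_pixel),
        "images": [img(i) for i in meta.images],
        "overlays": [ovl(o) for o in meta.overlays],
        "feature_groups": [fg(g) for g in meta.feature_groups],
    }


_REQUIRED_KEYS = {"name", "microns_per_pixel", "images", "overlays", "feature_groups"}


def _meta_from_dict(doc: dict) -> SampleMeta:
    if not isinstance(doc, dict):
        raise ValidationError("manifest root must be a JSON object")
    missing = sorted(_REQUIRED_KEYS - doc.keys())
    if missing:
        raise ValidationError(f"manifest missing required keys: {', '.join(missing)}")
    try:
        images = tuple(
            ImageSpec(
                path=i["path"],
                channels=tuple(i["channels"]),
                width=i["width"],
                height=i["height"],
                tile_size=i["tile_size"],
                n_levels=i["n_levels"],
                compression=i["compression"],
                jpeg_quality=i.get("jpeg_quality"),
            )
            for i in doc["images"]
        )
        overlays = tuple(
            OverlaySpec(
                name=o["name"],
                path=o["path"],
                n_points=o["n_points"],
                geometry=o["geometry"],
                diameter_um=o.get("diameter_um"),
            )
            for o in doc["overlays"]
        )
        groups = tuple(
            FeatureGroupSpec(
                name=g["name"],
                overlay_name=g["overlay_name"],
                path=g["path"],
                feature_names=tuple(g["feature_names"]),
                value_kind=g["value_kind"],
            )
            for g in doc["feature_groups"]
        )
    except KeyError as exc:
        raise ValidationError(f"manifest entry missing key {exc.args[0]!r}") from None
    return SampleMeta(
        name=doc["name"],
        microns_per_pixel=doc["microns_per_pixel"],
        images=images,
        overlays=overlays,
        feature_groups=groups,
    )


def write_sample_meta(meta: SampleMeta, folder) -> str:
    """Write ``sample.json`` into ``folder``; byte-stable for equal metas."""
    folder = os.fspath(folder)
    if not os.path.isdir(folder):
        raise IOError(f"sample folder does not exist: {folder}")
    path = os.path.join(folder, MANIFEST_NAME)
    dump_stable(_meta_to_dict(meta), path)
    return path


def read_sample_meta(path) -> SampleMeta:
    """Parse and re-validate a manifest file."""
    with open(path, "r", encoding="utf-8") as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ValidationError(f"manifest is not valid JSON: {exc}") from None
    return _meta_from_dict(doc)


def validate_sample(folder) -> list[str]:
    """Check a sample folder end to end; the returned findings are empty iff
    the folder is internally consistent.

    Covers: manifest parse, referenced-file existence, overlay row counts
    against ``n_points``, and feature-store index integrity (byte ranges and
    point-count agreement with the overlay).
    """
    folder = os.fspath(folder)
    findings: list[str] = []
    manifest = os.path.join(folder, MANIFEST_NAME)
    if not os.path.isfile(manifest):
        return [f"missing manifest {MANIFEST_NAME}"]
    try:
        meta = read_sample_meta(manifest)
    except ValidationError as exc:
        return [f"manifest invalid: {exc}"]

    overlay_counts: dict[str, int] = {}
    for img in meta.images:
        p = os.path.join(folder, img.path)
        if not os.path.isfile(p):
            findings.append(f"image file missing: {img.path}")
            continue
        from .pyramid import PyramidReader  # local import avoids a cycle

        try:
            reader = PyramidReader.open(p)
        except Exception as exc:
            findings.append(f"image {img.path} unreadable as a pyramid: {exc}")
            continue
        if reader.n_levels != img.n_levels:
            findings.append(
                f"image {img.path}: manifest says {img.n_levels} levels, file has {reader.n_levels}"
            )
        if reader.level_shape(0) != (img.height, img.width):
            findings.append(
                f"image {img.path}: manifest dims {img.width}x{img.height} do not match file"
            )
        findings.extend(f"image {img.path}: {f}" for f in reader.validate_index())

    for ovl in meta.overlays:
        p = os.path.join(folder, ovl.path)
        if not os.path.isfile(p):
            findings.append(f"overlay file missing: {ovl.path}")
            continue
        with open(p, "r", encoding="utf-8") as fh:
            n_rows = sum(1 for _ in fh) - 1  # header line
        overlay_counts[ovl.name] = n_rows
        if n_rows != ovl.n_points:
            findings.append(
                f"overlay {ovl.name!r}: manifest says {ovl.n_points} points, "
                f"file {ovl.path} has {n_rows} rows"
            )

    for fg in meta.feature_groups:
        payload = os.path.join(folder, fg.path)
        index_path = feature_index_path(payload)
        if not os.path.isfile(payload):
            findings.append(f"feature store payload missing: {fg.path}")
            continue
        if not os.path.isfile(index_path):
            findings.append(
                f"feature store index missing: {os.path.relpath(index_path, folder)}"
            )
            continue
        try:
            with open(index_path, "r", encoding="utf-8") as fh:
                index = json.load(fh)
        except json.JSONDecodeError as exc:
            findings.append(f"feature store index {fg.path}: not valid JSON: {exc}")
            continue
        payload_size = os.path.getsize(payload)
        prev_end = 0
        names = []
        for rec in index.get("features", []):
            names.append(rec["name"])
            if rec["offset"] < prev_end:
                findings.append(
                    f"feature group {fg.name!r}: byte range for {rec['name']!r} overlaps"
                )
            if rec["offset"] + rec["length"] > payload_size:
                findings.append(
                    f"feature group {fg.name!r}: byte range for {rec['name']!r} "
                    f"exceeds payload size {payload_size}"
                )
            prev_end = rec["offset"] + rec["length"]
        if tuple(names) != fg.feature_names:
            findings.append(
                f"feature group {fg.name!r}: index feature names disagree with manifest"
            )
        n_points = index.get("n_points")
        expected = overlay_counts.get(fg.overlay_name)
        if expected is not None and n_points != expected:
            findings.append(
                f"feature group {fg.name!r}: index n_points={n_points} but overlay "
                f"{fg.overlay_name!r} has {expected} rows"
            )
    return findings


def feature_index_path(payload_path) -> str:
    """``<name>.bin`` payload -> ``<name>.index.json`` sidecar path."""
    p = os.fspath(payload_path)
    stem = p[:-4] if p.endswith(".bin") else p
    return stem + ".index.json"
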