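"""Sparsified, chunked, compressed per-feature value store.

The store separates *coordinates* from *values*: an :class:`Overlay` is an
ordered layer of points (Visium spots, segmented cells) sharing one
coordinate frame, and a feature group attaches one value per point per
feature (e.g. one gene's expression).  Each feature is serialized as a tiny
sparse CSV record (``index,value`` lines), deflate-compressed independently,
and concatenated into a payload file whose JSON sidecar index maps feature
name -> byte range.  Reading one gene therefore costs one small index fetch
plus one record-sized range read, never the whole matrix.
"""

from __future__ import annotations

import json
import os
import zlib
from dataclasses import dataclass, field

import numpy as np

from ._json import dump_stable
from .errors import FormatError, ValidationError
from .rangeio import FileRangeReader, RangeReader
from .schema import FeatureGroupSpec, feature_index_path

__all__ = [
    "Overlay",
    "SparseFeature",
    "sparsify",
    "densify",
    "write_feature_group",
    "FeatureGroupReader",
    "list_features",
    "read_feature",
    "log_transform_counts",
    "encode_categorical",
    "decode_categorical",
]


@dataclass
class Overlay:
    """Ordered point layer: ids with level-0 pixel coordinates."""

    name: str
    ids: list[str]
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self):
        self.ids = [str(i) for i in self.ids]
        self.x = np.asarray(self.x, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.float64)
        if not (len(self.ids) == self.x.size == self.y.size):
            raise ValidationError(
                f"overlay {self.name!r}: ids/x/y lengths differ "
                f"({len(self.ids)}/{self.x.size}/{self.y.size})"
            )
        if len(set(self.ids)) != len(self.ids):
            raise ValidationError(f"overlay {self.name!r}: ids must be unique")

    @property
    def n_points(self) -> int:
        return len(self.ids)

    def to_csv(self, path) -> None:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("id,x,y\n")
            for i, xv, yv in zip(self.ids, self.x, self.y):
                fh.write(f"{i},{float(xv)!r},{float(yv)!r}\n")

    @classmethod
    def from_csv(cls, path, name: str | None = None) -> "Overlay":
        ids, xs, ys = [], [], []
        with open(path, "r", encoding="utf-8") as fh:
            header = fh.readline().strip()
            if header != "id,x,y":
                raise FormatError(f"overlay CSV must start with 'id,x,y', got {header!r}")
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                i, xv, yv = line.split(",")
                ids.append(i)
                xs.append(float(xv))
                ys.append(float(yv))
        if name is None:
            name = os.path.splitext(os.path.basename(os.fspath(path)))[0]
        return cls(name=name, ids=ids, x=np.array(xs), y=np.array(ys))


@dataclass
class SparseFeature:
    """Nonzero entries of one feature column over an overlay."""

    name: str
    indices: np.ndarray  # strictly increasing row positions
    values: np.ndarray

    def __post_init__(self):
        self.indices = np.asarray(self.indices, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.indices.size != self.values.size:
            raise ValidationError(
                f"feature {self.name!r}: {self.indices.size} indices vs "
                f"{self.values.size} values"
            )
        if self.indices.size and (
            np.any(np.diff(self.indices) <= 0) or self.indices[0] < 0
        ):
            raise ValidationError(
                f"feature {self.name!r}: indices must be strictly increasing and non-negative"
            )

    @property
    def n_nonzero(self) -> int:
        return int(self.indices.size)


def sparsify(dense, feature_names: list[str]) -> list[SparseFeature]:
    """Split a points x features matrix into per-column sparse features.

    Zeros are dropped; densifying each result reproduces its column exactly.
    NaNs are rejected (impute or drop upstream).
    """
    try:
        import scipy.sparse as sp

        if sp.issparse(dense):
            dense = np.asarray(dense.todense())
    except ImportError:  # pragma: no cover
        pass
    dense = np.asarray(dense, dtype=np.float64)
    if dense.ndim != 2:
        raise ValueError(f"expected a 2-D matrix, got shape {dense.shape}")
    if dense.shape[1] != len(feature_names):
        raise ValueError(
            f"matrix has {dense.shape[1]} columns but {len(feature_names)} names"
        )
    if np.isnan(dense).any():
        raise ValueError("matrix contains NaN; impute or drop before sparsifying")
    out = []
    for j, name in enumerate(feature_names):
        col = dense[:, j]
        idx = np.flatnonzero(col)
        out.append(SparseFeature(name=name, indices=idx, values=col[idx]))
    return out


def densify(feature: SparseFeature, n_points: int) -> np.ndarray:
    if feature.indices.size and feature.indices[-1] >= n_points:
        raise ValidationError(
            f"feature {feature.name!r}: index {int(feature.indices[-1])} "
            f">= n_points {n_points}"
        )
    dense = np.zeros(n_points, dtype=np.float64)
    dense[feature.indices] = feature.values
    return dense


def _fmt_value(v: float) -> str:
    return str(int(v)) if float(v).is_integer() and abs(v) < 2**53 else repr(float(v))


def _encode_record(feature: SparseFeature) -> bytes:
    lines = "".join(
        f"{int(i)},{_fmt_value(v)}\n" for i, v in zip(feature.indices, feature.values)
    )
    return zlib.compress(lines.encode("ascii"), 6)


def _decode_record(data: bytes, name: str) -> SparseFeature:
    text = zlib.decompress(data).decode("ascii")
    idx, vals = [], []
    for line in text.splitlines():
        i, v = line.split(",")
        idx.append(int(i))
        vals.append(float(v))
    return SparseFeature(name=name, indices=np.array(idx, dtype=np.int64),
                         values=np.array(vals, dtype=np.float64))


def write_feature_group(
    overlay: Overlay,
    features: list[SparseFeature],
    out,
    name: str | None = None,
    value_kind: str = "quantitative",
    categories: list[str] | None = None,
) -> FeatureGroupSpec:
    """Write payload ``<out>`` plus sidecar ``<out minus .bin>.index.json``.

    Feature records are concatenated in the given order with ascending,
    non-overlapping byte ranges; the index alone suffices to locate any one.
    """
    out = os.fspath(out)
    names = [f.name for f in features]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate feature names: {dupes}")
    for f in features:
        if f.indices.size and f.indices[-1] >= overlay.n_points:
            raise ValidationError(
                f"feature {f.name!r} indexes row {int(f.indices[-1])} but overlay "
                f"{overlay.name!r} has {overlay.n_points} points"
            )
    if value_kind == "categorical" and categories is None:
        raise ValueError("categorical groups need a code->label table")

    records = [_encode_record(f) for f in features]
    index_entries = []
    offset = 0
    for f, rec in zip(features, records):
        index_entries.append(
            {"name": f.name, "offset": offset, "length": len(rec), "n": f.n_nonzero}
        )
        offset += len(rec)
    with open(out, "wb") as fh:
        for rec in records:
            fh.write(rec)
    index = {
        "codec": "deflate",
        "overlay": overlay.name,
        "n_points": overlay.n_points,
        "value_kind": value_kind,
        "features": index_entries,
    }
    if categories is not None:
        index["categories"] = list(categories)
    dump_stable(index, feature_index_path(out))
    if name is None:
        name = os.path.splitext(os.path.basename(out))[0]
    return FeatureGroupSpec(
        name=name,
        overlay_name=overlay.name,
        path=os.path.basename(out),
        feature_names=tuple(names),
        value_kind=value_kind,
    )


class FeatureGroupReader:
    """Lazy reader: loads the index once, then range-reads single records."""

    def __init__(self, payload: RangeReader, index_bytes_raw: bytes):
        self.payload = payload
        self.index_bytes = len(index_bytes_raw)
        try:
            self.index = json.loads(index_bytes_raw)
        except json.JSONDecodeError as exc:
            raise FormatError(f"feature index is not valid JSON: {exc}") from None
        if self.index.get("codec") != "deflate":
            raise FormatError(f"unsupported codec {self.index.get('codec')!r}")
        self.n_points = int(self.index["n_points"])
        self._entries = {rec["name"]: rec for rec in self.index["features"]}
        self.categories = self.index.get("categories")

    @classmethod
    def open(cls, payload_path, index_path=None) -> "FeatureGroupReader":
        if index_path is None:
            index_path = feature_index_path(payload_path)
        with open(index_path, "rb") as fh:
            raw = fh.read()
        return cls(FileRangeReader(payload_path), raw)

    def list_features(self) -> list[str]:
        return [rec["name"] for rec in self.index["features"]]

    def read_feature(self, name: str) -> tuple[np.ndarray, int]:
        """Densified vector for one feature plus the payload bytes this cost."""
        rec = self._entries.get(name)
        if rec is None:
            near = sorted(
                self._entries, key=lambda n: (not n.startswith(name[:3]), n)
            )[:5]
            raise KeyError(f"unknown feature {name!r}; nearest: {near}")
        start = self.payload.total_bytes_fetched
        data = self.payload.read(rec["offset"], rec["length"])
        sparse = _decode_record(data, name)
        if sparse.n_nonzero != rec["n"]:
            raise FormatError(
                f"feature {name!r}: index says {rec['n']} nonzeros, record has "
                f"{sparse.n_nonzero}"
            )
        return densify(sparse, self.n_points), self.payload.total_bytes_fetched - start

    def read_sparse(self, name: str) -> SparseFeature:
        rec = self._entries[name]
        return _decode_record(self.payload.read(rec["offset"], rec["length"]), name)


def list_features(store: FeatureGroupReader) -> list[str]:
    return store.list_features()


def read_feature(store: FeatureGroupReader, name: str) -> tuple[np.ndarray, int]:
    return store.read_feature(name)


def log_transform_counts(counts) -> np.ndarray:
    """Elementwise natural log of (1 + count)."""
    arr = np.asarray(counts, dtype=np.float64)
    if arr.size and arr.min() < 0:
        raise ValueError(f"counts must be non-negative, found {arr.min()}")
    return np.log1p(arr)


def encode_categorical(labels) -> tuple[np.ndarray, list[str]]:
    """Map string labels to integer codes; "" encodes as 0 (absent).

    The returned table lists the non-empty labels; code k (k >= 1) means
    ``table[k - 1]``.
    """
    table: list[str] = []
    seen: dict[str, int] = {}
    codes = np.zeros(len(labels), dtype=np.float64)
    for i, lab in enumerate(labels):
        lab = str(lab)
        if lab == "":
            continue
        if lab not in seen:
            seen[lab] = len(table) + 1
            table.append(lab)
        codes[i] = seen[lab]
    return codes, table


def decode_categorical(codes, table: list[str]) -> list[str]:
    out = []
    for c in np.asarray(codes):
        c = int(c)
        out.append("" if c == 0 else table[c - 1])
    return out
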