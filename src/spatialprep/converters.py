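"""Converters from platform output folders into lazily loadable sample folders.

Supported inputs:

* Space Ranger-style Visium output: tissue positions CSV (with or without a
  header line), ``scalefactors_json.json``, and a filtered feature-barcode
  matrix in MatrixMarket triplet form.  Counts are log1p-transformed and the
  spots become a 55 μm circle overlay.
* Vizgen MERFISH-style tables: cell-by-gene counts CSV, cell metadata CSV
  with micron-space centroids, and the provided 3x3 micron->mosaic-pixel
  affine.  Counts are stored raw; centroids are mapped into pixel space with
  the affine.
* Bare TIFF images: Gaussian-filtered (optionally) and pyramidized.
"""

from __future__ import annotations

import glob
import gzip
import json
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import tifffile

from .errors import ConversionError, FormatError
from .features import Overlay, log_transform_counts, sparsify, write_feature_group
from .pyramid import build_pyramid, gaussian_filter_image
from .schema import OverlaySpec, SampleMeta, write_sample_meta

__all__ = [
    "VisiumScaleFactors",
    "AffineMatrix",
    "parse_tissue_positions",
    "parse_scalefactors",
    "parse_mtx_counts",
    "apply_affine",
    "convert_visium",
    "convert_merfish",
    "preprocess_image",
    "VISIUM_SPOT_DIAMETER_UM",
]

# Physical diameter of a Visium capture spot; anchors pixel -> micron scale.
VISIUM_SPOT_DIAMETER_UM = 55.0

_POSITION_COLUMNS = [
    "barcode",
    "in_tissue",
    "array_row",
    "array_col",
    "pxl_row_in_fullres",
    "pxl_col_in_fullres",
]


@dataclass(frozen=True)
class VisiumScaleFactors:
    spot_diameter_fullres: float

    def __post_init__(self):
        if not (self.spot_diameter_fullres > 0 and np.isfinite(self.spot_diameter_fullres)):
            raise FormatError(
                f"spot_diameter_fullres must be positive and finite, "
                f"got {self.spot_diameter_fullres}"
            )

    @property
    def microns_per_pixel(self) -> float:
        return VISIUM_SPOT_DIAMETER_UM / self.spot_diameter_fullres


class AffineMatrix:
    """3x3 homogeneous map from micron coordinates to mosaic pixels."""

    def __init__(self, matrix):
        m = np.asarray(matrix, dtype=np.float64)
        if m.shape == (2, 3):
            m = np.vstack([m, [0.0, 0.0, 1.0]])
        if m.shape != (3, 3):
            raise ValueError(f"affine must be 3x3 (or 2x3), got shape {m.shape}")
        if not np.array_equal(m[2], [0.0, 0.0, 1.0]):
            raise ValueError(f"affine bottom row must be (0, 0, 1), got {m[2]}")
        if abs(np.linalg.det(m)) < 1e-12:
            raise ValueError("affine matrix is singular")
        self.matrix = m

    @classmethod
    def from_csv(cls, path) -> "AffineMatrix":
        rows = []
        with open(path, "r", encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if line:
                    rows.append([float(v) for v in line.split(",")])
        return cls(np.array(rows))


def apply_affine(points, affine: AffineMatrix) -> np.ndarray:
    """Map n x 2 micron coordinates through the affine into pixels."""
    if not isinstance(affine, AffineMatrix):
        affine = AffineMatrix(affine)
    pts = np.asarray(points, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError(f"points must be n x 2, got shape {pts.shape}")
    homo = np.hstack([pts, np.ones((pts.shape[0], 1))])
    return (affine.matrix @ homo.T).T[:, :2]


def parse_tissue_positions(path, name: str = "spots") -> Overlay:
    """Read Space Ranger tissue positions in either dialect.

    Accepts the headerless 6-column listing or the same columns with a header
    line.  Keeps only in-tissue rows; x is the full-resolution pixel column
    and y the pixel row (note the row/col -> y/x swap), input order preserved.
    """
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
    has_header = "barcode" in first.lower()
    df = pd.read_csv(path, header=0 if has_header else None)
    if df.shape[1] != len(_POSITION_COLUMNS):
        raise FormatError(
            f"tissue positions file has {df.shape[1]} columns; expected the 6-column "
            f"Space Ranger listing {_POSITION_COLUMNS} either headerless or with a header"
        )
    df.columns = _POSITION_COLUMNS
    kept = df[df["in_tissue"].astype(int) == 1]
    return Overlay(
        name=name,
        ids=kept["barcode"].astype(str).tolist(),
        x=kept["pxl_col_in_fullres"].to_numpy(dtype=np.float64),
        y=kept["pxl_row_in_fullres"].to_numpy(dtype=np.float64),
    )


def parse_scalefactors(path) -> VisiumScaleFactors:
    with open(path, "r", encoding="utf-8") as fh:
        doc = json.load(fh)
    if "spot_diameter_fullres" not in doc:
        raise FormatError(f"scalefactors JSON lacks 'spot_diameter_fullres': {path}")
    return VisiumScaleFactors(spot_diameter_fullres=float(doc["spot_diameter_fullres"]))


def _open_maybe_gz(stems: list[str]):
    for stem in stems:
        if os.path.isfile(stem):
            return open(stem, "rt", encoding="utf-8")
        if os.path.isfile(stem + ".gz"):
            return gzip.open(stem + ".gz", "rt", encoding="utf-8")
    raise FormatError(f"none of {stems} (or .gz) found")


def parse_mtx_counts(directory) -> tuple[sp.csr_matrix, list[str], list[str]]:
    """Read a feature-barcode matrix directory (MatrixMarket triplet).

    Expects ``matrix.mtx``, ``barcodes.tsv`` and ``features.tsv`` (a
    ``genes.tsv`` fallback is accepted), each optionally gzipped.  The matrix
    file is genes x barcodes as Space Ranger writes it; the result is
    transposed to barcodes x genes aligned with the two lists.
    """
    directory = os.fspath(directory)
    mtx_candidates = [os.path.join(directory, "matrix.mtx")]
    found = None
    for cand in mtx_candidates:
        if os.path.isfile(cand) or os.path.isfile(cand + ".gz"):
            found = cand if os.path.isfile(cand) else cand + ".gz"
    if found is None:
        raise FormatError(f"no matrix.mtx[.gz] in {directory}")
    mat = scipy.io.mmread(found).tocsr()

    with _open_maybe_gz([os.path.join(directory, "barcodes.tsv")]) as fh:
        barcodes = [line.strip().split("\t")[0] for line in fh if line.strip()]
    with _open_maybe_gz(
        [os.path.join(directory, "features.tsv"), os.path.join(directory, "genes.tsv")]
    ) as fh:
        rows = [line.rstrip("\n").split("\t") for line in fh if line.strip()]
    # features.tsv columns: id, name[, type]; prefer the human-readable name
    gene_names = [r[1] if len(r) > 1 else r[0] for r in rows]

    if mat.shape != (len(gene_names), len(barcodes)):
        raise FormatError(
            f"matrix header says {mat.shape[0]} x {mat.shape[1]} but lists have "
            f"{len(gene_names)} features and {len(barcodes)} barcodes"
        )
    return mat.T.tocsr(), barcodes, gene_names


def _read_tiff_stack(path) -> np.ndarray:
    img = tifffile.imread(path)
    if img.ndim == 2:
        img = img[None]
    elif img.ndim == 3 and img.shape[2] in (3, 4) and img.shape[0] > 8:
        img = np.moveaxis(img, 2, 0)  # H x W x C interleaved -> C x H x W
    if img.ndim != 3:
        raise FormatError(f"cannot interpret TIFF of shape {img.shape} as channels x H x W")
    return img


def convert_visium(
    spaceranger_dir,
    image_path,
    out_dir,
    sample_name: str = "visium",
    gaussian_radius: float = 4.0,
    compression: str = "lossless",
    quality: int = 90,
    tile_size: int = 512,
) -> str:
    """Convert a Space Ranger-style folder plus full-resolution image.

    The output sample folder holds (i) a pyramid of the Gaussian-filtered
    image, (ii) a circle overlay (55 μm diameter) of the spots that are both
    in tissue and present in the count matrix, ordered as in the counts, and
    (iii) one feature group of log1p-transformed gene vectors.
    """
    spaceranger_dir = os.fspath(spaceranger_dir)
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)

    pos_path = None
    for cand in ("tissue_positions.csv", "tissue_positions_list.csv"):
        p = os.path.join(spaceranger_dir, cand)
        if os.path.isfile(p):
            pos_path = p
            break
    if pos_path is None:
        matches = glob.glob(os.path.join(spaceranger_dir, "*positions*.csv"))
        if not matches:
            raise FormatError(f"no tissue positions CSV in {spaceranger_dir}")
        pos_path = matches[0]
    positions = parse_tissue_positions(pos_path)
    scale = parse_scalefactors(os.path.join(spaceranger_dir, "scalefactors_json.json"))
    counts, barcodes, genes = parse_mtx_counts(
        os.path.join(spaceranger_dir, "filtered_feature_bc_matrix")
    )

    pos_index = {b: i for i, b in enumerate(positions.ids)}
    # Positions hold all array spots; any counted barcode entirely absent from
    # the positions file indicates mismatched inputs.
    with open(pos_path, "r", encoding="utf-8") as fh:
        all_pos_barcodes = set()
        first = fh.readline()
        if "barcode" not in first.lower():
            all_pos_barcodes.add(first.split(",")[0])
        for line in fh:
            if line.strip():
                all_pos_barcodes.add(line.split(",")[0])
    missing = [b for b in barcodes if b not in all_pos_barcodes]
    if missing:
        raise ConversionError(
            f"{len(missing)} barcodes in the count matrix are absent from the "
            f"positions file, e.g. {missing[:5]}"
        )

    keep = [(i, b) for i, b in enumerate(barcodes) if b in pos_index]
    rows = [i for i, _ in keep]
    kept_barcodes = [b for _, b in keep]
    overlay = Overlay(
        name="spots",
        ids=kept_barcodes,
        x=positions.x[[pos_index[b] for b in kept_barcodes]],
        y=positions.y[[pos_index[b] for b in kept_barcodes]],
    )
    overlay_path = os.path.join(out_dir, "spots.csv")
    overlay.to_csv(overlay_path)

    dense = np.asarray(counts[rows].todense(), dtype=np.float64)
    logged = log_transform_counts(dense)
    fg_spec = write_feature_group(
        overlay,
        sparsify(logged, genes),
        os.path.join(out_dir, "genes.bin"),
        name="genes",
    )

    image = _read_tiff_stack(image_path)
    filtered = gaussian_filter_image(image, gaussian_radius)
    img_spec = build_pyramid(
        filtered,
        channels=[f"channel{i}" for i in range(filtered.shape[0])],
        out=os.path.join(out_dir, "image.tif"),
        tile_size=tile_size,
        compression=compression,
        jpeg_quality=quality,
    )

    meta = SampleMeta(
        name=sample_name,
        microns_per_pixel=scale.microns_per_pixel,
        images=(img_spec,),
        overlays=(
            OverlaySpec(
                name="spots",
                path="spots.csv",
                n_points=overlay.n_points,
                geometry="circle",
                diameter_um=VISIUM_SPOT_DIAMETER_UM,
            ),
        ),
        feature_groups=(fg_spec,),
    )
    write_sample_meta(meta, out_dir)
    return out_dir


def convert_merfish(
    cell_by_gene_path,
    cell_metadata_path,
    affine_path,
    out_dir,
    image_path=None,
    sample_name: str = "merfish",
    compression: str = "lossless",
    quality: int = 90,
    tile_size: int = 512,
    microns_per_pixel: float | None = None,
) -> str:
    """Convert Vizgen-style MERFISH tables into a sample folder.

    The overlay is each cell's centroid mapped micron -> mosaic pixel with the
    provided affine; features are the raw per-cell transcript counts.
    """
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)

    cbg = pd.read_csv(cell_by_gene_path)
    id_col = cbg.columns[0]
    genes = [c for c in cbg.columns if c != id_col]
    cbg[id_col] = cbg[id_col].astype(str)

    meta_df = pd.read_csv(cell_metadata_path)
    meta_id = next(
        (c for c in meta_df.columns if c.lower() in ("entityid", "cell", "cell_id")), None
    )
    if meta_id is None:
        raise FormatError(
            f"cell metadata needs an EntityID/cell id column, has {list(meta_df.columns)}"
        )
    for col in ("center_x", "center_y"):
        if col not in meta_df.columns:
            raise FormatError(f"cell metadata lacks required column {col!r}")
    meta_df[meta_id] = meta_df[meta_id].astype(str)

    counts_ids = set(cbg[id_col])
    meta_ids = set(meta_df[meta_id])
    if counts_ids != meta_ids:
        raise ConversionError(
            f"cell id mismatch: {len(counts_ids - meta_ids)} only in counts, "
            f"{len(meta_ids - counts_ids)} only in metadata"
        )

    affine = AffineMatrix.from_csv(affine_path)
    meta_lookup = meta_df.set_index(meta_id)
    ordered = meta_lookup.loc[cbg[id_col]]
    microns = np.column_stack(
        [ordered["center_x"].to_numpy(float), ordered["center_y"].to_numpy(float)]
    )
    pixels = apply_affine(microns, affine)

    overlay = Overlay(name="cells", ids=cbg[id_col].tolist(), x=pixels[:, 0], y=pixels[:, 1])
    overlay.to_csv(os.path.join(out_dir, "cells.csv"))

    counts = cbg[genes].to_numpy(dtype=np.float64)
    fg_spec = write_feature_group(
        overlay, sparsify(counts, genes), os.path.join(out_dir, "genes.bin"), name="genes"
    )

    images = ()
    if image_path is not None:
        img = _read_tiff_stack(image_path)
        images = (
            build_pyramid(
                img,
                channels=[f"channel{i}" for i in range(img.shape[0])],
                out=os.path.join(out_dir, "image.tif"),
                tile_size=tile_size,
                compression=compression,
                jpeg_quality=quality,
            ),
        )

    meta = SampleMeta(
        name=sample_name,
        microns_per_pixel=microns_per_pixel
        if microns_per_pixel is not None
        else _affine_scale(affine),
        images=images,
        overlays=(
            OverlaySpec(
                name="cells",
                path="cells.csv",
                n_points=overlay.n_points,
                geometry="point",
            ),
        ),
        feature_groups=(fg_spec,),
    )
    write_sample_meta(meta, out_dir)
    return out_dir


def _affine_scale(affine: AffineMatrix) -> float:
    """Microns per pixel implied by the micron->pixel affine (mean axis scale)."""
    a = affine.matrix
    sx = float(np.hypot(a[0, 0], a[1, 0]))
    sy = float(np.hypot(a[0, 1], a[1, 1]))
    return 2.0 / (sx + sy)


def preprocess_image(
    tiff_path,
    out_dir,
    channels: list[str] | None = None,
    compression: str = "jpeg",
    quality: int = 90,
    gaussian_radius: float = 0.0,
    tile_size: int = 512,
    sample_name: str | None = None,
    microns_per_pixel: float = 1.0,
) -> str:
    """Pyramidize a bare TIFF into an image-only sample folder."""
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    img = _read_tiff_stack(tiff_path)
    if gaussian_radius:
        img = gaussian_filter_image(img, gaussian_radius)
    if channels is None:
        channels = [f"channel{i}" for i in range(img.shape[0])]
    spec = build_pyramid(
        img,
        channels=channels,
        out=os.path.join(out_dir, "image.tif"),
        tile_size=tile_size,
        compression=compression,
        jpeg_quality=quality,
    )
    if sample_name is None:
        sample_name = os.path.splitext(os.path.basename(os.fspath(tiff_path)))[0]
    meta = SampleMeta(
        name=sample_name, microns_per_pixel=microns_per_pixel, images=(spec,)
    )
    write_sample_meta(meta, out_dir)
    return out_dir
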