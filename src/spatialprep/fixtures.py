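"""Deterministic synthetic inputs for every converter and store in the package.

Generates, from a seed, the exact file dialects the converters consume: a
multi-channel TIFF (smooth blobs plus noise), a Space Ranger-style Visium
folder (hex-lattice spot positions in both CSV dialects, scalefactors JSON,
MatrixMarket counts), and Vizgen MERFISH-style tables (micron centroids,
cell-by-gene counts, micron->mosaic affine).  Each fixture also writes a
plain-text ground-truth table so oracle tests can compare converted output
against known values.  Everything is a pure function of the seed: the same
config regenerates byte-identical files.

These fixtures emulate formats and geometry only — counts are Poisson draws
with log-uniform per-gene rates, with no spatial expression structure.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import tifffile

from .converters import AffineMatrix, apply_affine
from .errors import ValidationError

__all__ = [
    "FixtureConfig",
    "make_synthetic_image",
    "make_visium_fixture",
    "make_merfish_fixture",
]


@dataclass
class FixtureConfig:
    seed: int = 0
    image_size: tuple[int, int] = (2000, 2000)  # (width, height), level-0 px
    n_channels: int = 1
    n_spots: int = 50
    n_cells: int = 100
    n_genes: int = 20
    density: float = 0.05
    spot_diameter_fullres: float = 110.0  # px; 55 um at 0.5 um/px
    affine: AffineMatrix = field(
        default_factory=lambda: AffineMatrix(
            [[9.2, 0.0, 420.0], [0.0, 9.2, 310.0], [0.0, 0.0, 1.0]]
        )
    )

    def __post_init__(self):
        w, h = self.image_size
        if w < 1 or h < 1 or self.n_genes < 1:
            raise ValidationError("fixture sizes must be positive")
        if not 0 < self.density <= 1:
            raise ValidationError(f"density must be in (0, 1], got {self.density}")


def make_synthetic_image(config: FixtureConfig, path) -> str:
    """Write a reproducible multi-channel uint8 TIFF of smooth blobs + noise."""
    rng = np.random.default_rng(config.seed)
    w, h = config.image_size
    yy, xx = np.mgrid[0:h, 0:w]
    channels = []
    for _ in range(config.n_channels):
        img = np.zeros((h, w), dtype=np.float64)
        for _ in range(6):
            cx, cy = rng.uniform(0, w), rng.uniform(0, h)
            sigma = rng.uniform(0.05, 0.25) * max(w, h)
            amp = rng.uniform(60, 160)
            img += amp * np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sigma**2))
        img += rng.normal(0, 8, size=(h, w))
        channels.append(np.clip(img, 0, 255).astype(np.uint8))
    stack = np.stack(channels)
    tifffile.imwrite(path, stack if config.n_channels > 1 else stack[0])
    return os.fspath(path)


def _poisson_counts(rng: np.random.Generator, n_rows: int, config: FixtureConfig) -> np.ndarray:
    """Sparse non-negative integer matrix at roughly the target density."""
    rates = np.exp(rng.uniform(np.log(0.5), np.log(8.0), size=config.n_genes))
    counts = rng.poisson(rates[None, :], size=(n_rows, config.n_genes))
    keep = rng.random(counts.shape) < (
        config.density / max(1e-9, (counts > 0).mean())
    )
    return (counts * keep).astype(np.int64)


def _write_counts_dir(directory: str, counts: np.ndarray, ids: list[str],
                      genes: list[str], gzipped: bool) -> None:
    import gzip as _gzip

    os.makedirs(directory, exist_ok=True)

    def _writer(name: str):
        p = os.path.join(directory, name + (".gz" if gzipped else ""))
        return _gzip.open(p, "wt", newline="\n") if gzipped else open(
            p, "w", encoding="utf-8", newline="\n"
        )

    nz = np.argwhere(counts.T > 0)  # gene-major, matching Space Ranger layout
    with _writer("matrix.mtx") as fh:
        fh.write("%%MatrixMarket matrix coordinate integer general\n")
        fh.write(f"{len(genes)} {len(ids)} {len(nz)}\n")
        for g, b in nz:
            fh.write(f"{g + 1} {b + 1} {counts[b, g]}\n")
    with _writer("barcodes.tsv") as fh:
        for b in ids:
            fh.write(b + "\n")
    with _writer("features.tsv") as fh:
        for j, g in enumerate(genes):
            fh.write(f"ENSG{j:011d}\t{g}\tGene Expression\n")


def make_visium_fixture(
    config: FixtureConfig,
    out_dir,
    positions_dialect: str = "headerless",
    gzip_matrix: bool = False,
    n_out_of_tissue: int = 5,
) -> str:
    """Build a Space Ranger-style directory plus ground-truth counts table.

    Spots sit on a hexagonal lattice inside the image bounds; a handful of
    extra out-of-tissue rows (in_tissue = 0) exercise downstream filtering.
    The dense truth matrix is written as ``truth_counts.csv``.
    """
    rng = np.random.default_rng(config.seed)
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    w, h = config.image_size

    # hex lattice: spacing mimics Visium packing (100 um pitch for 55 um spots)
    pitch = config.spot_diameter_fullres * (100.0 / 55.0)
    margin = config.spot_diameter_fullres
    coords = []
    row = 0
    y = margin
    while y <= h - margin and len(coords) < config.n_spots + n_out_of_tissue:
        x = margin + (pitch / 2 if row % 2 else 0)
        col = 0
        while x <= w - margin and len(coords) < config.n_spots + n_out_of_tissue:
            coords.append((row, col, x, y))
            x += pitch
            col += 2
        y += pitch * np.sqrt(3) / 2
        row += 1
    if len(coords) < config.n_spots + n_out_of_tissue:
        raise ValidationError(
            f"hex lattice overflow: only {len(coords)} spots fit in a "
            f"{w}x{h} image at pitch {pitch:.1f}; shrink n_spots or the spot diameter"
        )
    order = rng.permutation(len(coords))
    in_tissue_idx = set(order[: config.n_spots].tolist())

    barcodes_all = [f"BC{i:06d}-1" for i in range(len(coords))]
    lines = []
    for i, (arow, acol, x, y) in enumerate(coords):
        flag = 1 if i in in_tissue_idx else 0
        # positions file stores pixel row then pixel column
        lines.append(
            f"{barcodes_all[i]},{flag},{arow},{acol},{float(y)!r},{float(x)!r}"
        )
    pos_name = (
        "tissue_positions_list.csv"
        if positions_dialect == "headerless"
        else "tissue_positions.csv"
    )
    with open(os.path.join(out_dir, pos_name), "w", newline="\n") as fh:
        if positions_dialect == "headered":
            fh.write(
                "barcode,in_tissue,array_row,array_col,"
                "pxl_row_in_fullres,pxl_col_in_fullres\n"
            )
        fh.write("\n".join(lines) + "\n")

    with open(os.path.join(out_dir, "scalefactors_json.json"), "w", newline="\n") as fh:
        fh.write(
            '{"spot_diameter_fullres": %r, "tissue_hires_scalef": 0.15}\n'
            % config.spot_diameter_fullres
        )

    tissue_barcodes = [barcodes_all[i] for i in sorted(in_tissue_idx)]
    genes = [f"Gene{j:03d}" for j in range(config.n_genes)]
    counts = _poisson_counts(rng, len(tissue_barcodes), config)
    _write_counts_dir(
        os.path.join(out_dir, "filtered_feature_bc_matrix"),
        counts,
        tissue_barcodes,
        genes,
        gzipped=gzip_matrix,
    )

    with open(os.path.join(out_dir, "truth_counts.csv"), "w", newline="\n") as fh:
        fh.write("barcode," + ",".join(genes) + "\n")
        for b, rowvals in zip(tissue_barcodes, counts):
            fh.write(b + "," + ",".join(str(int(v)) for v in rowvals) + "\n")

    make_synthetic_image(config, os.path.join(out_dir, "image.tif"))
    return out_dir


def make_merfish_fixture(config: FixtureConfig, out_dir) -> str:
    """Build Vizgen-style tables plus the ground-truth pixel centroids.

    Micron-space centroids are drawn uniformly; ``truth_pixels.csv`` holds
    ``apply_affine(centroids)`` so converter output can be checked exactly.
    """
    rng = np.random.default_rng(config.seed)
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)

    n = config.n_cells
    ids = [str(100000 + i) for i in range(n)]
    microns = np.column_stack(
        [rng.uniform(0, 800, size=n), rng.uniform(0, 600, size=n)]
    )
    pixels = apply_affine(microns, config.affine)
    genes = [f"Blank-{j}" if j < 2 else f"Gene{j:03d}" for j in range(config.n_genes)]
    counts = _poisson_counts(rng, n, config)

    with open(os.path.join(out_dir, "cell_by_gene.csv"), "w", newline="\n") as fh:
        fh.write("cell," + ",".join(genes) + "\n")
        for cid, rowvals in zip(ids, counts):
            fh.write(cid + "," + ",".join(str(int(v)) for v in rowvals) + "\n")

    with open(os.path.join(out_dir, "cell_metadata.csv"), "w", newline="\n") as fh:
        fh.write("EntityID,fov,center_x,center_y\n")
        for cid, (mx, my) in zip(ids, microns):
            fh.write(f"{cid},0,{float(mx)!r},{float(my)!r}\n")

    with open(
        os.path.join(out_dir, "micron_to_mosaic_pixel_transform.csv"), "w", newline="\n"
    ) as fh:
        for mrow in config.affine.matrix:
            fh.write(",".join(repr(float(v)) for v in mrow) + "\n")

    with open(os.path.join(out_dir, "truth_pixels.csv"), "w", newline="\n") as fh:
        fh.write("cell,x,y\n")
        for cid, (px, py) in zip(ids, pixels):
            fh.write(f"{cid},{float(px)!r},{float(py)!r}\n")

    make_synthetic_image(config, os.path.join(out_dir, "image.tif"))
    return out_dir
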