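"""Multi-resolution tiled image pyramids with lazy byte-range reads.

A pyramid stores an image at level 0 (full resolution) plus overviews, each
level halving the previous one (ceiling division), down to the first level
that fits in a single tile.  Tiles are independently compressed and all byte
offsets live in a header region at the start of the file, so a viewer that
holds a :class:`~spatialprep.rangeio.RangeReader` can fetch exactly the tiles
intersecting its viewport and nothing else.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter as _nd_gaussian

from . import tiffio
from .errors import FormatError, ValidationError
from .rangeio import FileRangeReader, RangeReader
from .schema import ImageSpec

__all__ = [
    "LevelPlan",
    "plan_levels",
    "downsample_level",
    "gaussian_filter_image",
    "build_pyramid",
    "plan_viewport",
    "PyramidReader",
]


@dataclass(frozen=True)
class LevelPlan:
    """Per-level (width, height) pairs; index 0 is full resolution."""

    levels: tuple[tuple[int, int], ...]

    @property
    def n_levels(self) -> int:
        return len(self.levels)


def plan_levels(width: int, height: int, tile_size: int) -> LevelPlan:
    """Halve (ceiling) until the largest dimension fits in one tile."""
    if width < 1 or height < 1:
        raise ValueError(f"image dimensions must be positive, got {width}x{height}")
    if tile_size < 16:
        raise ValueError(f"tile_size must be >= 16, got {tile_size}")
    dims = [(width, height)]
    while max(dims[-1]) > tile_size:
        w, h = dims[-1]
        dims.append((-(-w // 2), -(-h // 2)))
    return LevelPlan(levels=tuple(dims))


def downsample_level(parent: np.ndarray) -> np.ndarray:
    """2x2 block mean with ceiling-half output dims.

    Edge blocks average only the pixels that exist; integer dtypes are
    rounded half-up.
    """
    if parent.size == 0:
        raise ValueError("cannot downsample an empty array")
    h, w = parent.shape
    oh, ow = -(-h // 2), -(-w // 2)
    acc = np.zeros((oh, ow), dtype=np.float64)
    cnt = np.zeros((oh, ow), dtype=np.int64)
    for dy in (0, 1):
        for dx in (0, 1):
            blk = parent[dy::2, dx::2]
            acc[: blk.shape[0], : blk.shape[1]] += blk
            cnt[: blk.shape[0], : blk.shape[1]] += 1
    mean = acc / cnt
    if np.issubdtype(parent.dtype, np.integer):
        return np.floor(mean + 0.5).astype(parent.dtype)
    return mean.astype(parent.dtype)


def gaussian_filter_image(image: np.ndarray, radius: float) -> np.ndarray:
    """Per-channel Gaussian blur; ``radius`` is the standard deviation in px.

    The kernel is truncated at 4 standard deviations with reflect boundary;
    radius 0 returns the input unchanged.
    """
    if radius < 0:
        raise ValueError(f"radius must be non-negative, got {radius}")
    if radius == 0:
        return image.copy()
    img = np.asarray(image)
    squeeze = img.ndim == 2
    if squeeze:
        img = img[None]
    out = np.empty_like(img)
    for ch in range(img.shape[0]):
        blurred = _nd_gaussian(
            img[ch].astype(np.float64), sigma=radius, truncate=4.0, mode="reflect"
        )
        if np.issubdtype(img.dtype, np.integer):
            info = np.iinfo(img.dtype)
            out[ch] = np.clip(np.floor(blurred + 0.5), info.min, info.max).astype(img.dtype)
        else:
            out[ch] = blurred.astype(img.dtype)
    return out[0] if squeeze else out


def build_pyramid(
    image: np.ndarray,
    channels: list[str],
    out,
    tile_size: int = 512,
    compression: str = "lossless",
    jpeg_quality: int = 90,
) -> ImageSpec:
    """Write ``image`` (channels x height x width) as a tiled pyramid at ``out``.

    Lossless mode (deflate tiles) reconstructs level 0 exactly; JPEG mode is
    lossy and limited to uint8.  Returns the manifest entry describing the
    file.
    """
    img = np.asarray(image)
    if img.ndim == 2:
        img = img[None]
    if img.ndim != 3 or img.size == 0:
        raise ValueError(f"expected a non-empty channels x H x W array, got shape {image.shape}")
    if img.shape[0] != len(channels):
        raise ValueError(
            f"{img.shape[0]} image channels but {len(channels)} channel names"
        )
    if img.dtype not in (np.dtype("uint8"), np.dtype("uint16")):
        raise ValueError(f"unsupported dtype {img.dtype}; use uint8 or uint16")
    if compression not in ("lossless", "jpeg"):
        raise ValueError(f"compression must be 'lossless' or 'jpeg', got {compression!r}")
    if compression == "jpeg":
        if img.dtype != np.dtype("uint8"):
            raise ValueError("JPEG compression supports uint8 images only")
        if not 1 <= jpeg_quality <= 100:
            raise ValueError(f"jpeg_quality must be in 1..100, got {jpeg_quality}")
    if tile_size % 16 != 0:
        raise ValueError(f"tile_size must be a multiple of 16, got {tile_size}")

    n_ch, h, w = img.shape
    plan = plan_levels(w, h, tile_size)
    levels = [img]
    for _ in plan.levels[1:]:
        prev = levels[-1]
        levels.append(np.stack([downsample_level(prev[c]) for c in range(n_ch)]))

    description = {
        "channels": list(channels),
        "compression": compression,
        "tile_size": tile_size,
        "n_levels": plan.n_levels,
    }
    if compression == "jpeg":
        description["jpeg_quality"] = jpeg_quality
    tiffio.write_tiled_tiff(
        out,
        levels,
        tile_size=tile_size,
        compression=compression,
        jpeg_quality=jpeg_quality if compression == "jpeg" else None,
        description=description,
    )
    import os

    return ImageSpec(
        path=os.path.basename(str(out)),
        channels=list(channels),
        width=w,
        height=h,
        tile_size=tile_size,
        n_levels=plan.n_levels,
        compression=compression,
        jpeg_quality=jpeg_quality if compression == "jpeg" else None,
    )


def plan_viewport(
    viewport: tuple[float, float, float, float],
    level: int,
    plan: LevelPlan,
    tile_size: int,
) -> list[tuple[int, int]]:
    """Tiles at ``level`` whose level-0 pixel footprint intersects the viewport.

    ``viewport`` is (x, y, width, height) in level-0 pixels (half-open).
    Returned (row, col) pairs are unique and row-major ordered.
    """
    if level < 0 or level >= plan.n_levels:
        raise IndexError(f"level {level} out of range (pyramid has {plan.n_levels})")
    x, y, vw, vh = viewport
    if vw <= 0 or vh <= 0:
        return []
    lw, lh = plan.levels[level]
    f = 2**level
    rows = -(-lh // tile_size)
    cols = -(-lw // tile_size)
    out = []
    for r in range(rows):
        # tile footprint in level-0 coords, clipped to the image
        ty0 = r * tile_size * f
        ty1 = min((r + 1) * tile_size, lh) * f
        if ty1 <= y or ty0 >= y + vh:
            continue
        for c in range(cols):
            tx0 = c * tile_size * f
            tx1 = min((c + 1) * tile_size, lw) * f
            if tx1 <= x or tx0 >= x + vw:
                continue
            out.append((r, c))
    return out


class PyramidReader:
    """Reads tiles and regions from a pyramid file through a RangeReader.

    Opening parses the header region only; every subsequent read fetches
    exactly the byte ranges of the tiles it needs.
    """

    def __init__(self, reader: RangeReader):
        self.reader = reader
        self.header = tiffio.parse_tiff_header(reader)
        self.tile_size = self.header.tile_size
        self.n_channels = self.header.n_channels
        self.channels = self.header.description.get(
            "channels", [f"channel{i}" for i in range(self.n_channels)]
        )
        self.plan = LevelPlan(
            levels=tuple((l.width, l.height) for l in self.header.levels)
        )

    @classmethod
    def open(cls, source) -> "PyramidReader":
        """Open from a path or any RangeReader."""
        if isinstance(source, (str, bytes)) or hasattr(source, "__fspath__"):
            source = FileRangeReader(source)
        return cls(source)

    @property
    def header_bytes(self) -> int:
        return self.header.header_bytes

    @property
    def n_levels(self) -> int:
        return len(self.header.levels)

    def level_shape(self, level: int) -> tuple[int, int]:
        l = self.header.levels[level]
        return (l.height, l.width)

    def read_tile(self, level: int, row: int, col: int) -> np.ndarray:
        """Decode one padded tile as a (channels, tile, tile) array."""
        try:
            lvl = self.header.levels[level]
        except IndexError:
            raise IndexError(f"level {level} out of range") from None
        if not (0 <= row < lvl.rows and 0 <= col < lvl.cols):
            raise IndexError(
                f"tile ({row}, {col}) outside the {lvl.rows}x{lvl.cols} grid of level {level}"
            )
        planes = []
        for ch in range(self.n_channels):
            off = int(lvl.offsets[ch, row, col])
            length = int(lvl.lengths[ch, row, col])
            data = self.reader.read(off, length)
            planes.append(
                tiffio._decode_tile(
                    data, self.header.compression, self.tile_size, self.header.dtype
                )
            )
        return np.stack(planes)

    def read_level(self, level: int) -> np.ndarray:
        """Decode a whole level as (channels, height, width)."""
        h, w = self.level_shape(level)
        region, _ = self.read_region((0, 0, w * 2**level, h * 2**level), level)
        return region

    def read_region(
        self, viewport: tuple[float, float, float, float], level: int
    ) -> tuple[np.ndarray, int]:
        """Stitch the viewport's pixels at ``level``.

        Returns (region, bytes_fetched) where bytes_fetched counts only the
        ranges pulled through the reader by this call.
        """
        start_bytes = self.reader.total_bytes_fetched
        tiles = plan_viewport(viewport, level, self.plan, self.tile_size)
        lvl = self.header.levels[level]
        f = 2**level
        x, y, vw, vh = viewport
        # viewport in this level's pixel coords, clipped
        x0 = max(0, int(np.floor(x / f)))
        y0 = max(0, int(np.floor(y / f)))
        x1 = min(lvl.width, int(np.ceil((x + vw) / f)))
        y1 = min(lvl.height, int(np.ceil((y + vh) / f)))
        if x1 <= x0 or y1 <= y0:
            return (
                np.zeros((self.n_channels, 0, 0), dtype=self.header.dtype),
                0,
            )
        region = np.zeros((self.n_channels, y1 - y0, x1 - x0), dtype=self.header.dtype)
        ts = self.tile_size
        for r, c in tiles:
            tile = self.read_tile(level, r, c)
            ty0, tx0 = r * ts, c * ts
            sy0 = max(y0, ty0)
            sx0 = max(x0, tx0)
            sy1 = min(y1, min(ty0 + ts, lvl.height))
            sx1 = min(x1, min(tx0 + ts, lvl.width))
            if sy1 <= sy0 or sx1 <= sx0:
                continue
            region[:, sy0 - y0 : sy1 - y0, sx0 - x0 : sx1 - x0] = tile[
                :, sy0 - ty0 : sy1 - ty0, sx0 - tx0 : sx1 - tx0
            ]
        return region, self.reader.total_bytes_fetched - start_bytes

    def validate_index(self) -> list[str]:
        """Sanity findings about the tile byte index (empty = healthy)."""
        findings: list[str] = []
        size = self.reader.size()
        spans = []
        for li, lvl in enumerate(self.header.levels):
            for off, length in zip(lvl.offsets.ravel(), lvl.lengths.ravel()):
                if off + length > size:
                    findings.append(
                        f"level {li}: tile range [{off}, {off + length}) exceeds file size {size}"
                    )
                spans.append((int(off), int(length)))
        spans.sort()
        for (o1, l1), (o2, _) in zip(spans, spans[1:]):
            if o1 + l1 > o2:
                findings.append(f"overlapping tile ranges at offset {o2}")
        return findings
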