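"""Minimal tiled-TIFF writer and header parser with a cloud-optimized layout.

The files written here are classic little-endian TIFFs: one page per pyramid
level (reduced-resolution pages flagged via NewSubfileType), tiled, with
deflate- or JPEG-compressed tiles and, for multi-channel images, one planar
sample per channel.  The defining layout property is that *all* IFDs and
out-of-line tag values (including every TileOffsets/TileByteCounts array) are
serialized in one contiguous segment at the start of the file, before any
tile data.  A reader can therefore discover every tile's byte range from a
single initial range read — the property that makes byte-range lazy loading
work.

Only the subset of TIFF needed for these pyramids is implemented; anything
else is rejected loudly.  Standard readers (e.g. tifffile) decode the output.
"""

from __future__ import annotations

import io
import json
import struct
import zlib
from dataclasses import dataclass, field

import numpy as np

from .errors import FormatError
from .rangeio import RangeReader

# TIFF tag codes
NEW_SUBFILE_TYPE = 254
IMAGE_WIDTH = 256
IMAGE_LENGTH = 257
BITS_PER_SAMPLE = 258
COMPRESSION = 259
PHOTOMETRIC = 262
IMAGE_DESCRIPTION = 270
SAMPLES_PER_PIXEL = 277
PLANAR_CONFIG = 284
TILE_WIDTH = 322
TILE_LENGTH = 323
TILE_OFFSETS = 324
TILE_BYTE_COUNTS = 325
SAMPLE_FORMAT = 339

TYPE_ASCII = 2
TYPE_SHORT = 3
TYPE_LONG = 4
_TYPE_SIZE = {TYPE_ASCII: 1, TYPE_SHORT: 2, TYPE_LONG: 4}

COMPRESSION_DEFLATE = 8  # Adobe deflate (zlib stream)
COMPRESSION_JPEG = 7  # new-style JPEG, one complete stream per tile


def _encode_tile(tile: np.ndarray, compression: int, jpeg_quality: int) -> bytes:
    if compression == COMPRESSION_DEFLATE:
        return zlib.compress(tile.tobytes(), 6)
    if compression == COMPRESSION_JPEG:
        from PIL import Image

        buf = io.BytesIO()
        Image.fromarray(tile, mode="L").save(buf, format="JPEG", quality=jpeg_quality)
        return buf.getvalue()
    raise FormatError(f"unsupported compression code {compression}")


def _decode_tile(
    data: bytes, compression: int, tile_size: int, dtype: np.dtype
) -> np.ndarray:
    if compression == COMPRESSION_DEFLATE:
        raw = zlib.decompress(data)
        arr = np.frombuffer(raw, dtype=dtype)
        if arr.size != tile_size * tile_size:
            raise FormatError(
                f"tile decompressed to {arr.size} px, expected {tile_size * tile_size}"
            )
        return arr.reshape(tile_size, tile_size).copy()
    if compression == COMPRESSION_JPEG:
        from PIL import Image

        arr = np.asarray(Image.open(io.BytesIO(data)))
        if arr.shape != (tile_size, tile_size):
            raise FormatError(f"JPEG tile has shape {arr.shape}")
        return arr.astype(dtype)
    raise FormatError(f"unsupported compression code {compression}")


@dataclass
class _Entry:
    tag: int
    dtype: int
    values: list  # ints, or a bytes payload for ASCII

    def payload(self, byteorder: str = "<") -> bytes:
        if self.dtype == TYPE_ASCII:
            return self.values  # already bytes, NUL-terminated
        fmt = {TYPE_SHORT: "H", TYPE_LONG: "I"}[self.dtype]
        return struct.pack(f"{byteorder}{len(self.values)}{fmt}", *self.values)

    @property
    def count(self) -> int:
        return len(self.values)

    @property
    def nbytes(self) -> int:
        return self.count * _TYPE_SIZE[self.dtype]


def _pad_tile(plane: np.ndarray, r: int, c: int, ts: int) -> np.ndarray:
    h, w = plane.shape
    block = plane[r * ts : min((r + 1) * ts, h), c * ts : min((c + 1) * ts, w)]
    if block.shape == (ts, ts):
        return block
    out = np.zeros((ts, ts), dtype=plane.dtype)
    out[: block.shape[0], : block.shape[1]] = block
    return out


def write_tiled_tiff(
    path,
    levels: list[np.ndarray],
    tile_size: int,
    compression: str,
    jpeg_quality: int | None,
    description: dict,
) -> int:
    """Write ``levels`` (each channels x H x W) as one tiled TIFF.

    Returns the size in bytes of the header region (everything before the
    first tile byte).
    """
    comp_code = COMPRESSION_DEFLATE if compression == "lossless" else COMPRESSION_JPEG
    n_channels = levels[0].shape[0]
    dtype = levels[0].dtype
    bits = dtype.itemsize * 8
    planar = 2 if n_channels > 1 else 1

    # Compress everything up front so every byte offset is known before writing.
    tile_bytes: list[list[bytes]] = []  # per level, flat plane-major row-major
    for lvl in levels:
        rows = -(-lvl.shape[1] // tile_size)
        cols = -(-lvl.shape[2] // tile_size)
        blobs = []
        for ch in range(n_channels):
            for r in range(rows):
                for c in range(cols):
                    blobs.append(
                        _encode_tile(
                            _pad_tile(lvl[ch], r, c, tile_size),
                            comp_code,
                            jpeg_quality or 90,
                        )
                    )
        tile_bytes.append(blobs)

    desc = (json.dumps(description, sort_keys=True) + "\x00").encode("ascii")

    # Build IFD entry lists with tile offsets still unknown.
    ifds: list[list[_Entry]] = []
    for li, lvl in enumerate(levels):
        _, h, w = lvl.shape
        n_tiles = len(tile_bytes[li])
        entries = [
            _Entry(NEW_SUBFILE_TYPE, TYPE_LONG, [0 if li == 0 else 1]),
            _Entry(IMAGE_WIDTH, TYPE_LONG, [w]),
            _Entry(IMAGE_LENGTH, TYPE_LONG, [h]),
            _Entry(BITS_PER_SAMPLE, TYPE_SHORT, [bits] * n_channels),
            _Entry(COMPRESSION, TYPE_SHORT, [comp_code]),
            _Entry(PHOTOMETRIC, TYPE_SHORT, [1]),
        ]
        if li == 0:
            entries.append(_Entry(IMAGE_DESCRIPTION, TYPE_ASCII, desc))
        entries += [
            _Entry(SAMPLES_PER_PIXEL, TYPE_SHORT, [n_channels]),
            _Entry(PLANAR_CONFIG, TYPE_SHORT, [planar]),
            _Entry(TILE_WIDTH, TYPE_LONG, [tile_size]),
            _Entry(TILE_LENGTH, TYPE_LONG, [tile_size]),
            _Entry(TILE_OFFSETS, TYPE_LONG, [0] * n_tiles),
            _Entry(TILE_BYTE_COUNTS, TYPE_LONG, [len(b) for b in tile_bytes[li]]),
            _Entry(SAMPLE_FORMAT, TYPE_SHORT, [1] * n_channels),
        ]
        ifds.append(entries)

    # Lay out: 8-byte header, IFD structures, out-of-line values, tile data.
    def _align(n: int) -> int:
        return n + (n & 1)

    pos = 8
    ifd_offsets = []
    for entries in ifds:
        ifd_offsets.append(pos)
        pos += 2 + 12 * len(entries) + 4
    # out-of-line tag values
    extern_offsets: dict[int, int] = {}  # id(entry) -> offset
    for entries in ifds:
        for e in entries:
            if e.nbytes > 4:
                pos = _align(pos)
                extern_offsets[id(e)] = pos
                pos += e.nbytes
    header_size = _align(pos)

    # tile data offsets
    pos = header_size
    for li, blobs in enumerate(tile_bytes):
        offs = []
        for b in blobs:
            offs.append(pos)
            pos = _align(pos + len(b))
        next(e for e in ifds[li] if e.tag == TILE_OFFSETS).values = offs

    # Serialize.
    out = bytearray()
    out += struct.pack("<2sHI", b"II", 42, ifd_offsets[0])
    for li, entries in enumerate(ifds):
        entries = sorted(entries, key=lambda e: e.tag)
        out += struct.pack("<H", len(entries))
        for e in entries:
            if e.nbytes > 4:
                val = struct.pack("<I", extern_offsets[id(e)])
            else:
                val = e.payload().ljust(4, b"\x00")
            out += struct.pack("<HHI", e.tag, e.dtype, e.count) + val
        nxt = ifd_offsets[li + 1] if li + 1 < len(ifds) else 0
        out += struct.pack("<I", nxt)
    for entries in ifds:
        for e in entries:
            if e.nbytes > 4:
                off = extern_offsets[id(e)]
                out += b"\x00" * (off - len(out))
                out += e.payload()
    out += b"\x00" * (header_size - len(out))
    for blobs in tile_bytes:
        for b in blobs:
            out += b
            if len(out) & 1:
                out += b"\x00"

    with open(path, "wb") as fh:
        fh.write(bytes(out))
    return header_size


@dataclass
class LevelIndex:
    """Tile grid and byte ranges for one pyramid level."""

    width: int
    height: int
    rows: int
    cols: int
    # shape (n_channels, rows, cols)
    offsets: np.ndarray = field(repr=False)
    lengths: np.ndarray = field(repr=False)


@dataclass
class TiffHeader:
    tile_size: int
    compression: int
    n_channels: int
    dtype: np.dtype
    levels: list[LevelIndex]
    description: dict
    header_bytes: int  # bytes fetched to parse the header region


class _PrefixBuffer:
    """Grows a contiguous prefix of the file through a RangeReader."""

    def __init__(self, reader: RangeReader, initial: int = 16384):
        self.reader = reader
        self.buf = reader.read(0, min(initial, reader.size()))

    def ensure(self, end: int) -> None:
        if end > self.reader.size():
            raise FormatError("TIFF header parse ran past end of file")
        while len(self.buf) < end:
            want = min(max(len(self.buf), 4096), self.reader.size() - len(self.buf))
            self.buf += self.reader.read(len(self.buf), want)

    def unpack(self, fmt: str, offset: int):
        size = struct.calcsize(fmt)
        self.ensure(offset + size)
        return struct.unpack_from(fmt, self.buf, offset)


def parse_tiff_header(reader: RangeReader) -> TiffHeader:
    """Parse the front-loaded header region of a pyramid TIFF.

    Fetches only a prefix of the file; the returned ``header_bytes`` is the
    number of bytes that were read to build the full tile index.
    """
    pb = _PrefixBuffer(reader)
    magic, forty_two, ifd_off = pb.unpack("<2sHI", 0)
    if magic != b"II" or forty_two != 42:
        raise FormatError("not a little-endian classic TIFF")

    levels: list[LevelIndex] = []
    description: dict = {}
    tile_size = compression = n_channels = None
    dtype = None
    while ifd_off:
        (n_entries,) = pb.unpack("<H", ifd_off)
        tags: dict[int, tuple[int, int, bytes]] = {}
        for i in range(n_entries):
            tag, typ, count, raw = pb.unpack("<HHI4s", ifd_off + 2 + 12 * i)
            size = count * _TYPE_SIZE.get(typ, 0)
            if size == 0:
                continue  # unknown value type; skip tag
            if size <= 4:
                payload = raw[:size]
            else:
                (off,) = struct.unpack("<I", raw)
                pb.ensure(off + size)
                payload = pb.buf[off : off + size]
            tags[tag] = (typ, count, payload)

        def _ints(tag: int, default=None) -> list[int]:
            if tag not in tags:
                if default is None:
                    raise FormatError(f"required TIFF tag {tag} missing")
                return default
            typ, count, payload = tags[tag]
            fmt = {TYPE_SHORT: "H", TYPE_LONG: "I"}[typ]
            return list(struct.unpack(f"<{count}{fmt}", payload))

        w = _ints(IMAGE_WIDTH)[0]
        h = _ints(IMAGE_LENGTH)[0]
        ts = _ints(TILE_WIDTH)[0]
        if _ints(TILE_LENGTH)[0] != ts:
            raise FormatError("non-square tiles are not supported")
        comp = _ints(COMPRESSION)[0]
        spp = _ints(SAMPLES_PER_PIXEL, [1])[0]
        planar = _ints(PLANAR_CONFIG, [1])[0]
        bits = _ints(BITS_PER_SAMPLE, [8])[0]
        offsets = np.asarray(_ints(TILE_OFFSETS), dtype=np.int64)
        lengths = np.asarray(_ints(TILE_BYTE_COUNTS), dtype=np.int64)
        if spp > 1 and planar != 2:
            raise FormatError("multi-channel pyramids must use planar configuration 2")
        rows = -(-h // ts)
        cols = -(-w // ts)
        if offsets.size != rows * cols * spp:
            raise FormatError(
                f"tile count mismatch: {offsets.size} offsets for a "
                f"{spp}x{rows}x{cols} grid"
            )
        if IMAGE_DESCRIPTION in tags and not description:
            text = tags[IMAGE_DESCRIPTION][2].rstrip(b"\x00").decode("ascii")
            try:
                description = json.loads(text)
            except json.JSONDecodeError:
                description = {}
        lvl_dtype = np.dtype("uint8") if bits == 8 else np.dtype("<u2")
        if tile_size is None:
            tile_size, compression, n_channels, dtype = ts, comp, spp, lvl_dtype
        elif (ts, comp, spp, lvl_dtype) != (tile_size, compression, n_channels, dtype):
            raise FormatError("pyramid levels disagree on tile/compression layout")
        levels.append(
            LevelIndex(
                width=w,
                height=h,
                rows=rows,
                cols=cols,
                offsets=offsets.reshape(spp, rows, cols),
                lengths=lengths.reshape(spp, rows, cols),
            )
        )
        (ifd_off,) = pb.unpack("<I", ifd_off + 2 + 12 * n_entries)

    if not levels:
        raise FormatError("TIFF contains no pages")
    # byte ranges must be sane
    flat = sorted(
        zip(
            np.concatenate([l.offsets.ravel() for l in levels]).tolist(),
            np.concatenate([l.lengths.ravel() for l in levels]).tolist(),
        )
    )
    prev_end = 0
    for off, length in flat:
        if off < prev_end:
            raise FormatError("overlapping tile byte ranges")
        if off + length > reader.size():
            raise FormatError("tile byte range extends past end of file")
        prev_end = off + length
    return TiffHeader(
        tile_size=tile_size,
        compression=compression,
        n_channels=n_channels,
        dtype=dtype,
        levels=levels,
        description=description,
        header_bytes=len(pb.buf),
    )
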