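"""Byte-range readers.

A :class:`RangeReader` retrieves an arbitrary byte span of a resource and
keeps a running count of bytes fetched.  It is the access contract that makes
lazy loading testable: the pyramid and feature-store readers fetch everything
through one of these, so tests can assert exactly how many bytes an operation
cost.  Implementations: a local seek+read reader, an HTTP byte-range client
with identical semantics, and a caching wrapper that never re-fetches a span
it has already seen.
"""

from __future__ import annotations

import io
import urllib.request
from typing import Protocol, runtime_checkable

__all__ = [
    "RangeReader",
    "FileRangeReader",
    "BytesRangeReader",
    "HTTPRangeReader",
    "CachingRangeReader",
]


@runtime_checkable
class RangeReader(Protocol):
    """Contract: ``read(offset, length)`` returns exactly ``length`` bytes
    (when in bounds) and ``total_bytes_fetched`` grows by ``length``."""

    total_bytes_fetched: int

    def read(self, offset: int, length: int) -> bytes: ...

    def size(self) -> int: ...


def _check_args(offset: int, length: int) -> None:
    if offset < 0 or length < 0:
        raise ValueError(f"offset and length must be non-negative, got ({offset}, {length})")


class FileRangeReader:
    """Seek+read over a local file."""

    def __init__(self, path):
        self._fh = open(path, "rb")
        self._fh.seek(0, io.SEEK_END)
        self._size = self._fh.tell()
        self.total_bytes_fetched = 0

    def size(self) -> int:
        return self._size

    def read(self, offset: int, length: int) -> bytes:
        _check_args(offset, length)
        if offset + length > self._size:
            raise ValueError(
                f"range [{offset}, {offset + length}) beyond end of file ({self._size} bytes)"
            )
        self._fh.seek(offset)
        data = self._fh.read(length)
        self.total_bytes_fetched += len(data)
        return data

    def close(self) -> None:
        self._fh.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()


class BytesRangeReader:
    """Range reader over an in-memory buffer (testing convenience)."""

    def __init__(self, data: bytes):
        self._data = data
        self.total_bytes_fetched = 0

    def size(self) -> int:
        return len(self._data)

    def read(self, offset: int, length: int) -> bytes:
        _check_args(offset, length)
        if offset + length > len(self._data):
            raise ValueError(f"range [{offset}, {offset + length}) beyond buffer end")
        self.total_bytes_fetched += length
        return self._data[offset : offset + length]


class HTTPRangeReader:
    """HTTP byte-range client with the same semantics as ``FileRangeReader``.

    Issues ``Range: bytes=start-end`` GET requests; the server must support
    partial content (status 206).
    """

    def __init__(self, url: str):
        self.url = url
        self.total_bytes_fetched = 0
        req = urllib.request.Request(url, method="HEAD")
        with urllib.request.urlopen(req) as resp:
            self._size = int(resp.headers["Content-Length"])

    def size(self) -> int:
        return self._size

    def read(self, offset: int, length: int) -> bytes:
        _check_args(offset, length)
        if length == 0:
            return b""
        if offset + length > self._size:
            raise ValueError(f"range [{offset}, {offset + length}) beyond resource end")
        req = urllib.request.Request(
            self.url, headers={"Range": f"bytes={offset}-{offset + length - 1}"}
        )
        with urllib.request.urlopen(req) as resp:
            data = resp.read()
        if len(data) != length:
            raise IOError(f"server returned {len(data)} bytes for a {length}-byte range")
        self.total_bytes_fetched += length
        return data


class CachingRangeReader:
    """Wraps another reader; an exact repeat of a span fetches 0 new bytes.

    ``total_bytes_fetched`` mirrors the wrapped reader's counter, so cache
    hits are free by construction.
    """

    def __init__(self, inner: RangeReader):
        self.inner = inner
        self._cache: dict[tuple[int, int], bytes] = {}

    @property
    def total_bytes_fetched(self) -> int:
        return self.inner.total_bytes_fetched

    def size(self) -> int:
        return self.inner.size()

    def read(self, offset: int, length: int) -> bytes:
        key = (offset, length)
        hit = self._cache.get(key)
        if hit is None:
            hit = self.inner.read(offset, length)
            self._cache[key] = hit
        return hit
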