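"""Deterministic JSON serialization helpers.

Manifests and index files are written with sorted keys, no trailing
whitespace, and shortest-repr floats so that writing the same object twice
produces byte-identical files.
"""

from __future__ import annotations

import json
import math
from typing import Any


def _clean(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {str(k): _clean(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_clean(v) for v in obj]
    if isinstance(obj, float):
        if not math.isfinite(obj):
            raise ValueError(f"non-finite float in JSON payload: {obj!r}")
        # repr round-trips exactly; integral floats stay floats
        return obj
    if hasattr(obj, "item") and not isinstance(obj, (str, bytes)):
        # numpy scalar
        return _clean(obj.item())
    return obj


def dumps_stable(obj: Any) -> str:
    """Serialize ``obj`` deterministically (sorted keys, compact separators)."""
    return json.dumps(_clean(obj), sort_keys=True, separators=(",", ":"), allow_nan=False)


def dump_stable(obj: Any, path) -> None:
    text = dumps_stable(obj) + "\n"
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(text)
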