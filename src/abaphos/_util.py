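"""Small shared helpers: reporting-grade rounding, hashing, deterministic JSON."""

from __future__ import annotations

import hashlib
import json
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round with ties going away from zero (0.5 -> 1, -0.5 -> -1).

    Reported percentages use this convention rather than banker's rounding.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def percent(count: float, total: float, ndigits: int = 1) -> float:
    if total <= 0:
        raise ValueError("total must be positive")
    return round_half_away(100.0 * count / total, ndigits)


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def dump_json(obj, path: str | Path) -> None:
    """Write JSON deterministically (sorted keys, fixed separators, trailing newline)."""
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
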