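"""Small numeric helpers used across modules."""

from __future__ import annotations

import math
from collections.abc import Iterable

import numpy as np


def round_sig(x: float, sig: int = 3) -> float:
    """Round ``x`` to ``sig`` significant figures (report convention)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


def geometric_mean(values: Iterable[float]) -> float:
    """Geometric mean computed in natural-log space.

    The result is independent of the log base; inputs must be positive.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("geometric mean of empty collection")
    if np.any(arr <= 0):
        raise ValueError("geometric mean requires positive values")
    return float(np.exp(np.mean(np.log(arr))))


def normalize_species(name: str) -> str:
    """Canonical species key: case-insensitive, whitespace-collapsed."""
    return " ".join(name.split()).lower()
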