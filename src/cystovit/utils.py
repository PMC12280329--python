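"""Shared utilities: seeded substreams and half-up rounding."""

from __future__ import annotations

import hashlib
from decimal import Decimal, ROUND_HALF_UP

import numpy as np

__all__ = ["substream", "round_half_up", "percent"]


def substream(seed: int, name: str) -> np.random.Generator:
    """Named random substream derived from one run seed.

    Every source of randomness in the package (phantoms, splitting, weight
    init, shuffling, bootstrap) pulls from ``substream(seed, <name>)`` so a
    single integer reproduces an entire run while the streams stay mutually
    independent.
    """
    digest = hashlib.sha256(name.encode("utf-8")).digest()
    tag = int.from_bytes(digest[:4], "big")
    return np.random.default_rng([int(seed) % (2 ** 31), tag])


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal round-half-up (0.125 -> 0.13 at 2 digits), matching clinical tables."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def percent(part: float, whole: float, ndigits: int = 2) -> float:
    """Percentage of ``part`` in ``whole`` rounded half-up (e.g. 780/1270 -> 61.42)."""
    if whole == 0:
        raise ZeroDivisionError("percentage of an empty total")
    return round_half_up(100.0 * part / whole, ndigits)
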