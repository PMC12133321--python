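"""Small numeric helpers shared across modules."""

from __future__ import annotations

import math
from typing import Sequence


def apportion(total: int, weights: Sequence[float]) -> list[int]:
    """Split ``total`` into integer counts proportional to ``weights``.

    Largest-remainder (Hamilton) apportionment: floor each quota, then hand
    the leftover units to the largest fractional remainders.  Ties break on
    position, so the result is fully deterministic for a given weight order.
    """
    if total < 0:
        raise ValueError("total must be non-negative")
    wsum = float(sum(weights))
    if wsum <= 0:
        raise ValueError("weights must sum to a positive value")
    quotas = [total * w / wsum for w in weights]
    counts = [math.floor(q) for q in quotas]
    leftover = total - sum(counts)
    order = sorted(range(len(weights)), key=lambda i: (-(quotas[i] - counts[i]), i))
    for i in order[:leftover]:
        counts[i] += 1
    return counts


def pct_round_half_up(numerator: int, denominator: int) -> int:
    """Round ``100 * numerator / denominator`` half-up to an integer.

    Exact integer arithmetic, no float intermediate: round-half-up of
    100*n/d equals floor((200*n + d) / (2*d)) for d > 0.
    """
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return (200 * numerator + denominator) // (2 * denominator)


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Half-up rounding for display values (Python's round() is banker's)."""
    factor = 10 ** ndigits
    return math.floor(x * factor + 0.5) / factor
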