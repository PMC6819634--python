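"""Small shared helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

__all__ = ["round_half_up"]


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round half away from zero to ``ndigits`` decimals (table convention).

    Python's built-in ``round`` is banker's rounding; printed survey tables
    round 0.05 up, e.g. 5.35 -> 5.4.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))
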