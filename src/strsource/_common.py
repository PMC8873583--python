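"""Small shared numeric helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero, the convention used in forensic reports.

    Python's built-in ``round`` uses banker's rounding, which would turn
    98.185 into 98.18 instead of 98.19.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def percent(count: int, total: int, ndigits: int = 2) -> float:
    """Report ``count / total`` as a percentage rounded half-up."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round_half_up(100.0 * count / total, ndigits)
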