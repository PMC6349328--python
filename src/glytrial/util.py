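"""Small shared numeric helpers."""
from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round half away from zero at ``ndigits`` decimals (table convention).

    Python's built-in round is banker's rounding; printed clinical tables
    round 0.05 upward, so 7.25 -> 7.3.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def pct(numerator: float, denominator: float, ndigits: int = 1) -> float:
    """Percentage rounded half-up, as the tables print it."""
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    return round_half_up(100.0 * numerator / denominator, ndigits)
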