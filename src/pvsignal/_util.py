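"""Small shared numeric/text helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero (half-up), as printed report tables do.

    Python's builtin round() is banker's rounding; frequency tables in
    pharmacovigilance reports conventionally use half-up to 2 decimals.
    """
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def percent(count: float, denominator: float, ndigits: int = 2) -> float:
    """100*count/denominator rounded half-up."""
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    return round_half_up(100.0 * count / denominator, ndigits)
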