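"""Half-up decimal rounding for printed ratios.

Python's built-in ``round`` is banker's rounding; the summary indicators
(alleles per sample, share of selected samples) follow the conventional
half-up rule instead, e.g. 5/48 as a percentage prints 10.42.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction

_TWO_DP = Decimal("0.01")


def round2(value: float | int | Fraction | Decimal) -> float:
    """Round to 2 decimal places, ties away from zero (half-up)."""
    if isinstance(value, Fraction):
        dec = Decimal(value.numerator) / Decimal(value.denominator)
    elif isinstance(value, Decimal):
        dec = value
    else:
        dec = Decimal(repr(value))
    return float(dec.quantize(_TWO_DP, rounding=ROUND_HALF_UP))


def ratio2(numerator: int, denominator: int, scale: int = 1) -> float:
    """Exact ``scale * numerator / denominator`` rounded half-up to 2 dp."""
    if denominator == 0:
        raise ZeroDivisionError("ratio undefined for zero denominator")
    return round2(Fraction(numerator * scale, denominator))


def fmt2(value: float) -> str:
    """Format an already 2-dp-rounded value with exactly two decimals."""
    return f"{value:.2f}"
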