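"""Small shared helpers: half-up rounding and percentage formatting."""
from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round ``x`` to ``ndigits`` decimals, ties away from zero."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def percent(count: int | float, total: int | float, ndigits: int = 2) -> float:
    """100 * count / total, rounded half-up to ``ndigits`` decimals.

    Computed in exact decimal arithmetic so printed-style fractions such as
    63/96 -> 65.63 round the way a human would round them.
    """
    if total <= 0:
        raise ValueError(f"percentage denominator must be positive, got {total}")
    q = Decimal(1).scaleb(-ndigits)
    val = (Decimal(100) * Decimal(str(count)) / Decimal(str(total)))
    return float(val.quantize(q, rounding=ROUND_HALF_UP))
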