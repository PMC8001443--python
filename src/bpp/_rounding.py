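"""Half-up decimal rounding for report display.

Python's built-in ``round`` is banker's rounding; the tabulated
frequencies in this package follow the half-up convention (0.0615
displays as 0.062 at three decimals), so reports go through this helper.
Stored values stay unrounded.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(value: float, ndigits: int = 3) -> float:
    """Round ``value`` half-up to ``ndigits`` decimal places."""
    if ndigits < 0:
        raise ValueError("ndigits must be >= 0")
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(value))).quantize(quantum, rounding=ROUND_HALF_UP))
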