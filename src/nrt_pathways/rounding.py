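"""Half-up decimal rounding for printed percentages.

Python's built-in ``round`` is banker's rounding; published tables round
half away from zero, so 0.125 -> 0.13 at two decimals.
"""

from __future__ import annotations

import decimal


def round_half_up(value: float, decimals: int = 2) -> float:
    quantum = decimal.Decimal(1).scaleb(-decimals)
    return float(
        decimal.Decimal(repr(value)).quantize(quantum, rounding=decimal.ROUND_HALF_UP)
    )


def percent(numerator: float, denominator: float, decimals: int = 2) -> float:
    """``100 * numerator / denominator`` rounded half-up; 0.0 when empty."""
    if denominator == 0:
        return 0.0
    return round_half_up(100.0 * numerator / denominator, decimals)
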