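"""Half-up decimal rounding for printed tables.

Python's builtin ``round`` is banker's rounding; claims-study tables are
conventionally printed with round-half-up at one decimal, so 14.45 -> 14.5
(not 14.4).  Kept in one place so every report agrees bit-for-bit.
"""

from __future__ import annotations

import decimal


def round_half_up(value: float, ndigits: int = 1) -> float:
    quantum = decimal.Decimal(1).scaleb(-ndigits)
    return float(
        decimal.Decimal(repr(value)).quantize(quantum, rounding=decimal.ROUND_HALF_UP)
    )


def pct(numerator: float, denominator: float, ndigits: int = 1) -> float:
    """Percentage at ``ndigits`` decimals, round-half-up."""
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    return round_half_up(100.0 * numerator / denominator, ndigits)
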