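"""Small shared numeric helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def percent(numerator: int, denominator: int, decimals: int = 1) -> float:
    """Percentage to ``decimals`` places, round-half-up.

    Clinical tables conventionally print one decimal with half-up rounding
    (so 11.85 → 11.9, not banker's 11.8); Python's built-in ``round`` is
    half-even, hence the Decimal detour.
    """
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    q = Decimal(numerator) * 100 / Decimal(denominator)
    exp = Decimal(1).scaleb(-decimals)
    return float(q.quantize(exp, rounding=ROUND_HALF_UP))
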