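"""Small shared helpers."""

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero (the convention used for all reported
    percentages), rather than banker's rounding.

    >>> round_half_up(100 * 8 / 17)
    47.06
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))
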