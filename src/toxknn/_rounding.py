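"""Half-up decimal rounding used in all human-facing reports.

Internal computations keep full double precision; only exported tables and
printed values pass through :func:`round_half_up`.
"""

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round ``x`` to ``ndigits`` decimals with ties going away from zero.

    Python's builtin ``round`` uses banker's rounding, which disagrees with
    the conventional half-up rounding of toxicology report tables
    (e.g. 443.6667 -> 443.67, 0.125 -> 0.13).
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))
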