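"""Small shared helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round with ties going away from zero (table-style rounding).

    Python's built-in ``round`` is banker's rounding; abundance tables use
    the conventional half-away-from-zero rule instead.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


class FormatError(ValueError):
    """A file violated the expected on-disk format."""
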