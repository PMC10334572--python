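"""Small numeric helpers: decimal rounding used for report tables."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round ``x`` to ``ndigits`` decimals, ties away from zero.

    Operates on the shortest decimal representation of the float (its
    ``repr``), so 0.125 -> 0.13 rather than the banker's 0.12 that the
    builtin ``round`` produces.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def round_sig(x: float, sig: int = 2) -> float:
    """Round ``x`` to ``sig`` significant figures, ties away from zero."""
    if sig < 1:
        raise ValueError("sig must be >= 1")
    x = float(x)
    if x == 0.0:
        return 0.0
    d = Decimal(repr(x))
    q = Decimal(1).scaleb(d.adjusted() - (sig - 1))
    return float(d.quantize(q, rounding=ROUND_HALF_UP))
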