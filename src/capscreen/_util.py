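"""Small shared helpers: printed-style rounding and base arithmetic."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero, the convention of printed summary tables.

    Python's built-in round() is banker's rounding; published tables in this
    field round 0.5 up, so 70.55 -> 70.6 and 2.855 -> 2.86.
    """
    q = Decimal(1).scaleb(-ndigits)
    v = float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))
    return v


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def percent(part: float, whole: float, ndigits: int = 2) -> float:
    """part/whole as a percentage, rounded half-up (table formatting)."""
    if whole == 0:
        raise ZeroDivisionError("percentage of an empty total is undefined")
    return round_half_up(100.0 * part / whole, ndigits)
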