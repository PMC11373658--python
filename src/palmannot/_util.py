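"""Small shared helpers: rounding, percentages, sequence utilities."""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero (the convention used for all reported
    percentages), unlike Python's banker's rounding."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def percent(part: float, whole: float, ndigits: int = 1) -> float:
    """``100 * part / whole`` rounded half-up to *ndigits* decimals."""
    if whole == 0:
        raise ValueError("percentage of an empty total is undefined")
    return round_half_up(100.0 * part / whole, ndigits)


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def find_all(haystack: str, needle: str) -> list[int]:
    """All (possibly overlapping) match start positions of *needle*."""
    out = []
    i = haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out
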