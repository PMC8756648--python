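"""Exact half-up rounding on rationals.

Printed tables in this domain round halves up (31.45 -> 31.5), whereas
Python's built-in ``round`` is banker's rounding; computing on
:class:`fractions.Fraction` avoids binary-float artefacts like
``68.15 * 10 == 681.4999...``.
"""

from __future__ import annotations

from fractions import Fraction
from numbers import Rational


def round_half_up(value, ndigits: int = 0) -> float | int:
    """Round to ``ndigits`` decimals, halves away from zero-wards up.

    Accepts ints, floats or Fractions; returns int when ``ndigits == 0``.
    """
    f = value if isinstance(value, Rational) else Fraction(value).limit_denominator(10**12)
    scale = Fraction(10) ** ndigits
    scaled = f * scale
    # floor(x + 1/2) implements half-up for the nonnegative quantities used
    # here; negatives round half toward +inf, which never arises in outputs.
    q = (scaled + Fraction(1, 2)).__floor__()
    if ndigits == 0:
        return int(q)
    return float(Fraction(q, 1) / scale)


def mean_half_up(values, ndigits: int = 1) -> float | int:
    """Exact mean of integers/rationals rounded half-up to ``ndigits``."""
    vals = list(values)
    if not vals:
        raise ValueError("mean of empty sequence")
    total = sum(Fraction(v) for v in vals)
    return round_half_up(total / len(vals), ndigits)
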