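"""Decimal-exact rounding used at reporting boundaries.

Tabular reports in this field round half away from zero on the decimal
value (so 3.725 % -> 3.73 %). Binary floats make ``round()`` unreliable for
that convention: ``41.49 - 40`` is slightly below 1.49, so a naive round of
the relative deviation yields 3.72. Routing the arithmetic through
:class:`decimal.Decimal` built from ``repr`` keeps inputs that were given
with a finite decimal expansion exact.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Round ``value`` to ``ndigits`` decimals, ties away from zero."""
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))


def relative_deviation_percent(measured: float, actual: float, ndigits: int = 2) -> float:
    """``100 * (measured - actual) / actual`` carried out in decimal arithmetic.

    Both operands typically originate from 2-decimal table entries; the
    reported value is the half-up rounding of the exact decimal quotient
    (e.g. measured 41.49 vs actual 40 -> exactly 3.725 -> 3.73).
    """
    m = Decimal(repr(measured))
    a = Decimal(repr(actual))
    quantum = Decimal(1).scaleb(-ndigits)
    return float((100 * (m - a) / a).quantize(quantum, rounding=ROUND_HALF_UP))
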