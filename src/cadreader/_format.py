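"""Display rounding used by every report table.

All internal arithmetic is unrounded; values pass through here exactly
once, at presentation time. Half-way cases round away from zero, which
reproduces conventions like 139/317 -> 44% and 90/139 -> 65%.
"""

from __future__ import annotations

import decimal


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round ``x`` to ``ndigits`` decimals, ties away from zero."""
    q = decimal.Decimal(1).scaleb(-ndigits)
    d = decimal.Decimal(repr(float(x))).quantize(q, rounding=decimal.ROUND_HALF_UP)
    return float(d)


def pct(x: float, ndigits: int = 0) -> float:
    """Format a proportion in [0, 1] as a rounded percentage."""
    return round_half_away(100.0 * x, ndigits)
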