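"""Small shared helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero, as clinical tables are conventionally printed.

    Python's built-in ``round`` uses banker's rounding; report tables round
    39.5 to 40, so we go through :class:`decimal.Decimal`.
    """
    q = Decimal(1).scaleb(-ndigits)
    r = float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))
    return int(r) if ndigits <= 0 else r


def pct(numerator: int, denominator: int) -> float | None:
    """Percentage ``100 * numerator / denominator``; ``None`` when undefined."""
    if denominator == 0:
        return None
    return 100.0 * numerator / denominator
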