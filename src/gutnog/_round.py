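"""Half-up decimal rounding used for all displayed percentages and count means.

Python's built-in ``round`` is banker's rounding; the tabular outputs here
follow the half-up convention (0.05 -> 0.1 at one decimal), so every display
value goes through :func:`round_half_up`.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

__all__ = ["round_half_up"]


def round_half_up(value: float, ndigits: int = 0) -> float:
    """Round ``value`` to ``ndigits`` decimals, ties away from zero-ward up.

    Returns a float; for ``ndigits=0`` the result is still float (use ``int()``
    at the call site when an integer is wanted).
    """
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(value))).quantize(quantum, rounding=ROUND_HALF_UP))
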