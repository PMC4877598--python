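"""Shared helpers: reporting-grade rounding and input checks."""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round with ties going away from zero (the convention used for every
    percent / fold figure this package reports).

    Python's builtin ``round`` is banker's rounding; report tables in this
    domain round 44.45 up to 44.5, so we fix the convention explicitly.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


class InputError(ValueError):
    """Raised when an operation's preconditions on its input are violated."""


class ConfigError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""
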