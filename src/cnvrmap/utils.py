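"""Small shared numerics: printed-table rounding and kb formatting."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(value: float, decimals: int = 2) -> float:
    """Round with ties away from zero, like the published tables do.

    Python's builtin ``round`` is banker's rounding; 341/660*100 =
    51.66666... would survive either way, but e.g. 0.125 -> 0.13 here
    and 0.12 under the builtin.
    """
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def percent(numerator: float, denominator: float, decimals: int = 2) -> float:
    """``100 * numerator / denominator`` rounded half-up."""
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    return round_half_up(100.0 * numerator / denominator, decimals)


def format_kb(span_bp: int) -> str:
    """Format ``span_bp / 1000`` the way CNVR tables print it.

    Up to three decimals with trailing zeros (and a bare point)
    stripped: 27289730 bp -> "27289.73", 3994234 bp -> "3994.234",
    1000000 bp -> "1000".
    """
    text = f"{span_bp / 1000.0:.3f}".rstrip("0").rstrip(".")
    return text if text else "0"
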