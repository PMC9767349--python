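"""Centralized rounding and formatting rules for report rendering.

All human-readable rounding in the package goes through these helpers so
that TSV/Markdown reports agree: p-values to 3 significant figures
(scientific notation below 1e-3), odds ratios and confidence bounds to
one decimal with round-half-up, fractions as one-decimal percentages.
"""

from __future__ import annotations

import math
from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero (not banker's rounding)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def format_p(p: float) -> str:
    """p-value to 3 significant figures; scientific below 1e-3."""
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"p-value out of range: {p}")
    if p == 0.0:
        return "0"
    if p < 1e-3:
        return f"{p:.2e}"
    return f"{p:.3g}"


def format_ratio(x: float) -> str:
    """Odds ratio / CI bound to one decimal, round-half-up."""
    if math.isinf(x):
        return "inf"
    if math.isnan(x):
        return "NA"
    return f"{round_half_up(x, 1):.1f}"


def percent(fraction: float, ndigits: int = 1) -> float:
    """Fraction as a percentage, round-half-up to ``ndigits`` decimals."""
    return round_half_up(100.0 * fraction, ndigits)


def format_percent(fraction: float) -> str:
    """One-decimal percent rendering, e.g. 0.295 -> '29.5%'."""
    return f"{percent(fraction, 1):.1f}%"
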