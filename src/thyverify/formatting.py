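"""Table rendering helpers shared by the reporting layer.

Percentages are rendered at one decimal using a two-stage rounding chain:
the value is first rounded half-up at two decimals and that intermediate is
then rounded at one decimal with exact midpoints resolved downward.  This
is the chain a value follows when it passes through a two-decimal
intermediate (spreadsheet exports, pre-rounded statistical printouts), and
it is the convention this package uses everywhere a percentage is printed;
e.g. 83.0508% renders as "83.0" (83.05 -> 83.0) while 89.7727% renders as
"89.8".  JSON output always carries the full-precision fraction alongside.
"""

from __future__ import annotations

from decimal import ROUND_HALF_DOWN, ROUND_HALF_UP, Decimal

__all__ = ["round_percent", "fmt_percent", "fmt_proportion_percent", "markdown_table"]


def round_percent(value_percent: float, decimals: int = 1) -> float:
    """Round a percentage for display (two-stage chain, see module docstring)."""
    if decimals < 0:
        raise ValueError("decimals must be >= 0")
    d = Decimal(repr(float(value_percent)))
    inner = Decimal(1).scaleb(-(decimals + 1))
    outer = Decimal(1).scaleb(-decimals)
    staged = d.quantize(inner, rounding=ROUND_HALF_UP)
    return float(staged.quantize(outer, rounding=ROUND_HALF_DOWN))


def fmt_percent(fraction: float, decimals: int = 1) -> str:
    """Format a fraction in [0, 1] as a percent string, e.g. 0.359 -> '35.9'."""
    return f"{round_percent(100.0 * fraction, decimals):.{decimals}f}"


def fmt_proportion_percent(prop, decimals: int = 1) -> str:
    """Render a Proportion as 'pp.p (lo-hi)' percent with its CI."""
    lo, hi = prop.ci.as_percent()
    return (
        f"{fmt_percent(prop.estimate, decimals)} "
        f"({round_percent(lo, decimals):.{decimals}f}-{round_percent(hi, decimals):.{decimals}f})"
    )


def markdown_table(header: list[str], rows: list[list[str]]) -> str:
    """Minimal GitHub-style markdown table."""
    lines = ["| " + " | ".join(header) + " |", "|" + "|".join(" --- " for _ in header) + "|"]
    for row in rows:
        lines.append("| " + " | ".join(str(c) for c in row) + " |")
    return "\n".join(lines)
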