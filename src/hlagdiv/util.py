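"""Small shared helpers."""

from __future__ import annotations


def percent(numerator: float, denominator: float, digits: int = 1) -> float:
    """Percentage rounded to ``digits`` decimals, as printed in summaries
    (e.g. 4640 of 4738 -> 97.9)."""
    if denominator == 0:
        raise ZeroDivisionError("percentage of an empty total")
    return round(100.0 * numerator / denominator, digits)
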