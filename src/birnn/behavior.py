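"""Small behavioral-score conversions used when reporting cohort summaries."""

from __future__ import annotations

__all__ = ["recall_percentage", "variance_explained"]


def recall_percentage(mean_correct: float, n_items: int = 16) -> float:
    """Mean number of correctly recalled items as a percentage of list
    length, rounded to the nearest whole percent."""
    if n_items <= 0:
        raise ValueError("n_items must be positive")
    if not 0 <= mean_correct <= n_items:
        raise ValueError("mean_correct must lie in [0, n_items]")
    return round(100.0 * mean_correct / n_items)


def variance_explained(r: float, decimals: int = 2) -> float:
    """R-squared implied by a correlation coefficient, rounded for
    reporting."""
    if not -1.0 <= r <= 1.0:
        raise ValueError("correlation must lie in [-1, 1]")
    return round(r * r, decimals)
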