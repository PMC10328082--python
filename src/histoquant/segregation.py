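"""Sister-chromatid segregation ratios and control-derived asymmetry categories.

The segregation ratio of a late-mitotic cell is the corrected old-histone
total of the brighter chromatid set divided by the dimmer set, so it is
always >= 1 and symmetric in its arguments.  Category boundaries come from
a control ratio distribution: ``t_med = mean + 1*sd`` separates symmetric
from medium-asymmetric, ``t_high = mean + 2*sd`` separates medium from
high.  The sample (n - 1) standard deviation is used.  Classification uses
the unrounded thresholds; reporting rounds to 2 decimals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ChromatidMeasurement",
    "AsymmetryThresholds",
    "CATEGORIES",
    "chromatid_ratio",
    "derive_thresholds",
    "thresholds_from_summary",
    "classify_ratio",
    "category_percentages",
]

CATEGORIES = ("symmetric", "medium", "high")


@dataclass(frozen=True)
class ChromatidMeasurement:
    """Corrected old-histone totals of the two sister-chromatid sets."""

    cell_id: str
    total_a: float
    total_b: float

    @property
    def ratio(self) -> float:
        return chromatid_ratio(self.total_a, self.total_b)


@dataclass(frozen=True)
class AsymmetryThresholds:
    """Category boundaries (mean + 1 sd, mean + 2 sd) of a control distribution."""

    mu: float
    sigma: float
    n_control: int | None = None
    control_label: str | None = None

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")

    @property
    def t_med(self) -> float:
        return self.mu + self.sigma

    @property
    def t_high(self) -> float:
        return self.mu + 2.0 * self.sigma

    def rounded(self, decimals: int = 2) -> tuple[float, float]:
        """The reporting form of the two boundaries."""
        return (round(self.t_med, decimals), round(self.t_high, decimals))


def chromatid_ratio(total_a: float, total_b: float) -> float:
    """Brighter-over-dimmer ratio of the two chromatid totals (>= 1)."""
    if not (total_a > 0 and total_b > 0):
        raise ValueError(
            f"chromatid totals must be positive (got {total_a}, {total_b}); "
            "a non-positive total signals failed background correction"
        )
    return max(total_a, total_b) / min(total_a, total_b)


def derive_thresholds(
    control_ratios: Sequence[float] | np.ndarray,
    control_label: str | None = None,
) -> AsymmetryThresholds:
    """Thresholds from a list of control ratios (sample sd, ddof=1)."""
    x = np.asarray(control_ratios, dtype=np.float64)
    if x.size < 2:
        raise ValueError(f"need >= 2 control ratios, got {x.size}")
    return AsymmetryThresholds(
        mu=float(x.mean()),
        sigma=float(x.std(ddof=1)),
        n_control=int(x.size),
        control_label=control_label,
    )


def thresholds_from_summary(
    mu: float,
    sigma: float,
    n_control: int | None = None,
    control_label: str | None = None,
) -> AsymmetryThresholds:
    """Thresholds from published summary statistics instead of raw ratios."""
    return AsymmetryThresholds(mu, sigma, n_control, control_label)


def classify_ratio(ratio: float, thresholds: AsymmetryThresholds) -> str:
    """Category of one ratio: symmetric (<= t_med), medium ((t_med, t_high]),
    or high (> t_high); monotone non-decreasing in the ratio."""
    if ratio < 1:
        raise ValueError(f"segregation ratios are >= 1 by construction, got {ratio}")
    if ratio <= thresholds.t_med:
        return "symmetric"
    if ratio <= thresholds.t_high:
        return "medium"
    return "high"


def category_percentages(
    ratios: Iterable[float], thresholds: AsymmetryThresholds
) -> dict[str, float]:
    """Percentage of ratios in each category (sums to 100 before rounding)."""
    labels = [classify_ratio(r, thresholds) for r in ratios]
    n = len(labels)
    if n == 0:
        raise ValueError("empty ratio list")
    return {cat: 100.0 * labels.count(cat) / n for cat in CATEGORIES}
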