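"""The statistical decision tree applied to ratio and category outputs.

One-sample comparisons are gated on a Shapiro-Wilk normality test at
alpha = 0.05: normally distributed samples get a two-sided one-sample
t-test, skewed samples a two-sided Wilcoxon signed-rank test.  Two-sample
comparisons use the unpaired Student t-test (Welch available by flag).
Categorical distributions are compared by Pearson chi-square, either as an
R x C independence test (expected counts from the margins) or as a
goodness-of-fit test against stated proportions; no continuity correction.
No multiple-testing correction is applied anywhere, deliberately.
Significance stars: * p<0.05, ** p<0.01, *** p<0.001, **** p<0.0001, with
strict inequalities (p exactly at a cutoff takes the less significant
label).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as _sps

__all__ = [
    "TestResult",
    "SHAPIRO_ALPHA",
    "normality_gate",
    "one_sample_location_test",
    "two_sample_test",
    "chisq_test",
    "star_map",
]

SHAPIRO_ALPHA = 0.05


@dataclass(frozen=True)
class TestResult:
    __test__ = False  # not a pytest class

    method: str
    statistic: float
    p_value: float
    df: float | None = None
    stars: str = "ns"

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p_value {self.p_value} outside [0, 1]")


def _result(method: str, statistic: float, p: float, df: float | None = None) -> TestResult:
    p = float(min(max(p, 0.0), 1.0))
    return TestResult(method, float(statistic), p, df, star_map(p))


def normality_gate(x) -> str:
    """'normal' iff the Shapiro-Wilk p-value is >= 0.05, else 'skewed'."""
    x = np.asarray(x, dtype=np.float64)
    if x.size < 3:
        raise ValueError(f"need n >= 3 for the normality gate, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("constant sample: Shapiro-Wilk W undefined")
    _, p = _sps.shapiro(x)
    return "normal" if p >= SHAPIRO_ALPHA else "skewed"


def one_sample_location_test(x, null_value: float = 0.0) -> TestResult:
    """Two-sided one-sample location test routed through the normality gate.

    Normal data: one-sample t-test against ``null_value``.  Skewed data:
    Wilcoxon signed-rank test of ``x - null_value`` against a median of 0.
    """
    x = np.asarray(x, dtype=np.float64)
    gate = normality_gate(x)
    if gate == "normal":
        t, p = _sps.ttest_1samp(x, null_value)
        return _result("one-sample t", t, p, df=float(x.size - 1))
    d = x - null_value
    if np.all(d == 0):
        raise ValueError("all values equal the null value: Wilcoxon undefined")
    stat, p = _sps.wilcoxon(d)
    return _result("Wilcoxon signed-rank", stat, p)


def two_sample_test(x, y, welch: bool = False) -> TestResult:
    """Two-sided unpaired t-test; Student (equal variance) unless ``welch``."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size < 3 or y.size < 3:
        raise ValueError("need n >= 3 in both samples")
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        raise ValueError("both samples degenerate (zero variance)")
    t, p = _sps.ttest_ind(x, y, equal_var=not welch)
    if welch:
        vx, vy = x.var(ddof=1) / x.size, y.var(ddof=1) / y.size
        df = (vx + vy) ** 2 / (vx**2 / (x.size - 1) + vy**2 / (y.size - 1))
        return _result("two-sample t (Welch)", t, p, df=float(df))
    return _result("two-sample t", t, p, df=float(x.size + y.size - 2))


def chisq_test(observed, expected_proportions=None) -> TestResult:
    """Pearson chi-square, X^2 = sum((O - E)^2 / E), no continuity correction.

    With ``expected_proportions`` the test is goodness-of-fit on a 1-D count
    vector (E = proportions * n, df = C - 1); otherwise ``observed`` is an
    R x C table and expected counts come from the row/column margins,
    df = (R - 1)(C - 1).  Any zero expected count raises.
    """
    obs = np.asarray(observed, dtype=np.float64)
    if expected_proportions is not None:
        props = np.asarray(expected_proportions, dtype=np.float64)
        if obs.ndim != 1 or props.shape != obs.shape:
            raise ValueError("goodness-of-fit needs matching 1-D counts and proportions")
        expected = props / props.sum() * obs.sum()
        if (expected <= 0).any():
            raise ValueError("expected count of 0")
        stat, p = _sps.chisquare(obs, expected)
        return _result("chi-square-gof", stat, p, df=float(obs.size - 1))
    if obs.ndim != 2:
        raise ValueError("independence test needs an R x C table")
    expected = _sps.contingency.expected_freq(obs)
    if (expected <= 0).any():
        raise ValueError("expected count of 0")
    stat, p, df, _ = _sps.chi2_contingency(obs, correction=False)
    return _result("chi-square-independence", stat, p, df=float(df))


def star_map(p_value: float) -> str:
    """Asterisk notation with strict '<' cutoffs."""
    if not 0.0 <= p_value <= 1.0:
        raise ValueError(f"p-value {p_value} outside [0, 1]")
    if p_value < 0.0001:
        return "****"
    if p_value < 0.001:
        return "***"
    if p_value < 0.01:
        return "**"
    if p_value < 0.05:
        return "*"
    return "ns"
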