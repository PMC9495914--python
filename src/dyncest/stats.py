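"""Group comparisons: Welch's t, paired t, and cellwise significance maps.

These mirror the statistical surface of the dynamic study: an unequal-
variance two-sample comparison between test and control MTR values at a time
point, a paired comparison of each subject against its pre-injection value,
and a Welch test per cell of the offsets x time partial-spectral maps.  All
tests are two-sided.  No multiplicity correction is applied to the
significance map by default (a Benjamini-Hochberg option is available); the
map is therefore exploratory, with an expected ~alpha false-positive cell
fraction under the null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .zspec import PartialMap

__all__ = ["TestResult", "welch_t", "paired_t", "significance_map"]


@dataclass(frozen=True)
class TestResult:
    """t statistic, two-sided p, degrees of freedom and group sizes."""

    statistic: float
    p_value: float
    df: float
    n1: int
    n2: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p value must lie in [0, 1]")
        if self.df <= 0:
            raise ValueError("degrees of freedom must be positive")


def welch_t(a: np.ndarray, b: np.ndarray) -> TestResult:
    """Welch's unequal-variance t test with Welch-Satterthwaite df, two-sided."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 observations per group")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        raise ValueError("both groups have zero variance")
    res = sps.ttest_ind(a, b, equal_var=False)
    return TestResult(float(res.statistic), float(res.pvalue), float(res.df),
                      len(a), len(b))


def paired_t(pre: np.ndarray, post: np.ndarray) -> TestResult:
    """Paired (one-sample-on-differences) t test, df = n - 1, two-sided."""
    pre = np.asarray(pre, float)
    post = np.asarray(post, float)
    if len(pre) != len(post):
        raise ValueError("paired samples must have equal length")
    if len(pre) < 2:
        raise ValueError("need at least 2 pairs")
    if (post - pre).var(ddof=1) == 0:
        raise ValueError("differences have zero variance")
    res = sps.ttest_rel(post, pre)
    return TestResult(float(res.statistic), float(res.pvalue), float(len(pre) - 1),
                      len(pre), len(pre))


def significance_map(
    test_stack: np.ndarray | list[PartialMap],
    control_stack: np.ndarray | list[PartialMap],
    alpha: float = 0.05,
    fdr: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Cellwise Welch comparison of two groups of partial maps.

    Inputs are (n_subjects, n_offsets, n_sweeps) stacks (or lists of
    per-subject PartialMap).  Returns ``(significant, p)`` where
    ``significant`` is the boolean p < alpha mask (after optional
    Benjamini-Hochberg adjustment, off by default).
    """
    def as_stack(x):
        if isinstance(x, (list, tuple)):
            x = np.stack([m.mtr_avg for m in x])
        return np.asarray(x, float)

    t_stack, c_stack = as_stack(test_stack), as_stack(control_stack)
    if t_stack.shape[1:] != c_stack.shape[1:]:
        raise ValueError("group map axes do not match")
    if t_stack.shape[0] < 2 or c_stack.shape[0] < 2:
        raise ValueError("need at least 2 subjects per group")
    res = sps.ttest_ind(t_stack, c_stack, axis=0, equal_var=False)
    p = np.asarray(res.pvalue, float)
    if fdr:
        flat = sps.false_discovery_control(p.ravel(), method="bh")
        p_adj = flat.reshape(p.shape)
        return p_adj < alpha, p
    return p < alpha, p
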