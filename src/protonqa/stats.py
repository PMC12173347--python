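"""Comparison statistics for QA cohorts: paired t-test between two QA methods
on the same plans, and one-way ANOVA across treatment sites.

Thin wrappers over scipy.stats with the degenerate cases handled explicitly
(identical samples, zero-variance differences).  Two-sided p-values
throughout; no multiple-testing correction is applied (a documented
limitation of the emulated workflow).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as _st

from .spc import RateSummary, summarize_rates

__all__ = ["PairedSample", "paired_t", "one_way_anova", "summarize"]


@dataclass
class PairedSample:
    """Per-plan rates from two methods, same plans in the same order."""

    a: np.ndarray
    b: np.ndarray

    def __post_init__(self) -> None:
        self.a = np.atleast_1d(np.asarray(self.a, dtype=float))
        self.b = np.atleast_1d(np.asarray(self.b, dtype=float))
        if len(self.a) != len(self.b):
            raise ValueError("paired samples must have equal length")
        if len(self.a) < 2:
            raise ValueError("paired t-test needs at least 2 pairs")

    @property
    def n(self) -> int:
        return len(self.a)


def paired_t(sample: PairedSample) -> tuple[float, float]:
    """Paired t-test on d = a - b: t = mean(d) / (sd(d)/sqrt(n)), two-sided p
    from the t distribution with n-1 df.  Identical samples give (0, 1);
    zero-variance differences with nonzero mean are an error (infinite t)."""
    d = sample.a - sample.b
    sd = float(np.std(d, ddof=1))
    if sd == 0:
        if float(np.mean(d)) == 0:
            return 0.0, 1.0
        raise ValueError("zero-variance differences with nonzero mean: t is infinite")
    t, p = _st.ttest_rel(sample.a, sample.b)
    return float(t), float(p)


def one_way_anova(groups: list) -> tuple[float, float]:
    """Classical one-way ANOVA F statistic and p-value across rate groups."""
    arrays = [np.atleast_1d(np.asarray(g, dtype=float)) for g in groups]
    if len(arrays) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    if any(len(g) < 2 for g in arrays):
        raise ValueError("every group needs at least 2 values")
    if all(float(np.var(g)) == 0 for g in arrays):
        raise ValueError("degenerate: zero within-group variance in every group")
    f, p = _st.f_oneway(*arrays)
    return float(f), float(p)


def summarize(rates) -> RateSummary:
    """Mean and n-1 sample SD of a rate list (the 'mean +/- SD' table cell)."""
    return summarize_rates(rates)
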