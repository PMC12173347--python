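"""Statistical process-control limits for per-plan gamma passing rates.

Three families of limits, all standard in radiotherapy QA:

* **Confidence limit** (TG-119 style): the mean deviation from the ideal
  plus 1.96 SD.  Passing rates deviate *downward* from 100%, so the limit is
  reported as a lower bound on the rate:
  ``CL = 100 - (|100 - mean| + 1.96 * SD)``.
* **Tolerance limits** (individuals control chart): center line = mean of the
  series, control lines = center +/- 2.660 * mean moving range, where the
  moving range is the mean absolute difference of consecutive observations in
  acquisition order.  The lower control line is the reported tolerance limit.
* **Action limits** (TG-218): ``dA = beta * sqrt(sd^2 + (mean - target)^2)``
  with beta = 6 and target = 100; limits are target +/- dA/2 and the lower
  one is the reported action limit.

Raw values are exact closed forms; rounding to one decimal and capping at
[0, 100] happen only at report time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "QASeries",
    "RateSummary",
    "SPCLimits",
    "summarize_rates",
    "confidence_limit",
    "moving_range",
    "i_chart",
    "action_limits",
    "spc_limits",
    "limits_report",
]

ICHART_CONSTANT = 2.660  # individuals-chart factor: 3 / d2(n=2), d2 = 1.128
DEFAULT_TARGET = 100.0
DEFAULT_BETA = 6.0
POOLED_LABEL = "All regions"


@dataclass
class QASeries:
    """Ordered per-plan passing rates for one site and one set of criteria.

    Order is acquisition order — the moving range depends on it.
    """

    site: str
    criteria_label: str
    rates: np.ndarray

    def __post_init__(self) -> None:
        self.rates = np.atleast_1d(np.asarray(self.rates, dtype=float))
        if np.any(self.rates <= 0) or np.any(self.rates > 100):
            bad = self.rates[(self.rates <= 0) | (self.rates > 100)][0]
            raise ValueError(f"passing rate {bad} outside (0, 100]")

    @property
    def n(self) -> int:
        return len(self.rates)


@dataclass(frozen=True)
class RateSummary:
    """Mean and sample SD (n-1 denominator) of a passing-rate series."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be non-negative")


@dataclass(frozen=True)
class SPCLimits:
    """One full set of derived limits for a site/criteria cell."""

    confidence_limit: float
    center_line: float
    ucl: float
    lcl: float
    mean_moving_range: float
    delta_a: float
    upper_action: float
    lower_action: float


def summarize_rates(rates) -> RateSummary:
    rates = np.asarray(rates, dtype=float)
    if len(rates) < 2:
        raise ValueError("at least 2 rates required for a summary")
    return RateSummary(
        mean=float(np.mean(rates)), sd=float(np.std(rates, ddof=1)), n=len(rates)
    )


def confidence_limit(summary: RateSummary) -> float:
    """TG-119-style confidence limit on the passing rate:
    100 - (|100 - mean| + 1.96 * SD)."""
    return 100.0 - (abs(100.0 - summary.mean) + 1.96 * summary.sd)


def moving_range(series: QASeries) -> float:
    """Mean moving range: (1/(n-1)) * sum |x_i - x_{i-1}|, acquisition order."""
    if series.n < 2:
        raise ValueError("moving range needs at least 2 observations")
    return float(np.mean(np.abs(np.diff(series.rates))))


def i_chart(series: QASeries) -> tuple[float, float, float]:
    """Individuals-chart lines (center, UCL, LCL): center = mean of the
    series, UCL/LCL = center +/- 2.660 * mean moving range."""
    mr = moving_range(series)
    center = float(np.mean(series.rates))
    return center, center + ICHART_CONSTANT * mr, center - ICHART_CONSTANT * mr


def action_limits(
    summary: RateSummary,
    target: float = DEFAULT_TARGET,
    beta: float = DEFAULT_BETA,
) -> tuple[float, float, float]:
    """TG-218 action limits: returns (delta_a, upper, lower) with
    delta_a = beta * sqrt(sd^2 + (mean - target)^2), limits = target -/+ dA/2."""
    if beta <= 0:
        raise ValueError("beta must be positive")
    delta_a = beta * float(np.sqrt(summary.sd**2 + (summary.mean - target) ** 2))
    return delta_a, target + delta_a / 2.0, target - delta_a / 2.0


def spc_limits(
    series: QASeries,
    target: float = DEFAULT_TARGET,
    beta: float = DEFAULT_BETA,
) -> SPCLimits:
    """All limits for one series (exact, unrounded, uncapped)."""
    summary = summarize_rates(series.rates)
    center, ucl, lcl = i_chart(series)
    delta_a, upper, lower = action_limits(summary, target, beta)
    return SPCLimits(
        confidence_limit=confidence_limit(summary),
        center_line=center,
        ucl=ucl,
        lcl=lcl,
        mean_moving_range=moving_range(series),
        delta_a=delta_a,
        upper_action=upper,
        lower_action=lower,
    )


def limits_report(
    serieses: list[QASeries],
    target: float = DEFAULT_TARGET,
    beta: float = DEFAULT_BETA,
) -> pd.DataFrame:
    """Site-by-criteria table of CL / TL / AL, one decimal, with a pooled
    "All regions" row appended per criteria label.

    TL is the lower control line of the individuals chart and AL the lower
    action limit (rates fail downward); values are capped to [0, 100].
    """
    if not serieses:
        raise ValueError("no series supplied")

    def _cap(v: float) -> float:
        return float(np.clip(round(v, 1), 0.0, 100.0))

    rows = []
    by_label: dict[str, list[QASeries]] = {}
    for s in serieses:
        lim = spc_limits(s, target, beta)
        rows.append(
            {
                "site": s.site,
                "criteria": s.criteria_label,
                "n": s.n,
                "confidence_limit": _cap(lim.confidence_limit),
                "tolerance_limit": _cap(lim.lcl),
                "action_limit": _cap(lim.lower_action),
            }
        )
        by_label.setdefault(s.criteria_label, []).append(s)

    for label, group in by_label.items():
        pooled = QASeries(
            site=POOLED_LABEL,
            criteria_label=label,
            rates=np.concatenate([s.rates for s in group]),
        )
        lim = spc_limits(pooled, target, beta)
        rows.append(
            {
                "site": POOLED_LABEL,
                "criteria": label,
                "n": pooled.n,
                "confidence_limit": _cap(lim.confidence_limit),
                "tolerance_limit": _cap(lim.lcl),
                "action_limit": _cap(lim.lower_action),
            }
        )
    return pd.DataFrame(rows)
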