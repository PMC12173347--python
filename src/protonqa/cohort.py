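"""Site-labelled cohorts of per-plan gamma passing rates.

Rates are drawn from a normal distribution truncated above at 100% (a passing
rate cannot exceed 100).  Truncation shifts the moments of a normal, so the
generator *moment-matches*: it solves for the pre-truncation (mu0, sigma0)
whose upper-truncated distribution has exactly the requested mean and SD, and
samples from that.  Sample statistics therefore converge to the targets as n
grows, which is what lets the SPC limits computed on generated cohorts recover
the closed-form values of the generating parameters.

An upper-truncated normal always satisfies SD < (bound - mean); summary cells
with SD >= (100 - mean) — which occur in heavily right-censored clinical
passing-rate tables — are infeasible for this family.  For those the mean is
matched exactly and the SD capped at the achievable maximum (documented
limitation; a warning attribute on the spec records it).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.stats import truncnorm

from .spc import QASeries

__all__ = ["SiteSpec", "CohortSpec", "generate_cohort", "truncated_normal_params"]

# beta below this leaves < 1e-9 truncated mass; treat as effectively untruncated
_BETA_FREE = 8.0
# most negative standardized bound before the family degenerates numerically
_BETA_FLOOR = -8.0


@dataclass(frozen=True)
class SiteSpec:
    """Target statistics for one site's passing-rate series."""

    site: str
    mean: float
    sd: float
    n: int = 10

    def __post_init__(self) -> None:
        if not 0 < self.mean <= 100:
            raise ValueError(f"mean {self.mean} outside (0, 100]")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")
        if self.n < 2:
            raise ValueError("n must be at least 2")


@dataclass(frozen=True)
class CohortSpec:
    """A cohort: one series per site, common criteria label and seed."""

    sites: tuple[SiteSpec, ...]
    criteria_label: str = "3%/3mm"
    upper: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.sites:
            raise ValueError("cohort needs at least one site")


def _standard_truncated_moments(beta: float) -> tuple[float, float]:
    """(mean, sd) of a standard normal truncated to (-inf, beta]."""
    m, v = truncnorm.stats(-np.inf, beta, moments="mv")
    return float(m), float(np.sqrt(v))


def truncated_normal_params(mean: float, sd: float, upper: float = 100.0):
    """Solve for (mu0, sigma0, beta) such that N(mu0, sigma0) truncated to
    (-inf, upper] has the requested moments.

    beta is the standardized bound (upper - mu0)/sigma0.  Returns the
    achievable-SD solution: when the requested SD is infeasible
    (sd >= upper - mean is impossible under upper truncation) the SD is
    capped at the family's maximum and only the mean is matched exactly.
    """
    gap = upper - mean
    if gap < 0:
        raise ValueError(f"mean {mean} exceeds the upper bound {upper}")
    if sd == 0 or gap == 0:
        return mean, 0.0, np.inf

    def ratio(beta: float) -> float:
        m, s = _standard_truncated_moments(beta)
        return s / (beta - m)

    target_ratio = sd / gap
    if target_ratio <= ratio(_BETA_FREE):
        # bound is >= 8 sigma away: truncation negligible, plain normal
        return mean, sd, gap / sd

    max_ratio = ratio(_BETA_FLOOR)
    if target_ratio >= max_ratio:
        beta = _BETA_FLOOR  # capped: SD short of target, mean exact
    else:
        beta = brentq(lambda b: ratio(b) - target_ratio, _BETA_FLOOR, _BETA_FREE)

    m, s = _standard_truncated_moments(beta)
    sigma0 = gap / (beta - m)  # matches the mean gap exactly
    mu0 = upper - beta * sigma0
    return mu0, sigma0, beta


def generate_cohort(spec: CohortSpec) -> list[QASeries]:
    """One QASeries per site, reproducible from the spec's seed."""
    rng = np.random.default_rng(spec.seed)
    out = []
    for site in spec.sites:
        child = np.random.default_rng(int(rng.integers(2**31)))
        if site.sd == 0:
            rates = np.full(site.n, float(site.mean))
        else:
            mu0, sigma0, beta = truncated_normal_params(site.mean, site.sd, spec.upper)
            rates = truncnorm.rvs(
                -np.inf, beta, loc=mu0, scale=sigma0, size=site.n, random_state=child
            )
            # guard against floating round-up at the bound
            rates = np.minimum(rates, spec.upper)
        out.append(QASeries(site=site.site, criteria_label=spec.criteria_label, rates=rates))
    return out
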