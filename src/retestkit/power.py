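"""Two-sample t-test power analysis via the noncentral t distribution.

Exact power of the two-tailed pooled-variance (Student) t-test: with group
sizes n1, n2, common SD σ and true mean difference δ, the test statistic
follows a noncentral t with df = n1 + n2 − 2 and noncentrality
λ = δ / (σ·√(1/n1 + 1/n2)); power is the probability that it falls beyond
the two-sided critical values. The normal approximation is provided for
cross-checks only.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil, sqrt

import numpy as np
from scipy import stats
from scipy.optimize import brentq

from .errors import DomainError


@dataclass
class PowerAnalysisRow:
    """One metric's power-analysis summary (young-vs-elderly style)."""

    metric: str
    alpha: float
    n1: int
    n2: int
    sd: float
    min_diff_80: float
    observed_diff: float
    achieved_power: float
    required_n: int

    def as_record(self) -> dict:
        return {
            "metric": self.metric,
            "alpha": self.alpha,
            "n1": self.n1,
            "n2": self.n2,
            "sd": self.sd,
            "min_diff_80": self.min_diff_80,
            "observed_diff": self.observed_diff,
            "achieved_power": self.achieved_power,
            "required_n": self.required_n,
        }


def _check(sd: float, n1: int, n2: int, alpha: float) -> None:
    if sd <= 0:
        raise DomainError(f"sd must be positive, got {sd}")
    if n1 < 2 or n2 < 2:
        raise DomainError(f"group sizes must be >= 2, got {n1}, {n2}")
    if not 0.0 < alpha < 1.0:
        raise DomainError(f"alpha must be in (0,1), got {alpha}")


def t_test_power(
    delta: float, sd: float, n1: int, n2: int, alpha: float = 0.05
) -> float:
    """Power of the two-sided pooled-variance two-sample t-test."""
    _check(sd, n1, n2, alpha)
    df = n1 + n2 - 2
    nc = abs(delta) / (sd * sqrt(1.0 / n1 + 1.0 / n2))
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)
    upper = stats.nct.sf(tcrit, df, nc)
    lower = stats.nct.cdf(-tcrit, df, nc)
    # scipy's nct loses accuracy at extreme noncentrality; power is 1 there
    if not np.isfinite(upper) or not np.isfinite(lower):
        return 1.0 if nc > tcrit else float(alpha)
    return float(upper + lower)


def t_test_power_normal_approx(
    delta: float, sd: float, n1: int, n2: int, alpha: float = 0.05
) -> float:
    """Large-sample normal approximation to the same power (cross-check)."""
    _check(sd, n1, n2, alpha)
    se = sd * sqrt(1.0 / n1 + 1.0 / n2)
    z = abs(delta) / se
    za = stats.norm.ppf(1.0 - alpha / 2.0)
    return float(stats.norm.sf(za - z) + stats.norm.cdf(-za - z))


def min_detectable_difference(
    sd: float,
    n1: int,
    n2: int,
    alpha: float = 0.05,
    target_power: float = 0.80,
) -> float:
    """Smallest true difference δ > 0 yielding the target power.

    Power is continuous and strictly increasing in δ, so the root of
    power(δ) − target is bracketed by doubling and solved by Brent's
    method to 1e-6 relative tolerance.
    """
    _check(sd, n1, n2, alpha)
    if not 0.0 < target_power < 1.0:
        raise DomainError(f"target_power must be in (0,1), got {target_power}")

    def gap(d: float) -> float:
        return t_test_power(d, sd, n1, n2, alpha) - target_power

    hi = sd
    while gap(hi) < 0:
        hi *= 2.0
    return float(brentq(gap, 0.0, hi, rtol=1e-9, xtol=1e-12))


def required_sample_size(
    delta: float,
    sd: float,
    alpha: float = 0.05,
    target_power: float = 0.80,
    allocation: float = 1.0,
    per_group: bool = False,
) -> int:
    """Smallest sample size reaching the target power at the given δ.

    By default returns the TOTAL N, split across the two groups by the
    ``allocation`` ratio n1/n2 (equal by default); ``per_group=True``
    instead returns the common per-group size for equal allocation. The
    search walks N upward from the floor of 4 (2 per group), coarsening to
    a doubling bracket plus bisection when the answer is large.
    """
    if delta == 0:
        raise DomainError("required sample size undefined for delta = 0")
    if allocation <= 0:
        raise DomainError(f"allocation ratio must be positive, got {allocation}")
    _check(sd, 2, 2, alpha)

    def split(total: int) -> tuple[int, int]:
        n1 = max(2, round(total * allocation / (1.0 + allocation)))
        n2 = max(2, total - n1)
        return n1, n2

    def ok(total: int) -> bool:
        n1, n2 = split(total)
        if n1 + n2 != total:
            return False
        return t_test_power(delta, sd, n1, n2, alpha) >= target_power

    lo, hi = 4, 4
    while not ok(hi):
        lo, hi = hi, hi * 2
        if hi > 10**9:
            raise DomainError("required sample size exceeds 1e9")
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if ok(mid):
            hi = mid
        else:
            lo = mid
    total = hi if ok(hi) else hi + 1
    if per_group:
        if allocation != 1.0:
            raise DomainError("per_group reading requires equal allocation")
        return ceil(total / 2)
    return total


def power_analysis_row(
    metric: str,
    sd: float,
    n1: int,
    n2: int,
    observed_diff: float,
    alpha: float = 0.05,
    target_power: float = 0.80,
) -> PowerAnalysisRow:
    """Assemble one power-analysis table row for a metric.

    ``sd`` is the assumed common SD of the metric across subjects (whole-WM
    values); ``observed_diff`` the young-minus-elderly difference in means.
    ``required_n`` is total N at equal allocation for the observed
    difference.
    """
    achieved = t_test_power(observed_diff, sd, n1, n2, alpha) if observed_diff != 0 else alpha
    required = (
        required_sample_size(observed_diff, sd, alpha, target_power)
        if observed_diff != 0
        else 0
    )
    return PowerAnalysisRow(
        metric=metric,
        alpha=alpha,
        n1=n1,
        n2=n2,
        sd=sd,
        min_diff_80=min_detectable_difference(sd, n1, n2, alpha, target_power),
        observed_diff=observed_diff,
        achieved_power=achieved,
        required_n=required,
    )
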