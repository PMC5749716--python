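"""Sensitivity analyses: repeated-measures ANOVA and error-aware comparisons.

Whether a metric can distinguish spinal-cord regions, vertebral levels or
age groups is assessed on two axes at once:

1. classical significance — one-way repeated-measures ANOVA across the
   within-subject conditions (levels or ROIs), with Lilliefors normality
   and Mauchly sphericity checks, a Greenhouse-Geisser df correction when
   sphericity fails, and Tukey HSD post hocs; a split-plot (mixed-design)
   ANOVA adds age group as a between-subjects factor;
2. measurement error — a difference between condition or group means only
   counts as "detectable" if it also exceeds the test-retest error
   envelope given by CI_d for the matching stratum.

A difference can be statistically significant yet indistinguishable from
measurement error; both flags are always reported. Normality failures are
reported as warnings, not gates. No multiple-testing correction is applied
across metrics or strata.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import log, sqrt
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.stats import studentized_range

from .errors import DegenerateDataError, DomainError, InsufficientDataError
from .reliability import DifferenceSummary

logger = logging.getLogger(__name__)


@dataclass
class AssumptionTestResult:
    statistic: float
    p_value: float
    method: str
    n: int
    df: float


@dataclass
class RepeatedAnovaResult:
    f_stat: float
    df_num: float
    df_den: float
    epsilon_gg: float
    sphericity: AssumptionTestResult
    gg_applied: bool
    p_value: float
    p_uncorrected: float
    ss_conditions: float
    ss_subjects: float
    ss_error: float
    ms_error: float
    n: int
    k: int

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


@dataclass
class PosthocComparison:
    pair: tuple[str, str]
    mean_diff: float
    q_stat: float
    p_adjusted: float
    significant: bool


@dataclass
class EffectResult:
    f_stat: float
    df_num: float
    df_den: float
    p_value: float


@dataclass
class MixedAnovaResult:
    between: EffectResult
    within: EffectResult
    interaction: EffectResult
    epsilon_gg: float
    sphericity: AssumptionTestResult
    gg_applied: bool


@dataclass
class ErrorAwareComparison:
    pair: tuple[str, str]
    observed_diff: float
    error_interval_halfwidth: float
    distinguishable: bool
    significant: bool


# ---------------------------------------------------------------------------
# assumption checks


def lilliefors_test(
    values: np.ndarray,
    mc_reps: int = 10000,
    seed: int | np.random.Generator | None = None,
) -> AssumptionTestResult:
    """Lilliefors test of composite normality (KS with estimated mean/SD).

    The null distribution of the statistic depends only on the sample size
    once mean and SD are estimated, so the p-value is obtained by Monte
    Carlo: ``mc_reps`` standard-normal samples of the same size are drawn,
    the statistic recomputed on each, and p = (1 + #exceedances)/(reps+1).
    """
    values = np.asarray(values, dtype=float).ravel()
    n = values.size
    if n < 4:
        raise InsufficientDataError(f"Lilliefors test needs n >= 4, got {n}")
    sd = values.std(ddof=1)
    if sd == 0.0:
        raise DegenerateDataError("constant vector: normality test undefined")
    d_obs = _lilliefors_statistic(values)
    rng = np.random.default_rng(seed)
    null = rng.standard_normal((mc_reps, n))
    d_null = _lilliefors_statistic_batch(null)
    p = (1.0 + float(np.count_nonzero(d_null >= d_obs))) / (mc_reps + 1.0)
    return AssumptionTestResult(
        statistic=float(d_obs), p_value=p, method="lilliefors-mc", n=n, df=np.nan
    )


def _lilliefors_statistic(x: np.ndarray) -> float:
    z = np.sort((x - x.mean()) / x.std(ddof=1))
    cdf = stats.norm.cdf(z)
    n = x.size
    up = np.arange(1, n + 1) / n - cdf
    down = cdf - np.arange(0, n) / n
    return float(max(up.max(), down.max()))


def _lilliefors_statistic_batch(X: np.ndarray) -> np.ndarray:
    """Row-wise Lilliefors statistic for an (reps, n) array."""
    n = X.shape[1]
    z = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, ddof=1, keepdims=True)
    z.sort(axis=1)
    cdf = stats.norm.cdf(z)
    grid_hi = np.arange(1, n + 1) / n
    grid_lo = np.arange(0, n) / n
    return np.maximum((grid_hi - cdf).max(axis=1), (cdf - grid_lo).max(axis=1))


def _helmert_contrasts(k: int) -> np.ndarray:
    """k x (k-1) orthonormal contrast matrix (columns sum to zero)."""
    C = np.zeros((k, k - 1))
    for j in range(1, k):
        C[:j, j - 1] = 1.0
        C[j, j - 1] = -j
        C[:, j - 1] /= np.linalg.norm(C[:, j - 1])
    return C


def mauchly_test(within_matrix: np.ndarray) -> AssumptionTestResult:
    """Mauchly's W test of sphericity for an n x k within-subject matrix.

    W is the ratio of the determinant of the orthonormal-contrast
    covariance to the k-1 power of its mean eigenvalue; the p-value uses
    the standard chi-square approximation with df = k(k-1)/2 - 1. For
    k = 2 there is a single contrast, so W = 1 and p = 1: sphericity holds
    trivially.
    """
    X = np.asarray(within_matrix, dtype=float)
    n, k = X.shape
    if k < 2:
        raise InsufficientDataError("need at least 2 conditions")
    if k == 2:
        return AssumptionTestResult(1.0, 1.0, "mauchly", n, 0.0)
    if n <= k:
        raise InsufficientDataError(
            f"Mauchly's test needs n > k (got n={n}, k={k}): contrast "
            "covariance is singular"
        )
    C = _helmert_contrasts(k)
    S = np.cov(X, rowvar=False, ddof=1)
    A = C.T @ S @ C
    det = float(np.linalg.det(A))
    tr = float(np.trace(A))
    if tr <= 0 or det <= 0:
        raise DegenerateDataError("singular contrast covariance")
    W = det / (tr / (k - 1)) ** (k - 1)
    df = k * (k - 1) / 2.0 - 1.0
    # Mauchly's chi-square correction factor
    f = 1.0 - (2.0 * (k - 1) ** 2 + (k - 1) + 2.0) / (6.0 * (k - 1) * (n - 1))
    chi2 = -(n - 1) * f * log(W)
    p = float(stats.chi2.sf(chi2, df))
    return AssumptionTestResult(float(W), p, "mauchly", n, df)


def greenhouse_geisser_epsilon(within_matrix: np.ndarray) -> float:
    """Box/Greenhouse-Geisser ε̂ from the sample condition covariance.

    Clipped to its mathematical range [1/(k-1), 1]; ε = 1 means exact
    sphericity (and k = 2 always gives 1).
    """
    X = np.asarray(within_matrix, dtype=float)
    n, k = X.shape
    if n < 2 or k < 2:
        raise InsufficientDataError("need n >= 2 subjects and k >= 2 conditions")
    if k == 2:
        return 1.0
    S = np.cov(X, rowvar=False, ddof=1)
    mean_diag = float(np.trace(S)) / k
    grand = float(S.mean())
    row_means = S.mean(axis=1)
    num = (k * (mean_diag - grand)) ** 2
    den = (k - 1) * (
        float((S**2).sum()) - 2.0 * k * float((row_means**2).sum()) + k**2 * grand**2
    )
    if den <= 0:
        return 1.0
    return float(np.clip(num / den, 1.0 / (k - 1), 1.0))


# ---------------------------------------------------------------------------
# ANOVA


def _within_decomposition(X: np.ndarray) -> tuple[float, float, float]:
    """(ss_subjects, ss_conditions, ss_error) of the two-way layout."""
    n, k = X.shape
    grand = X.mean()
    ss_subjects = k * float(((X.mean(axis=1) - grand) ** 2).sum())
    ss_conditions = n * float(((X.mean(axis=0) - grand) ** 2).sum())
    ss_total = float(((X - grand) ** 2).sum())
    ss_error = max(ss_total - ss_subjects - ss_conditions, 0.0)
    return ss_subjects, ss_conditions, ss_error


def one_way_repeated_anova(
    within_matrix: np.ndarray, alpha_sphericity: float = 0.05
) -> RepeatedAnovaResult:
    """One-way repeated-measures ANOVA on an n x k complete matrix.

    F = MS_conditions / MS_error with df (k-1), (k-1)(n-1). When Mauchly's
    test rejects sphericity at ``alpha_sphericity`` (and k > 2), both
    degrees of freedom are multiplied by the Greenhouse-Geisser ε̂ before
    the p-value is computed; the uncorrected p is kept alongside.
    """
    X = np.asarray(within_matrix, dtype=float)
    if X.ndim != 2:
        raise InsufficientDataError("within_matrix must be 2-D (subjects x conditions)")
    n, k = X.shape
    if n < 3 or k < 2:
        raise InsufficientDataError(f"need n >= 3 and k >= 2, got n={n}, k={k}")
    if not np.all(np.isfinite(X)):
        raise InsufficientDataError("incomplete within-subject matrix (no imputation)")
    ss_subjects, ss_conditions, ss_error = _within_decomposition(X)
    df_num = float(k - 1)
    df_den = float((k - 1) * (n - 1))
    ms_cond = ss_conditions / df_num
    ms_err = ss_error / df_den
    f_stat = ms_cond / ms_err if ms_err > 0 else (0.0 if ms_cond == 0.0 else np.inf)
    try:
        sphericity = mauchly_test(X)
        eps = greenhouse_geisser_epsilon(X)
    except (DegenerateDataError, InsufficientDataError):
        # no within-subject variability, or n <= k: sphericity cannot be
        # assessed and is taken to hold
        sphericity = AssumptionTestResult(1.0, 1.0, "mauchly", n, 0.0)
        eps = 1.0
    gg_applied = bool(sphericity.p_value < alpha_sphericity and k > 2)
    p_unc = float(stats.f.sf(f_stat, df_num, df_den))
    if gg_applied:
        df_num_c, df_den_c = df_num * eps, df_den * eps
    else:
        df_num_c, df_den_c = df_num, df_den
    p = float(stats.f.sf(f_stat, df_num_c, df_den_c))
    return RepeatedAnovaResult(
        f_stat=float(f_stat),
        df_num=df_num_c,
        df_den=df_den_c,
        epsilon_gg=eps,
        sphericity=sphericity,
        gg_applied=gg_applied,
        p_value=p,
        p_uncorrected=p_unc,
        ss_conditions=ss_conditions,
        ss_subjects=ss_subjects,
        ss_error=ss_error,
        ms_error=ms_err,
        n=n,
        k=k,
    )


def studentized_range_cdf(q: float, k: int, df: float) -> float:
    """CDF of the studentized range of k means with ``df`` error df."""
    if q < 0 or k < 2 or df <= 0:
        raise DomainError(f"invalid studentized-range parameters q={q}, k={k}, df={df}")
    if q == 0:
        return 0.0
    return float(studentized_range.cdf(q, k, df))


def tukey_hsd(
    within_matrix: np.ndarray | None = None,
    *,
    means: Sequence[float] | None = None,
    labels: Sequence[str] | None = None,
    ms_err: float | None = None,
    df_err: float | None = None,
    n_per_group: int | None = None,
    alpha: float = 0.05,
) -> list[PosthocComparison]:
    """Tukey HSD pairwise comparisons of k condition means.

    Either pass the repeated-measures matrix (the within-subject error MS
    and its uncorrected df are used, the standard pairing with the fitted
    model), or pass ``means``/``ms_err``/``df_err``/``n_per_group``
    explicitly. q = |m_a − m_b|/√(MS_err/n); p from the studentized-range
    distribution with k groups.
    """
    if within_matrix is not None:
        X = np.asarray(within_matrix, dtype=float)
        n, k = X.shape
        if k < 2:
            raise InsufficientDataError("need at least 2 conditions")
        _, _, ss_error = _within_decomposition(X)
        df_err = float((k - 1) * (n - 1))
        ms_err = ss_error / df_err
        means = X.mean(axis=0)
        n_per_group = n
    if means is None or ms_err is None or df_err is None or n_per_group is None:
        raise DomainError("need a matrix or explicit means/ms_err/df_err/n_per_group")
    means = np.asarray(means, dtype=float)
    k = means.size
    if k < 2:
        raise InsufficientDataError("need at least 2 groups")
    if labels is None:
        labels = [str(i) for i in range(k)]
    se = sqrt(ms_err / n_per_group)
    out = []
    for a in range(k):
        for b in range(a + 1, k):
            diff = float(means[a] - means[b])
            q = abs(diff) / se if se > 0 else (0.0 if diff == 0.0 else np.inf)
            p = 1.0 - studentized_range_cdf(min(q, 1e8), k, df_err) if np.isfinite(q) else 0.0
            out.append(
                PosthocComparison(
                    pair=(labels[a], labels[b]),
                    mean_diff=diff,
                    q_stat=float(q),
                    p_adjusted=float(p),
                    significant=bool(p < alpha),
                )
            )
    return out


def mixed_design_anova(
    within_matrix: np.ndarray,
    groups: Sequence[object],
    alpha_sphericity: float = 0.05,
) -> MixedAnovaResult:
    """Split-plot ANOVA: one between-subjects factor, one within factor.

    ``within_matrix`` is n x k (every subject measured under all k
    conditions); ``groups`` labels each row (e.g. young/elderly). The
    between effect is tested against the subjects-within-groups MS; the
    within effect and the interaction against the condition-by-subject
    error MS, with GG-corrected dfs when sphericity fails. Sphericity is
    assessed on the pooled within-group covariance (group means removed
    per condition).
    """
    X = np.asarray(within_matrix, dtype=float)
    groups = np.asarray(groups)
    n, k = X.shape
    if groups.shape != (n,):
        raise DomainError("groups must label each row of within_matrix")
    labels, idx = np.unique(groups, return_inverse=True)
    g = labels.size
    if g < 2:
        raise InsufficientDataError("need at least 2 groups")
    counts = np.bincount(idx)
    if counts.min() < 2:
        raise InsufficientDataError("every group needs at least 2 subjects")
    if not np.all(np.isfinite(X)):
        raise InsufficientDataError("incomplete within-subject matrix (no imputation)")

    grand = X.mean()
    subj_means = X.mean(axis=1)
    cond_means = X.mean(axis=0)
    group_means = np.array([subj_means[idx == j].mean() for j in range(g)])
    cell_means = np.array([X[idx == j].mean(axis=0) for j in range(g)])  # g x k

    ss_between = k * float((counts * (group_means - grand) ** 2).sum())
    ss_subj_within = k * float(((subj_means - group_means[idx]) ** 2).sum())
    ss_cond = n * float(((cond_means - grand) ** 2).sum())
    ss_inter = float(
        (
            counts[:, None]
            * (cell_means - group_means[:, None] - cond_means[None, :] + grand) ** 2
        ).sum()
    )
    ss_total = float(((X - grand) ** 2).sum())
    ss_error = max(ss_total - ss_between - ss_subj_within - ss_cond - ss_inter, 0.0)

    df_between = float(g - 1)
    df_subj = float(n - g)
    df_cond = float(k - 1)
    df_inter = float((g - 1) * (k - 1))
    df_err = float((n - g) * (k - 1))

    ms_between = ss_between / df_between
    ms_subj = ss_subj_within / df_subj
    ms_cond = ss_cond / df_cond
    ms_inter = ss_inter / df_inter
    ms_err = ss_error / df_err

    resid = X - cell_means[idx]  # remove group-by-condition means
    if k > 2 and n - g > k:
        sphericity = mauchly_test(resid + cond_means)  # restore column structure
        eps = greenhouse_geisser_epsilon(resid)
    else:
        sphericity = AssumptionTestResult(1.0, 1.0, "mauchly", n, 0.0)
        eps = 1.0
    gg_applied = bool(sphericity.p_value < alpha_sphericity and k > 2)
    scale = eps if gg_applied else 1.0

    def _effect(ms_num: float, df_num: float, ms_den: float, df_den: float,
                corrected: bool) -> EffectResult:
        f = ms_num / ms_den if ms_den > 0 else 0.0
        c = scale if corrected else 1.0
        return EffectResult(
            f_stat=float(f),
            df_num=df_num * c,
            df_den=df_den * c,
            p_value=float(stats.f.sf(f, df_num * c, df_den * c)),
        )

    return MixedAnovaResult(
        between=_effect(ms_between, df_between, ms_subj, df_subj, False),
        within=_effect(ms_cond, df_cond, ms_err, df_err, True),
        interaction=_effect(ms_inter, df_inter, ms_err, df_err, True),
        epsilon_gg=eps,
        sphericity=sphericity,
        gg_applied=gg_applied,
    )


# ---------------------------------------------------------------------------
# measurement-error-aware comparisons


def error_aware_comparison(
    mean_a: float,
    mean_b: float,
    diff_summary: DifferenceSummary,
    pair: tuple[str, str] = ("a", "b"),
    significant: bool = False,
) -> ErrorAwareComparison:
    """Is mean_b distinguishable from mean_a given test-retest error?

    The CI_d envelope is centered at mean_a honoring its asymmetry (a
    non-zero mean test-retest difference d̄ shifts the envelope):
    distinguishable iff mean_b falls outside
    [mean_a + ci_low, mean_a + ci_high].
    """
    lo = mean_a + diff_summary.ci_low
    hi = mean_a + diff_summary.ci_high
    return ErrorAwareComparison(
        pair=pair,
        observed_diff=float(mean_b - mean_a),
        error_interval_halfwidth=diff_summary.halfwidth,
        distinguishable=bool(mean_b < lo or mean_b > hi),
        significant=significant,
    )


def detectable_differences(
    anova: RepeatedAnovaResult,
    posthoc: list[PosthocComparison],
    means: dict[str, float],
    diff_summaries: dict[str, DifferenceSummary],
    alpha: float = 0.05,
) -> list[ErrorAwareComparison]:
    """Cross the significance and measurement-error filters for all pairs.

    Returns one comparison per post-hoc pair when the omnibus ANOVA is
    significant (empty list otherwise), each carrying both flags: the
    Tukey significance and whether the mean difference exceeds the CI_d
    envelope of the first member's stratum. A pair counts as a detectable
    difference only when both hold.
    """
    if anova.p_value >= alpha:
        return []
    out = []
    for comp in posthoc:
        a, b = comp.pair
        cmp = error_aware_comparison(
            means[a], means[b], diff_summaries[a], pair=(a, b),
            significant=comp.significant,
        )
        out.append(cmp)
    return out
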