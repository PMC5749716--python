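"""Test-retest repeatability and reliability indexes.

Given paired test/retest measurements of a quantitative metric on the same
subjects, this module computes the standard battery of repeatability
indexes used in rehabilitation and quantitative-imaging research:

* the mean test-retest difference d̄ with its 95% confidence interval
  CI_d = d̄ ± t_{n-1}·SE, SE = SD_d/√n — a CI_d excluding zero flags a
  systematic bias between sessions, and its width bounds the group-level
  measurement error;
* the mean absolute difference |d|, a direct magnitude of measurement
  error;
* the intraclass correlation coefficient from the two-way mixed-effects
  ANOVA (subjects random, sessions fixed), single measures, absolute
  agreement — ICC(A,1) in the McGraw & Wong taxonomy:

      ICC = (MS_R − MS_E) / (MS_R + (k−1)·MS_E + (k/n)·(MS_C − MS_E))

  The session-variance term in the denominator penalizes systematic
  session differences, which is why the absolute-agreement form (rather
  than the consistency form) is the default here;
* the standard error of measurement SEM = SD_pooled·√(1−ICC) and the
  minimal detectable change MDC = 1.96·√2·SEM: the smallest difference
  between two single measurements not attributable to measurement error
  at the 95% level;
* unit-free normalizations: any index as a percentage of the
  between-subject SD (first session), and the coefficient of variation
  CV = 100·SD/mean.

Sample (n−1) SD denominators are used throughout, matching the t-based CI
construction. Negative ICC estimates are reported as computed (their
interpretation is the same as an ICC of zero: no reliability), and the MDC
then uses √(1−ICC) > 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import sqrt

import numpy as np
from scipy import stats

from .cohort import CohortDataset, PairedMeasurements, extract_pairs
from .errors import DegenerateDataError, DomainError, InsufficientDataError

#: literal MDC constant 1.96·√2 (the conventional printed factor, not the
#: exact normal quantile 1.95996...; the difference is < 0.01%)
MDC_FACTOR = 1.96 * sqrt(2.0)


@dataclass
class DifferenceSummary:
    """Mean test-retest difference and its confidence interval."""

    d_mean: float
    d_sd: float
    se: float
    t_quantile: float
    ci_low: float
    ci_high: float
    abs_d_mean: float
    confidence: float
    n: int

    @property
    def systematic_bias(self) -> bool:
        """True iff zero is excluded from CI_d."""
        return not (self.ci_low <= 0.0 <= self.ci_high)

    @property
    def halfwidth(self) -> float:
        return 0.5 * (self.ci_high - self.ci_low)


@dataclass
class ICCResult:
    icc: float
    ms_rows: float
    ms_cols: float
    ms_err: float
    n: int
    k: int
    model: str = "two-way mixed, absolute agreement, single measures"


@dataclass
class MDCResult:
    sd_pooled: float
    sem: float
    mdc: float
    icc_used: float


@dataclass
class ReliabilityRow:
    """One stratum's worth of repeatability indexes (one table row)."""

    metric: str
    roi: str
    level: str
    n: int
    mean_session1: float
    sd_subjects: float
    diff: DifferenceSummary
    icc: ICCResult
    mdc: MDCResult
    mdc_pct_sd: float
    cv_pct: float

    def as_record(self) -> dict:
        return {
            "metric": self.metric,
            "roi": self.roi,
            "level": self.level,
            "n": self.n,
            "mean_s1": self.mean_session1,
            "sd_subjects": self.sd_subjects,
            "d_mean": self.diff.d_mean,
            "ci_low": self.diff.ci_low,
            "ci_high": self.diff.ci_high,
            "abs_d_mean": self.diff.abs_d_mean,
            "icc": self.icc.icc,
            "sd_pooled": self.mdc.sd_pooled,
            "sem": self.mdc.sem,
            "mdc": self.mdc.mdc,
            "mdc_pct_sd": self.mdc_pct_sd,
            "cv_pct": self.cv_pct,
        }


def difference_summary(
    pairs: PairedMeasurements, confidence: float = 0.95
) -> DifferenceSummary:
    """Mean difference d̄ = mean(retest − test) with its t-based CI.

    A zero SD of the differences is legal and yields a degenerate CI of
    width zero.
    """
    if pairs.n < 2:
        raise InsufficientDataError(f"need at least 2 pairs, got {pairs.n}")
    if not 0.0 < confidence < 1.0:
        raise DomainError(f"confidence must be in (0,1), got {confidence}")
    d = pairs.retest_values - pairs.test_values
    n = pairs.n
    d_mean = float(np.mean(d))
    d_sd = float(np.std(d, ddof=1))
    se = d_sd / sqrt(n)
    t_quantile = float(stats.t.ppf(0.5 + confidence / 2.0, n - 1))
    return DifferenceSummary(
        d_mean=d_mean,
        d_sd=d_sd,
        se=se,
        t_quantile=t_quantile,
        ci_low=d_mean - t_quantile * se,
        ci_high=d_mean + t_quantile * se,
        abs_d_mean=float(np.mean(np.abs(d))),
        confidence=confidence,
        n=n,
    )


def _two_way_mean_squares(X: np.ndarray) -> tuple[float, float, float, int, int]:
    """Mean squares of the two-way (subjects x sessions) layout."""
    X = np.asarray(X, dtype=float)
    n, k = X.shape
    grand = X.mean()
    ss_rows = k * float(((X.mean(axis=1) - grand) ** 2).sum())
    ss_cols = n * float(((X.mean(axis=0) - grand) ** 2).sum())
    ss_tot = float(((X - grand) ** 2).sum())
    ss_err = ss_tot - ss_rows - ss_cols
    ms_rows = ss_rows / (n - 1)
    ms_cols = ss_cols / (k - 1)
    ms_err = max(ss_err, 0.0) / ((n - 1) * (k - 1))
    return ms_rows, ms_cols, ms_err, n, k


def icc_two_way_mixed(
    pairs: PairedMeasurements | np.ndarray, agreement: bool = True
) -> ICCResult:
    """Single-measures ICC from the two-way mixed-effects ANOVA.

    Rows are subjects (random), columns are sessions (fixed). The default
    is the absolute-agreement coefficient ICC(A,1); ``agreement=False``
    gives the consistency variant ICC(C,1) for sensitivity checks. Values
    may be negative and are returned unmodified.

    Accepts either a :class:`PairedMeasurements` (k = 2) or an n x k
    matrix with k >= 2 sessions.
    """
    X = pairs.as_matrix() if isinstance(pairs, PairedMeasurements) else np.asarray(pairs, float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise InsufficientDataError(f"need an n>=2 by k>=2 matrix, got shape {X.shape}")
    ms_rows, ms_cols, ms_err, n, k = _two_way_mean_squares(X)
    if ms_rows == 0.0 and ms_cols == 0.0 and ms_err == 0.0:
        raise DegenerateDataError("all values identical: ICC undefined")
    if agreement:
        denom = ms_rows + (k - 1) * ms_err + (k / n) * (ms_cols - ms_err)
        model = "two-way mixed, absolute agreement, single measures"
    else:
        denom = ms_rows + (k - 1) * ms_err
        model = "two-way mixed, consistency, single measures"
    icc = (ms_rows - ms_err) / denom
    return ICCResult(icc=float(icc), ms_rows=ms_rows, ms_cols=ms_cols,
                     ms_err=ms_err, n=n, k=k, model=model)


def sem_and_mdc(all_values: np.ndarray, icc: float) -> MDCResult:
    """SEM and MDC from the pooled test+retest values and an ICC.

    ``all_values`` pools every measurement of both sessions; its sample SD
    (n·k − 1 denominator) is SD_pooled. SEM = SD_pooled·√(1−ICC) and
    MDC = 1.96·√2·SEM. An ICC above 1 is outside the domain; negative ICCs
    are legal and inflate the SEM.
    """
    all_values = np.asarray(all_values, dtype=float).ravel()
    if all_values.size < 4:
        raise InsufficientDataError(
            f"need at least 4 pooled values, got {all_values.size}"
        )
    if icc > 1.0:
        raise DomainError(f"ICC cannot exceed 1, got {icc}")
    sd_pooled = float(np.std(all_values, ddof=1))
    sem = sd_pooled * sqrt(1.0 - icc)
    return MDCResult(sd_pooled=sd_pooled, sem=sem, mdc=MDC_FACTOR * sem, icc_used=icc)


def normalize_by_subject_sd(index_value: float, sd_subjects: float) -> float:
    """Express a repeatability index as % of the between-subject SD.

    This makes indexes with different units (ms vs %) comparable side by
    side: what matters is the measurement error relative to the dispersion
    the metric offers across subjects.
    """
    if sd_subjects <= 0:
        raise DomainError(f"sd_subjects must be positive, got {sd_subjects}")
    return 100.0 * index_value / sd_subjects


def coefficient_of_variation(values: np.ndarray) -> float:
    """CV = 100·SD/mean (sample SD). Unit-free but mean-dependent."""
    values = np.asarray(values, dtype=float).ravel()
    mean = float(np.mean(values))
    if mean == 0.0:
        raise DomainError("CV undefined for zero mean")
    return 100.0 * float(np.std(values, ddof=1)) / mean


def reliability_row(
    pairs: PairedMeasurements, confidence: float = 0.95
) -> ReliabilityRow:
    """All repeatability indexes for one stratum.

    Mean and SD_subjects come from first-session (test) values only, so
    they describe a single scan of the cohort; SD_pooled for the SEM uses
    both sessions.
    """
    diff = difference_summary(pairs, confidence=confidence)
    icc = icc_two_way_mixed(pairs)
    mdc = sem_and_mdc(pairs.as_matrix(), icc.icc)
    mean_s1 = float(np.mean(pairs.test_values))
    sd_subjects = float(np.std(pairs.test_values, ddof=1))
    return ReliabilityRow(
        metric=pairs.metric,
        roi=pairs.roi,
        level=pairs.level,
        n=pairs.n,
        mean_session1=mean_s1,
        sd_subjects=sd_subjects,
        diff=diff,
        icc=icc,
        mdc=mdc,
        mdc_pct_sd=normalize_by_subject_sd(mdc.mdc, sd_subjects),
        cv_pct=coefficient_of_variation(pairs.test_values),
    )


def reliability_table(
    ds: CohortDataset,
    strata: list[tuple[str, str, str]] | None = None,
    confidence: float = 0.95,
) -> list[ReliabilityRow]:
    """One :class:`ReliabilityRow` per stratum.

    ``strata`` defaults to every (metric, roi, level) combination present
    in the dataset, in sorted order.
    """
    if strata is None:
        strata = ds.strata()
    rows = []
    for metric, roi, level in strata:
        pairs = extract_pairs(ds, metric, roi, level)
        rows.append(reliability_row(pairs, confidence=confidence))
    return rows
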