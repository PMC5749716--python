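# Methods

## Measurement model

All analyses assume the additive Gaussian measurement model that underlies
two-way mixed-effects reliability theory. For subject *i* in session *j*:

    y_ij = μ + b_i + s_j + e_ij,   b_i ~ N(0, σ_b²),   e_ij ~ N(0, σ_e²)

with subjects random and sessions fixed (s_j a fixed session bias, zero in
expectation over a well-calibrated scanner). μ absorbs region, vertebral
level and age-group offsets. Repeatability asks how large σ_e (and any
systematic s_j) is; reliability asks how large σ_b is relative to the
total.

## Repeatability indexes

**CI_d.** With paired differences d_i = retest_i − test_i, the interval
d̄ ± t_{n−1;0.975}·SD_d/√n. The t quantile is computed exactly from the
Student distribution (at n = 16 it is 2.1314, conventionally printed as
2.131). Zero outside the interval flags a systematic session bias. The
interval width also bounds the measurement error of a group mean, which is
how the group comparisons below use it.

**ICC(A,1).** From the two-way layout mean squares MS_R (subjects, df
n−1), MS_C (sessions, df k−1), MS_E (residual, df (n−1)(k−1)):

    ICC = (MS_R − MS_E) / (MS_R + (k−1)·MS_E + (k/n)·(MS_C − MS_E))

This is the single-measures absolute-agreement coefficient of the
two-way mixed model. Absolute agreement (not consistency) is the default
because the session term in the denominator penalizes systematic
inter-session shifts — the property wanted of a test-retest index; the
consistency variant `(MS_R − MS_E)/(MS_R + (k−1)MS_E)` is available via
`agreement=False` for sensitivity checks. Negative estimates are returned
unmodified; they are interpreted like zero (no reliability). An
all-identical table has an undefined ICC and raises. The estimator is
algebraically identical to the method-of-moments variance-component ratio
σ̂_b²/(σ̂_b² + σ̂_s² + σ̂_e²), which the tests exploit as a brute-force
oracle.

**SEM and MDC.** SEM = SD_pooled·√(1−ICC), with SD_pooled the sample SD of
all n·k pooled measurements (the alternative — a mean of per-session SDs —
was considered and rejected; pooling matches the ICC's own normalization).
MDC = 1.96·√2·SEM with the constant taken literally as printed convention
rather than the exact quantile 1.95996 (difference < 0.01%). Under the
model SEM estimates σ_e, and a test-retest difference is N(0, 2σ_e²), so
|d| ≤ MDC with 95% probability — verified by simulation. With a negative
ICC, √(1−ICC) > 1 and the MDC inflates accordingly, which is the correct
degenerate behaviour.

**Normalizations.** Any index divided by the between-subject SD of the
*first* session (×100) compares metrics with different units by what
matters: error relative to the dispersion the metric offers. The
coefficient of variation 100·SD/mean is provided for cross-study
comparison but is mean-dependent and therefore not the primary index.
Sample (n−1) SDs are used everywhere, consistent with the t-based CI.
First-session-only means/SDs describe a single scan of the cohort; both
sessions feed only SD_pooled and the ANOVA.

## Sensitivity analyses

**One-way repeated-measures ANOVA** across levels or regions partitions
the within-subject SS into conditions and error; F = MS_cond/MS_err with
df (k−1), (k−1)(n−1). Normality per condition is checked with a
Lilliefors test whose p-value is Monte-Carlo (seeded, default 10⁴ null
samples) since the null distribution of the statistic with estimated
mean/SD has no closed form; failures warn but do not gate. Sphericity is
checked with Mauchly's W (chi-square approximation); when it rejects at
0.05 and k > 2, both F dfs are multiplied by the Box/Greenhouse–Geisser
ε̂ (clipped to [1/(k−1), 1]) before the p-value — exactly the conditional
policy of gating on the Mauchly test, with no Huynh–Feldt fallback. When
the within-subject variability is exactly zero (or n ≤ k) the sphericity
check is undefined and sphericity is taken to hold.

**Tukey HSD** follows a significant omnibus: q = |m_a − m_b|/√(MS_err/n)
against the studentized-range distribution with k groups and the
*uncorrected* within-error df. Pairing the post hoc with the fitted
model's error term is the standard choice; the GG-shrunken df is not fed
to the post hoc. The studentized-range CDF comes from scipy's numerical
integration. With k = 2 the Tukey p collapses exactly to the two-sided t
p-value (q = t√2).

**Mixed-design (split-plot) ANOVA** adds a between-subjects factor (age
group): the group effect is tested against the subjects-within-groups MS;
the condition effect and interaction against the condition-by-subject
error MS, GG-corrected on the same Mauchly gate. ε̂ is estimated from the
pooled within-group covariance (group-by-condition cell means removed),
which differs slightly from implementations that pool across groups
without removing group means; the F statistics agree exactly with
pingouin, the corrected p only through ε̂.

**Measurement-error filter.** Two condition or group means are
*distinguishable* when one falls outside the other's CI_d envelope. The
envelope honors the asymmetry of CI_d: it is [m_a + ci_low, m_a + ci_high],
i.e. centered at m_a + d̄ — a non-zero mean session difference shifts it.
(The simpler |Δ| > halfwidth rule is the special case d̄ = 0; with d̄ ≠ 0
the two disagree, and the shifted form is used.) A pair is *detectable*
only when significant (ANOVA + Tukey) *and* distinguishable; the study
logic reports both flags because significance without distinguishability
is common and is precisely the phenomenon worth flagging. No
multiple-testing correction is applied across metrics or strata — the
analysis reports per-stratum decisions and inherits that convention.

A note on the Greenhouse–Geisser correction: shrinking both dfs raises the
p-value whenever F is well above 1, making the correction conservative in
the significance region; very close to F = 1 it can lower the p slightly.
The property tests assert conservatism for F ≥ 2 only, since the
unrestricted claim is false.

## Power analysis

Exact power of the two-tailed pooled-variance two-sample t-test via the
noncentral t with df n1+n2−2 and noncentrality δ/(σ√(1/n1+1/n2)); Welch
power is out of scope. scipy's noncentral t loses accuracy at extreme
noncentrality, where the power saturates to 1 explicitly. The minimum
detectable difference at a target power inverts the power function by
bracketing and Brent's method; the required sample size is the smallest
total N at the given allocation ratio (equal by default) reaching the
target, found by a doubling bracket plus bisection over integers. "Sample
size" is reported as TOTAL N by default with a `per_group` option: the two
readings differ by a factor ≈ 2 and published tables do not always say
which they print, so both are exposed.

## Synthetic cohorts

The generator emits the exact model above, per stratum: value =
grand_mean + level/ROI offset + age_effect·1[elderly] + b_i +
session_bias·1[session>1] + e_ij. Defaults describe a healthy-adult
cervical-cord qMRI cohort at 3T: per-metric whole-WM grand means and
between-subject SDs (T1 1011.2 ± 60.8 ms, MTR 45.82 ± 1.30%, MTsat
3.517 ± 0.177%, MTV 36.79 ± 2.30%), with the SD split into σ_b/σ_e by the
whole-WM reliability typical of each metric (ICC 0.74, 0.28, 0.60, 0.60
respectively), realistic level and sub-region offsets, zero session bias,
small elderly shifts (e.g. +3.6 ms T1), and a test-retest design of
8 young + 8 elderly subjects scanned twice. These defaults were chosen
once as the study conditions for all recovery experiments.

Ground truth: consistency ICC = σ_b²/(σ_b²+σ_e²); the absolute-agreement
ICC adds the fixed-session variance term θ² = Σ(session deviations)²/(k−1)
= bias²/k for the bias-after-first-session convention (bias²/2 at k = 2).
By default each (subject, metric, ROI, level) stratum draws an independent
b_i; `shared_subject_effect=True` shares one standardized subject effect
across a metric's strata, for users who want cross-strata correlation (no
claims are tested about it).

What the generator does *not* emulate: image-level artifacts (motion,
susceptibility), heavy-tailed or skewed errors, level-to-level error
correlation within a scan, or the distinction between same-session and
long-interval retests. Passing recovery tests therefore demonstrate
correctness of the estimators under the Gaussian model, not robustness of
the indexes on real scanner data.

## Numerical choices and problem sizes

* Lilliefors Monte-Carlo p with 10⁴ null replicates by default; suite
  checks use 500–2000 replicates at n ≤ 500.
* Type-I-error suites use 2000 replicates (MC SE ≈ 0.5 percentage points
  at the 5% level); estimator-recovery runs 1000 replicates at n = 16.
* MDC coverage is calibrated on a 10⁴-subject cohort and evaluated on
  2·10⁴ fresh differences.
* Monte-Carlo power cross-checks use 10⁵ replicates per grid point.
* Ties/degenerate inputs: zero SD_d gives a legal width-zero CI; an
  all-identical two-way table raises (undefined ICC); a constant vector
  raises in the normality test; incomplete within-subject matrices raise
  rather than impute; complete-case pairing per stratum with a warning per
  excluded subject.

## Known limitations

* The ANOVA layer covers balanced complete designs only; unbalanced
  within-factors or missing cells need a mixed-effects model, which is out
  of scope.
* Mauchly's p uses the first-order chi-square approximation (adequate for
  the gating role it plays; exact small-sample p-values differ in the
  third decimal).
* The MDC's 95% semantics inherit the normality assumption; heavy-tailed
  errors would under-cover.
* Bland–Altman limits of agreement are recoverable from the difference
  summary but not drawn; no figures are produced.
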