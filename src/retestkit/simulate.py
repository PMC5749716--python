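"""Synthetic test-retest cohorts with known variance components.

Every measurement is generated from the additive Gaussian model that the
two-way mixed-effects reliability analysis assumes:

    value_ij = grand_mean + level/roi offset + age_effect·1[elderly]
               + b_i + session_bias·1[session j > 0] + e_ij

with subject effects b_i ~ N(0, σ_b²) and measurement errors
e_ij ~ N(0, σ_e²). Because the ground truth is known, every pipeline
stage can be checked: the population consistency ICC is
σ_b²/(σ_b² + σ_e²), the absolute-agreement ICC adds the fixed-session
variance term θ² = bias²/k to the denominator, SEM → σ_e, and CI_d is a
t-interval for the session bias.

Default parameters emulate a healthy-adult cervical spinal-cord qMRI
cohort: per-metric grand means, between-subject SDs and reliability in
the whole white matter typical of 3T myelin imaging (T1 ≈ 1011 ms,
MTR ≈ 45.8%, MTsat ≈ 3.52%, MTV ≈ 36.8%), with level and sub-region
offsets of realistic magnitude, a zero session bias, and small
age-group shifts. The study design defaults are a test-retest subcohort
of 8 young + 8 elderly subjects scanned twice.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from math import sqrt
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import COLUMNS, CohortDataset
from .errors import DomainError
from .reliability import reliability_table

#: per-metric (grand_mean, total between-subject SD, reliability) in the
#: whole WM used to derive default variance components
_WM_DEFAULTS = {
    "T1": (1011.2, 60.8, 0.74),
    "MTR": (45.82, 1.30, 0.28),
    "MTsat": (3.517, 0.177, 0.60),
    "MTV": (36.79, 2.30, 0.60),
}

#: elderly-minus-young mean shifts (whole WM)
_AGE_EFFECTS = {"T1": 3.6, "MTR": -0.70, "MTsat": 0.092, "MTV": -0.01}

DEFAULT_LEVEL_OFFSETS = {
    "T1": {"C2": -46.3, "C3": -4.0, "C4": 48.8, "C5": 72.4, "pooled": 0.0},
    "MTR": {"C2": 1.01, "C3": -0.04, "C4": -0.95, "C5": -1.80, "pooled": 0.0},
    "MTsat": {"C2": 0.062, "C3": -0.025, "C4": -0.027, "C5": 0.045, "pooled": 0.0},
    "MTV": {"C2": 0.57, "C3": 0.05, "C4": -0.54, "C5": -0.87, "pooled": 0.0},
}

DEFAULT_ROI_OFFSETS = {
    "T1": {"WM": 0.0, "DC": 57.1, "LF": -39.6, "VF": -4.4},
    "MTR": {"WM": 0.0, "DC": 0.26, "LF": 0.27, "VF": -1.18},
    "MTsat": {"WM": 0.0, "DC": -0.065, "LF": 0.073, "VF": -0.079},
    "MTV": {"WM": 0.0, "DC": -0.33, "LF": 0.09, "VF": 0.38},
}


@dataclass
class MetricParams:
    """Variance components and fixed effects for one metric."""

    grand_mean: float
    sigma_between: float
    sigma_error: float
    session_bias: float = 0.0
    age_effect: float = 0.0  # elderly minus young


def _default_metrics() -> dict[str, MetricParams]:
    out = {}
    for metric, (mean, sd, icc) in _WM_DEFAULTS.items():
        out[metric] = MetricParams(
            grand_mean=mean,
            sigma_between=sd * sqrt(icc),
            sigma_error=sd * sqrt(1.0 - icc),
            session_bias=0.0,
            age_effect=_AGE_EFFECTS[metric],
        )
    return out


@dataclass
class SyntheticCohortConfig:
    """Full description of a synthetic cohort.

    The default strata mirror the two analysis families: the whole WM at
    each vertebral level C2-C5, and each WM sub-region at the pooled
    (C2-C4 averaged) level.
    """

    n_young: int = 8
    n_elderly: int = 8
    k_sessions: int = 2
    metrics: dict[str, MetricParams] = field(default_factory=_default_metrics)
    level_offsets: dict[str, dict[str, float]] = field(
        default_factory=lambda: {m: dict(v) for m, v in DEFAULT_LEVEL_OFFSETS.items()}
    )
    roi_offsets: dict[str, dict[str, float]] = field(
        default_factory=lambda: {m: dict(v) for m, v in DEFAULT_ROI_OFFSETS.items()}
    )
    levels: tuple[str, ...] = ("C2", "C3", "C4", "C5")
    rois: tuple[str, ...] = ("WM", "DC", "LF", "VF")
    #: one independent subject effect per stratum (default); if True, a
    #: single standard-normal per subject is shared across strata of a
    #: metric (scaled by each stratum's sigma_between)
    shared_subject_effect: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for metric, p in self.metrics.items():
            if p.sigma_between < 0 or p.sigma_error < 0:
                raise DomainError(f"{metric}: negative SD component")
        if self.n_young < 0 or self.n_elderly < 0 or self.n_young + self.n_elderly < 2:
            raise DomainError("need at least 2 subjects in total")
        if self.k_sessions < 1:
            raise DomainError("need at least 1 session")

    def strata(self) -> list[tuple[str, str, str]]:
        """(metric, roi, level) combinations the generator emits."""
        out = []
        for metric in self.metrics:
            for level in self.levels:
                out.append((metric, "WM", level))
            for roi in self.rois:
                out.append((metric, roi, "pooled"))
        return sorted(set(out))

    # -- flat JSON config round-trip -------------------------------------
    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticCohortConfig":
        raw = json.loads(Path(path).read_text())
        if "metrics" in raw:
            raw["metrics"] = {m: MetricParams(**p) for m, p in raw["metrics"].items()}
        for key in ("levels", "rois"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def single_stratum_config(
    sigma_between: float,
    sigma_error: float,
    grand_mean: float = 100.0,
    session_bias: float = 0.0,
    age_effect: float = 0.0,
    n_young: int = 8,
    n_elderly: int = 8,
    k_sessions: int = 2,
    metric: str = "MTR",
    seed: int = 0,
) -> SyntheticCohortConfig:
    """A minimal one-stratum (metric/WM/pooled) config for experiments."""
    return SyntheticCohortConfig(
        n_young=n_young,
        n_elderly=n_elderly,
        k_sessions=k_sessions,
        metrics={
            metric: MetricParams(
                grand_mean=grand_mean,
                sigma_between=sigma_between,
                sigma_error=sigma_error,
                session_bias=session_bias,
                age_effect=age_effect,
            )
        },
        level_offsets={metric: {"pooled": 0.0}},
        roi_offsets={metric: {"WM": 0.0}},
        levels=(),
        rois=("WM",),
        seed=seed,
    )


@dataclass
class RecoveryReport:
    """Estimator-recovery summary over repeated simulations."""

    true_icc: float
    mean_estimated_icc: float
    bias: float
    rmse: float
    coverage_ci_d: float
    n_reps: int


_SESSION_NAMES = ("test", "retest")


def simulate_cohort(
    cfg: SyntheticCohortConfig, seed: int | None = None, cohort_label: str = "synthetic"
) -> CohortDataset:
    """Draw one cohort dataset from the config's generative model.

    Deterministic given the seed (``cfg.seed`` unless overridden). With
    more than two sessions the extra sessions are labelled
    ``retest2, retest3, ...``; the session bias applies to every session
    after the first.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    n = cfg.n_young + cfg.n_elderly
    width = max(3, len(str(n)))
    subjects = np.array([f"sub-{i:0{width}d}" for i in range(n)])
    age = np.array(["young"] * cfg.n_young + ["elderly"] * cfg.n_elderly)
    elderly = (age == "elderly").astype(float)
    sessions = [
        _SESSION_NAMES[j] if j < 2 else f"retest{j}" for j in range(cfg.k_sessions)
    ]

    shared = {m: rng.standard_normal(n) for m in cfg.metrics} if cfg.shared_subject_effect else None

    frames = []
    for metric, roi, level in cfg.strata():
        p = cfg.metrics[metric]
        offset = (
            cfg.level_offsets.get(metric, {}).get(level, 0.0)
            + cfg.roi_offsets.get(metric, {}).get(roi, 0.0)
        )
        if shared is not None:
            b = p.sigma_between * shared[metric]
        else:
            b = p.sigma_between * rng.standard_normal(n)
        base = p.grand_mean + offset + p.age_effect * elderly + b
        for j, session in enumerate(sessions):
            e = p.sigma_error * rng.standard_normal(n)
            values = base + (p.session_bias if j > 0 else 0.0) + e
            frames.append(
                pd.DataFrame(
                    {
                        "subject_id": subjects,
                        "session": session,
                        "age_group": age,
                        "metric": metric,
                        "roi": roi,
                        "level": level,
                        "value": values,
                    }
                )
            )
    frame = pd.concat(frames, ignore_index=True)[list(COLUMNS)]
    return CohortDataset(frame, cohort_label=cohort_label)


def true_icc(cfg: SyntheticCohortConfig, metric: str | None = None) -> dict[str, float]:
    """Population ICCs implied by the config's variance components.

    ``consistency`` = σ_b²/(σ_b² + σ_e²). ``absolute`` adds the fixed
    session-effect variance term θ² = Σ(session deviations)²/(k−1) to the
    denominator; with the bias applied to every session after the first
    this is bias²/k (bias²/2 for the test-retest design).
    """
    if metric is None:
        metric = next(iter(cfg.metrics))
    p = cfg.metrics[metric]
    vb, ve = p.sigma_between**2, p.sigma_error**2
    if vb == 0.0 and ve == 0.0:
        raise DomainError("both variance components are zero")
    k = cfg.k_sessions
    theta2 = p.session_bias**2 / k if k > 1 else 0.0
    return {
        "consistency": vb / (vb + ve) if vb + ve > 0 else 0.0,
        "absolute": vb / (vb + ve + theta2),
    }


def recovery_experiment(
    cfg: SyntheticCohortConfig,
    n_reps: int = 1000,
    seed: int = 0,
    stratum: tuple[str, str, str] | None = None,
    icc_type: str = "consistency",
) -> RecoveryReport:
    """Bias/RMSE of the ICC estimator and coverage of CI_d over replicates.

    Each replicate simulates a fresh cohort, runs the reliability table on
    one stratum, and records the ICC estimate and whether CI_d covered the
    true session bias. ``icc_type`` selects which population value (and
    matching estimator) is tracked.
    """
    if n_reps < 2:
        raise DomainError("need at least 2 replicates")
    if icc_type not in ("consistency", "absolute"):
        raise DomainError(f"unknown icc_type {icc_type!r}")
    if stratum is None:
        stratum = cfg.strata()[0]
    metric = stratum[0]
    truth = true_icc(cfg, metric)[icc_type]
    bias_true = cfg.metrics[metric].session_bias

    rng = np.random.default_rng(seed)
    estimates = np.empty(n_reps)
    covered = np.empty(n_reps, dtype=bool)
    from .reliability import icc_two_way_mixed  # local to avoid cycle at import

    for r in range(n_reps):
        ds = simulate_cohort(cfg, seed=int(rng.integers(2**31)))
        row = reliability_table(ds, [stratum])[0]
        if icc_type == "absolute":
            estimates[r] = row.icc.icc
        else:
            from .cohort import extract_pairs

            pairs = extract_pairs(ds, *stratum)
            estimates[r] = icc_two_way_mixed(pairs, agreement=False).icc
        covered[r] = row.diff.ci_low <= bias_true <= row.diff.ci_high

    mean_icc = float(estimates.mean())
    bias = mean_icc - truth
    rmse = float(np.sqrt(((estimates - truth) ** 2).mean()))
    return RecoveryReport(
        true_icc=truth,
        mean_estimated_icc=mean_icc,
        bias=bias,
        rmse=rmse,
        coverage_ci_d=float(covered.mean()),
        n_reps=n_reps,
    )
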