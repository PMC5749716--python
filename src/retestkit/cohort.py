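"""Cohort data model and I/O.

Long-format test-retest tables of quantitative MRI metric values: one row
per (subject, session, metric, region, vertebral level). The four metrics
are myelin-sensitive quantities measured in spinal-cord white matter —
T1 (longitudinal relaxation time, ms), MTR (magnetization transfer ratio,
%), MTsat (MT saturation, %) and MTV (macromolecular tissue volume, %) —
quantified either in the whole white matter (WM) or in its sub-regions
(dorsal column DC, lateral funiculi LF, ventral funiculi VF) at cervical
levels C2-C5, or already pooled across levels (level "pooled").

The schema is deliberately tidy/long: a single unambiguous layout instead
of the wide per-metric spreadsheet tabs such data often ships in.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import CohortFormatError, InsufficientDataError

logger = logging.getLogger(__name__)

SESSIONS = ("test", "retest")
AGE_GROUPS = ("young", "elderly")
METRICS = ("T1", "MTR", "MTsat", "MTV")
ROIS = ("WM", "DC", "LF", "VF")
LEVELS = ("C2", "C3", "C4", "C5", "pooled")

#: canonical column order of a cohort table
COLUMNS = ("subject_id", "session", "age_group", "metric", "roi", "level", "value")

#: unique key of a measurement record within a dataset
KEY_COLUMNS = ("subject_id", "session", "metric", "roi", "level")

_CANONICAL = {
    "session": {s.lower(): s for s in SESSIONS},
    "age_group": {s.lower(): s for s in AGE_GROUPS},
    "metric": {s.lower(): s for s in METRICS},
    "roi": {s.lower(): s for s in ROIS},
    "level": {s.lower(): s for s in LEVELS},
}


@dataclass
class CohortDataset:
    """A validated-on-demand collection of measurement records.

    Parameters
    ----------
    frame
        Long-format table with the columns in :data:`COLUMNS`.
    cohort_label
        Free-text label, e.g. ``"retest_n16"`` or ``"full_n33"``.
    """

    frame: pd.DataFrame
    cohort_label: str = ""

    @property
    def n_records(self) -> int:
        return len(self.frame)

    @property
    def subjects(self) -> list[str]:
        return sorted(self.frame["subject_id"].unique())

    def strata(self) -> list[tuple[str, str, str]]:
        """Distinct (metric, roi, level) combinations present."""
        cols = ["metric", "roi", "level"]
        return sorted(map(tuple, self.frame[cols].drop_duplicates().to_numpy()))


@dataclass
class PairedMeasurements:
    """Aligned test/retest vectors for one (metric, roi, level) stratum.

    ``test_values[i]`` and ``retest_values[i]`` belong to ``subject_ids[i]``;
    subjects are ordered lexicographically by id.
    """

    subject_ids: list[str]
    test_values: np.ndarray
    retest_values: np.ndarray
    metric: str = ""
    roi: str = ""
    level: str = ""

    @property
    def n(self) -> int:
        return len(self.subject_ids)

    def as_matrix(self) -> np.ndarray:
        """n x 2 matrix, columns = (test, retest)."""
        return np.column_stack([self.test_values, self.retest_values])


@dataclass
class ValidationReport:
    n_records: int
    n_subjects: int
    strata_present: list[tuple[str, str, str]]
    problems: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.problems


def _normalize_enums(frame: pd.DataFrame, source: str) -> pd.DataFrame:
    frame = frame.copy()
    for col, mapping in _CANONICAL.items():
        lowered = frame[col].astype(str).str.strip().str.lower()
        bad = ~lowered.isin(mapping)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise CohortFormatError(
                f"{source}: unparseable {col} value {frame[col].iloc[row]!r} "
                f"in data row {row + 1}"
            )
        frame[col] = lowered.map(mapping)
    return frame


def _check_duplicates(frame: pd.DataFrame, source: str) -> None:
    dup = frame.duplicated(subset=list(KEY_COLUMNS), keep=False)
    if dup.any():
        key = tuple(frame.loc[dup, list(KEY_COLUMNS)].iloc[0])
        raise CohortFormatError(f"{source}: duplicate record key {key}")


def read_cohort_table(
    path: str | Path, format: str | None = None, cohort_label: str | None = None
) -> CohortDataset:
    """Read a long-format cohort CSV/TSV.

    The header must name the seven fields ``subject_id, session, age_group,
    metric, roi, level, value``; enum fields are parsed case-insensitively.
    ``format`` may be ``"csv"`` or ``"tsv"``; by default it is inferred from
    the file extension (``.tsv``/``.tab`` -> tab, otherwise comma).
    """
    path = Path(path)
    if format is None:
        format = "tsv" if path.suffix.lower() in (".tsv", ".tab") else "csv"
    if format not in ("csv", "tsv"):
        raise CohortFormatError(f"unknown format {format!r}")
    sep = "\t" if format == "tsv" else ","
    frame = pd.read_csv(path, sep=sep, dtype={"subject_id": str})
    missing = [c for c in COLUMNS if c not in frame.columns]
    if missing:
        raise CohortFormatError(f"{path}: missing column(s) {', '.join(missing)}")
    frame = frame[list(COLUMNS)]
    frame = _normalize_enums(frame, str(path))
    values = pd.to_numeric(frame["value"], errors="coerce")
    bad = values.isna() & frame["value"].notna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise CohortFormatError(
            f"{path}: unparseable value {frame['value'].iloc[row]!r} in data "
            f"row {row + 1}"
        )
    frame["value"] = values.astype(float)
    _check_duplicates(frame, str(path))
    label = cohort_label if cohort_label is not None else path.stem
    return CohortDataset(frame.reset_index(drop=True), cohort_label=label)


def write_cohort_table(ds: CohortDataset, path: str | Path, format: str = "csv") -> None:
    """Write a cohort table; inverse of :func:`read_cohort_table`."""
    sep = "\t" if format == "tsv" else ","
    ds.frame[list(COLUMNS)].to_csv(path, sep=sep, index=False)


def validate_cohort(ds: CohortDataset) -> ValidationReport:
    """Enumerate invariant violations without mutating or raising.

    Checks: non-empty; finite values; positive T1; unique record keys;
    every retest record matched by a test record for the same stratum.
    """
    frame = ds.frame
    problems: list[str] = []
    if len(frame) == 0:
        return ValidationReport(0, 0, [], ["no records"])

    finite = np.isfinite(frame["value"].to_numpy(dtype=float))
    for i in np.flatnonzero(~finite):
        rec = frame.iloc[int(i)]
        problems.append(
            f"non-finite value for subject {rec['subject_id']} "
            f"({rec['metric']}/{rec['roi']}/{rec['level']}, {rec['session']})"
        )
    t1_bad = (frame["metric"] == "T1") & finite & (frame["value"] <= 0)
    for i in np.flatnonzero(t1_bad.to_numpy()):
        rec = frame.iloc[int(i)]
        problems.append(f"non-positive T1 value for subject {rec['subject_id']}")

    dup = frame.duplicated(subset=list(KEY_COLUMNS), keep=False)
    for key in frame.loc[dup, list(KEY_COLUMNS)].drop_duplicates().itertuples(index=False):
        problems.append(f"duplicate record key {tuple(key)}")

    # every retest needs a matching test in the same stratum
    keyed = frame.set_index(["metric", "roi", "level", "subject_id"])
    sessions = frame.groupby(["metric", "roi", "level", "subject_id"])["session"].agg(set)
    for key, ses in sessions.items():
        if "retest" in ses and "test" not in ses:
            problems.append(
                f"subject {key[3]} has a retest but no test record for stratum "
                f"{key[0]}/{key[1]}/{key[2]}"
            )
    del keyed

    return ValidationReport(
        n_records=len(frame),
        n_subjects=frame["subject_id"].nunique(),
        strata_present=ds.strata(),
        problems=problems,
    )


def extract_pairs(
    ds: CohortDataset, metric: str, roi: str, level: str
) -> PairedMeasurements:
    """Aligned test/retest vectors for one stratum (complete cases only).

    Subjects lacking either session are excluded and logged at warning
    level. Raises :class:`InsufficientDataError` with fewer than 2 complete
    pairs.
    """
    sub = ds.frame[
        (ds.frame["metric"] == metric)
        & (ds.frame["roi"] == roi)
        & (ds.frame["level"] == level)
    ]
    wide = sub.pivot_table(
        index="subject_id", columns="session", values="value", aggfunc="first"
    )
    for col in SESSIONS:
        if col not in wide.columns:
            wide[col] = np.nan
    complete = wide[list(SESSIONS)].dropna()
    excluded = sorted(set(wide.index) - set(complete.index))
    for sid in excluded:
        logger.warning(
            "excluding subject %s from %s/%s/%s: missing session", sid, metric, roi, level
        )
    if len(complete) < 2:
        raise InsufficientDataError(
            f"stratum {metric}/{roi}/{level}: {len(complete)} complete pair(s), "
            "need at least 2"
        )
    complete = complete.sort_index()
    return PairedMeasurements(
        subject_ids=list(complete.index),
        test_values=complete["test"].to_numpy(dtype=float),
        retest_values=complete["retest"].to_numpy(dtype=float),
        metric=metric,
        roi=roi,
        level=level,
    )


def within_matrix(
    ds: CohortDataset,
    metric: str,
    conditions: Sequence[str],
    axis: str = "level",
    fixed: str | None = None,
    session: str = "test",
) -> tuple[np.ndarray, list[str], list[str]]:
    """Complete n x k within-subject matrix for a repeated-measures ANOVA.

    ``axis`` names the within factor column ("level" or "roi"); ``fixed``
    pins the other stratification column (defaults: roi="WM" when the axis
    is level, level="pooled" when the axis is roi). Only subjects with all
    k conditions in the chosen session are kept (complete case), sorted by
    id. Returns (matrix, subject_ids, condition_labels).
    """
    if axis not in ("level", "roi"):
        raise CohortFormatError(f"axis must be 'level' or 'roi', got {axis!r}")
    other = "roi" if axis == "level" else "level"
    if fixed is None:
        fixed = "WM" if axis == "level" else "pooled"
    sub = ds.frame[
        (ds.frame["metric"] == metric)
        & (ds.frame["session"] == session)
        & (ds.frame[other] == fixed)
        & (ds.frame[axis].isin(conditions))
    ]
    wide = sub.pivot_table(index="subject_id", columns=axis, values="value", aggfunc="first")
    missing = [c for c in conditions if c not in wide.columns]
    if missing:
        raise InsufficientDataError(
            f"{metric}: no data for {axis}(s) {', '.join(missing)} at {other}={fixed}"
        )
    wide = wide[list(conditions)].dropna().sort_index()
    dropped = sub["subject_id"].nunique() - len(wide)
    if dropped:
        logger.warning(
            "%s/%s: excluded %d subject(s) with incomplete conditions", metric, axis, dropped
        )
    return wide.to_numpy(dtype=float), list(wide.index), list(conditions)


# ---------------------------------------------------------------------------
# report tables

#: printed decimals per metric for means/SDs/MDC (T1 in ms, others in %)
_METRIC_DECIMALS = {"T1": 1, "MTR": 2, "MTsat": 3, "MTV": 2}
#: decimals for unit-free columns
_FIXED_DECIMALS = {"icc": 2, "mdc_pct_sd": 1, "cv_pct": 1, "abs_d_pct_sd": 1}
_METRIC_SCALED = (
    "mean_s1", "sd_subjects", "d_mean", "ci_low", "ci_high", "abs_d_mean",
    "sd_pooled", "sem", "mdc", "sd", "min_diff_80", "observed_diff",
)


def _format_cell(value: object, column: str, metric: str) -> object:
    if not isinstance(value, (int, float, np.floating)) or isinstance(value, bool):
        return value
    if isinstance(value, (int, np.integer)):
        return value
    if column in _FIXED_DECIMALS:
        return round(float(value), _FIXED_DECIMALS[column])
    if column in _METRIC_SCALED and metric in _METRIC_DECIMALS:
        return round(float(value), _METRIC_DECIMALS[metric] + 1)
    return float(value)


def write_report_table(
    rows: Sequence[object] | pd.DataFrame, path: str | Path, format: str = "csv"
) -> None:
    """Write a homogeneous list of report rows as CSV/TSV.

    Rows may be dataclass instances exposing ``as_record()`` (the report-row
    types of this package), plain dicts, or an already-built DataFrame.
    Column order is deterministic (first row wins); numeric cells are
    rounded to the conventional printed precision for their metric.
    """
    if isinstance(rows, pd.DataFrame):
        if rows.empty:
            raise ValueError("empty report")
        frame = rows
    else:
        rows = list(rows)
        if not rows:
            raise ValueError("empty report")
        records = [
            r.as_record() if hasattr(r, "as_record") else dict(r) for r in rows
        ]
        first_keys = list(records[0])
        if any(list(r) != first_keys for r in records):
            raise ValueError("report rows are not homogeneous")
        records = [
            {
                col: _format_cell(val, col, rec.get("metric", ""))
                for col, val in rec.items()
            }
            for rec in records
        ]
        frame = pd.DataFrame.from_records(records, columns=first_keys)
    sep = "\t" if format == "tsv" else ","
    frame.to_csv(path, sep=sep, index=False)


def from_records(records: Iterable[dict], cohort_label: str = "") -> CohortDataset:
    """Build a dataset from an iterable of record dicts (mostly for tests)."""
    frame = pd.DataFrame.from_records(list(records), columns=list(COLUMNS))
    frame["subject_id"] = frame["subject_id"].astype(str)
    frame["value"] = frame["value"].astype(float)
    frame = _normalize_enums(frame, "records")
    _check_duplicates(frame, "records")
    return CohortDataset(frame, cohort_label=cohort_label)
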