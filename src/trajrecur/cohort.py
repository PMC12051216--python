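"""Cohort data model, CSV round-trip, baseline-date imputation, windows.

The time axis is weeks since the date of diabetes diagnosis (DDD);
dates convert to weeks as day-difference / 7 with fractional weeks
kept.  Subjects whose diagnosis year predates their first HbA1c record
get a DDD drawn uniformly over the days of the diagnosis year.
"""

from __future__ import annotations

import datetime as _dt
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

PRIOR_FLAGS = ("cvd", "ihd", "pad", "hs", "is", "tia", "af", "neuropathy", "dpa", "hf")
MED_FLAGS = ("acarbose", "metformin", "sulfonylureas", "dpp4i", "sglt2i")
SEXES = ("male", "female")
ETHNICITIES = ("Chinese", "Malay", "Indian", "Other")

HBA1C_RANGE = (3.0, 25.0)

DAYS_PER_WEEK = 7.0


class SchemaError(ValueError):
    """A required CSV column is missing."""


class CohortValidationError(ValueError):
    """One or more rows violate the cohort invariants."""

    def __init__(self, problems: list[str]):
        self.problems = list(problems)
        super().__init__("cohort validation failed:\n" + "\n".join(self.problems))


class DegenerateWindowError(ValueError):
    """Observation window would be empty (R <= L)."""


@dataclass
class SubjectRecord:
    """Baseline covariates for one subject."""

    subject_id: str
    diagnosis_year: int
    ddd: _dt.date | None = None
    ddd_known: bool = False
    age_at_ddd: float = float("nan")
    sex: str = "female"
    ethnicity: str = "Chinese"
    baseline_hba1c: float | None = None
    prior_flags: dict[str, bool] = field(default_factory=dict)
    medication_flags: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self):
        # normalize to the full flag sets so equality is representation-free
        self.prior_flags = {f: bool(self.prior_flags.get(f, False)) for f in PRIOR_FLAGS}
        self.medication_flags = {
            f: bool(self.medication_flags.get(f, False)) for f in MED_FLAGS
        }

    def validate(self) -> list[str]:
        out = []
        if not (self.age_at_ddd > 0):
            out.append(f"subject {self.subject_id}: age_at_ddd must be > 0")
        if self.sex not in SEXES:
            out.append(f"subject {self.subject_id}: sex {self.sex!r} not in {SEXES}")
        if self.ethnicity not in ETHNICITIES:
            out.append(
                f"subject {self.subject_id}: ethnicity {self.ethnicity!r} "
                f"not in {ETHNICITIES}"
            )
        if self.baseline_hba1c is not None and not (
            HBA1C_RANGE[0] <= self.baseline_hba1c <= HBA1C_RANGE[1]
        ):
            out.append(
                f"subject {self.subject_id}: baseline_hba1c "
                f"{self.baseline_hba1c} outside {HBA1C_RANGE}"
            )
        return out


@dataclass
class MeasurementSeries:
    """One subject's irregular HbA1c observations (weeks since DDD, %)."""

    subject_id: str
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)

    def dedupe(self) -> "MeasurementSeries":
        """Keep the first observation at each duplicated time."""
        _, first = np.unique(self.times, return_index=True)
        if len(first) < len(self.times):
            warnings.warn(
                f"subject {self.subject_id}: dropped "
                f"{len(self.times) - len(first)} duplicate measurement time(s)",
                stacklevel=2,
            )
            return MeasurementSeries(
                self.subject_id, self.times[np.sort(first)], self.values[np.sort(first)]
            )
        return self

    def validate(self) -> list[str]:
        out = []
        sid = self.subject_id
        if len(self.times) != len(self.values):
            out.append(f"subject {sid}: times/values length mismatch")
            return out
        if len(self.times) < 1:
            out.append(f"subject {sid}: empty measurement series")
            return out
        if np.any(self.times < 0):
            out.append(f"subject {sid}: negative measurement time")
        if np.any(np.diff(self.times) <= 0):
            out.append(f"subject {sid}: measurement times not strictly increasing")
        if np.any((self.values < HBA1C_RANGE[0]) | (self.values > HBA1C_RANGE[1])):
            out.append(f"subject {sid}: HbA1c value outside {HBA1C_RANGE}")
        return out

    def __eq__(self, other):
        return (
            isinstance(other, MeasurementSeries)
            and self.subject_id == other.subject_id
            and np.array_equal(self.times, other.times)
            and np.array_equal(self.values, other.values)
        )


@dataclass
class EventWindow:
    """Recurrent-event record: window [L, R] in weeks, events inside it.

    ``x`` is the covariate vector used by the recurrent-event model
    (class indicators plus adjusted risk factors); it may be empty when
    the window is used purely for simulation bookkeeping.
    """

    subject_id: str
    L: float
    R: float
    event_times: np.ndarray
    x: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self):
        self.event_times = np.asarray(self.event_times, dtype=float)
        self.x = np.asarray(self.x, dtype=float)

    def validate(self) -> list[str]:
        out = []
        sid = self.subject_id
        if not (0 <= self.L < self.R):
            out.append(f"subject {sid}: window requires 0 <= L < R, got ({self.L}, {self.R})")
        t = self.event_times
        if len(t) and np.any(np.diff(t) <= 0):
            out.append(f"subject {sid}: event times not strictly increasing")
        if len(t) and (np.any(t <= self.L) or np.any(t > self.R) or np.any(t <= 0)):
            out.append(f"subject {sid}: event time outside (L, R] or not positive")
        return out

    def __eq__(self, other):
        return (
            isinstance(other, EventWindow)
            and self.subject_id == other.subject_id
            and self.L == other.L
            and self.R == other.R
            and np.array_equal(self.event_times, other.event_times)
            and np.array_equal(self.x, other.x)
        )


@dataclass
class Cohort:
    """Validated bundle of subjects, measurement series and event windows."""

    subjects: dict[str, SubjectRecord] = field(default_factory=dict)
    series: dict[str, MeasurementSeries] = field(default_factory=dict)
    windows: dict[str, EventWindow] = field(default_factory=dict)

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def subject_ids(self) -> list[str]:
        return list(self.subjects)

    def validate(self) -> None:
        problems: list[str] = []
        for s in self.subjects.values():
            problems += s.validate()
        for ser in self.series.values():
            problems += ser.validate()
            if ser.subject_id not in self.subjects:
                problems.append(f"series for unknown subject {ser.subject_id}")
        for w in self.windows.values():
            problems += w.validate()
            if w.subject_id not in self.subjects:
                problems.append(f"window for unknown subject {w.subject_id}")
        if problems:
            raise CohortValidationError(problems)

    def __eq__(self, other):
        return (
            isinstance(other, Cohort)
            and self.subjects == other.subjects
            and self.series == other.series
            and self.windows == other.windows
        )


# ---------------------------------------------------------------------------
# CSV schemas

_SUBJECT_COLS = (
    ["subject_id", "diagnosis_year", "ddd", "ddd_known", "age_at_ddd", "sex",
     "ethnicity", "baseline_hba1c"]
    + [f"prior_{f}" for f in PRIOR_FLAGS]
    + [f"med_{f}" for f in MED_FLAGS]
)
_MEASUREMENT_COLS = ["subject_id", "t_weeks", "hba1c"]
_EVENT_COLS = ["subject_id", "L_weeks", "R_weeks", "t_weeks"]


def _require_columns(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def read_cohort(subjects_path, measurements_path, events_path=None) -> Cohort:
    """Read and validate a cohort from its three CSV files.

    ``events_path`` may be None for cohorts without recurrent-event
    records.  Raises :class:`SchemaError` for missing columns and
    :class:`CohortValidationError` with a per-row report for invariant
    violations.
    """
    sdf = pd.read_csv(subjects_path, dtype={"subject_id": str},
                      float_precision="round_trip")
    _require_columns(sdf, _SUBJECT_COLS, subjects_path)
    mdf = pd.read_csv(measurements_path, dtype={"subject_id": str},
                      float_precision="round_trip")
    _require_columns(mdf, _MEASUREMENT_COLS, measurements_path)

    cohort = Cohort()
    for row in sdf.itertuples(index=False):
        ddd = None
        if isinstance(row.ddd, str) and row.ddd:
            ddd = _dt.date.fromisoformat(row.ddd)
        baseline = None if pd.isna(row.baseline_hba1c) else float(row.baseline_hba1c)
        rec = SubjectRecord(
            subject_id=row.subject_id,
            diagnosis_year=int(row.diagnosis_year),
            ddd=ddd,
            ddd_known=bool(row.ddd_known),
            age_at_ddd=float(row.age_at_ddd),
            sex=str(row.sex),
            ethnicity=str(row.ethnicity),
            baseline_hba1c=baseline,
            prior_flags={f: bool(getattr(row, f"prior_{f}")) for f in PRIOR_FLAGS},
            medication_flags={f: bool(getattr(row, f"med_{f}")) for f in MED_FLAGS},
        )
        cohort.subjects[rec.subject_id] = rec

    for sid, grp in mdf.groupby("subject_id", sort=False):
        ser = MeasurementSeries(
            str(sid), grp["t_weeks"].to_numpy(float), grp["hba1c"].to_numpy(float)
        ).dedupe()
        cohort.series[str(sid)] = ser

    if events_path is not None:
        edf = pd.read_csv(events_path, dtype={"subject_id": str},
                          float_precision="round_trip")
        _require_columns(edf, _EVENT_COLS, events_path)
        # optional covariate columns x0..x{p-1} (window-level, repeated per row)
        xcols = sorted(
            (c for c in edf.columns if c.startswith("x") and c[1:].isdigit()),
            key=lambda c: int(c[1:]),
        )
        for sid, grp in edf.groupby("subject_id", sort=False):
            times = grp["t_weeks"].dropna().to_numpy(float)
            x = grp[xcols].iloc[0].to_numpy(float) if xcols else np.zeros(0)
            cohort.windows[str(sid)] = EventWindow(
                str(sid),
                float(grp["L_weeks"].iloc[0]),
                float(grp["R_weeks"].iloc[0]),
                np.sort(times) if len(times) else times,
                x,
            )

    cohort.validate()
    return cohort


def write_cohort(cohort: Cohort, out_dir) -> dict[str, Path]:
    """Write a cohort to subjects/measurements/events CSVs in ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "subjects": out_dir / "subjects.csv",
        "measurements": out_dir / "measurements.csv",
        "events": out_dir / "events.csv",
    }

    srows = []
    for s in cohort.subjects.values():
        row = {
            "subject_id": s.subject_id,
            "diagnosis_year": s.diagnosis_year,
            "ddd": s.ddd.isoformat() if s.ddd else "",
            "ddd_known": int(s.ddd_known),
            "age_at_ddd": s.age_at_ddd,
            "sex": s.sex,
            "ethnicity": s.ethnicity,
            "baseline_hba1c": s.baseline_hba1c,
        }
        for f in PRIOR_FLAGS:
            row[f"prior_{f}"] = int(s.prior_flags.get(f, False))
        for f in MED_FLAGS:
            row[f"med_{f}"] = int(s.medication_flags.get(f, False))
        srows.append(row)
    pd.DataFrame(srows, columns=_SUBJECT_COLS).to_csv(
        paths["subjects"], index=False, float_format="%.17g"
    )

    mrows = []
    for ser in cohort.series.values():
        for t, v in zip(ser.times, ser.values):
            mrows.append({"subject_id": ser.subject_id, "t_weeks": t, "hba1c": v})
    pd.DataFrame(mrows, columns=_MEASUREMENT_COLS).to_csv(
        paths["measurements"], index=False, float_format="%.17g"
    )

    erows = []
    p = max((len(w.x) for w in cohort.windows.values()), default=0)
    ecols = _EVENT_COLS + [f"x{j}" for j in range(p)]
    for w in cohort.windows.values():
        base = {"subject_id": w.subject_id, "L_weeks": w.L, "R_weeks": w.R}
        for j in range(p):
            base[f"x{j}"] = w.x[j] if j < len(w.x) else 0.0
        if len(w.event_times):
            for t in w.event_times:
                erows.append({**base, "t_weeks": t})
        else:
            erows.append({**base, "t_weeks": None})
    pd.DataFrame(erows, columns=ecols).to_csv(
        paths["events"], index=False, float_format="%.17g"
    )
    return paths


# ---------------------------------------------------------------------------
# Baseline-date imputation and observation windows


def impute_ddd(
    diagnosis_year: int,
    first_hba1c_date: _dt.date,
    seed: int | np.random.Generator = 0,
) -> _dt.date:
    """Impute the date of diabetes diagnosis (DDD).

    When the diagnosis year matches the year of the first HbA1c record
    the DDD is taken as that record's date; otherwise it is drawn
    uniformly over the days of the diagnosis year (365 or 366),
    reproducibly under ``seed``.
    """
    if diagnosis_year == first_hba1c_date.year:
        return first_hba1c_date
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    start = _dt.date(diagnosis_year, 1, 1)
    n_days = (_dt.date(diagnosis_year + 1, 1, 1) - start).days
    return start + _dt.timedelta(days=int(rng.integers(n_days)))


def build_observation_window(
    subject_ddd: _dt.date,
    truncation_date: _dt.date,
    followup_end: _dt.date,
) -> tuple[float, float]:
    """Window bounds (L, R) in fractional weeks since DDD.

    The left bound is 0 when the DDD falls after the date from which
    covariates are completely observed (the truncation date), otherwise
    the elapsed weeks between truncation date and DDD; the right bound
    is the elapsed weeks at end of follow-up.
    """
    L = max(0.0, (truncation_date - subject_ddd).days / DAYS_PER_WEEK)
    R = (followup_end - subject_ddd).days / DAYS_PER_WEEK
    if R <= L:
        raise DegenerateWindowError(
            f"window ({L}, {R}) is empty: follow-up ends at or before window start"
        )
    return L, R
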