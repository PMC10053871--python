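"""Patient-level cohort container, I/O, validation and baseline summaries.

A cohort holds one row per hospital admission.  Each patient carries the
baseline covariates measured at admission (age, sex, oxygen saturation,
respiratory rate, serum creatinine, calendar month of admission), the day
on which the study drug was first given (absent if never given), and the
terminal event: in-hospital death or discharge alive.  Days are positive
integers counted from admission, with day 1 the admission calendar day, so
"within two days" means ``treatment_day in {1, 2}``.

Rows with any missing covariate or missing outcome information are dropped
on read (complete-case rule) and counted in ``Cohort.exclusion_log``; no
imputation is performed.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterator, Mapping, Sequence
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

EVENT_DEATH = "death"
EVENT_DISCHARGE = "discharge"
EVENT_TYPES = (EVENT_DEATH, EVENT_DISCHARGE)

#: baseline covariates entering the censoring models, in canonical order
COVARIATE_COLUMNS = ("age", "sex", "spo2", "resp_rate", "creatinine")

CANONICAL_COLUMNS = (
    "patient_id",
    *COVARIATE_COLUMNS,
    "admission_month",
    "treatment_day",
    "event_day",
    "event_type",
)

_SEX_MAP = {"m": 1, "male": 1, "f": 0, "female": 0, "1": 1, "0": 0}


@dataclass(frozen=True)
class PatientRecord:
    """One hospital admission with baseline covariates and terminal outcome."""

    patient_id: object
    age: float
    sex: int
    spo2: float
    resp_rate: float
    creatinine: float
    admission_month: str
    treatment_day: int | None
    event_day: int
    event_type: str


@dataclass(frozen=True)
class Violation:
    """A single invariant violation found by :func:`validate_cohort`."""

    patient_id: object
    rule: str
    message: str


class CohortReadError(RuntimeError):
    """Raised when a cohort file cannot be parsed or fails validation."""


class Cohort:
    """An ordered collection of complete patient records.

    Parameters
    ----------
    df : pandas.DataFrame
        One row per patient, canonical columns (see ``CANONICAL_COLUMNS``).
    exclusion_log : dict, optional
        Counts of input rows dropped per reason during reading.
    """

    def __init__(self, df: pd.DataFrame, exclusion_log: Mapping[str, int] | None = None):
        missing = [c for c in CANONICAL_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"cohort frame is missing columns: {missing}")
        df = df.loc[:, list(CANONICAL_COLUMNS)].reset_index(drop=True).copy()
        df["treatment_day"] = pd.to_numeric(df["treatment_day"], errors="coerce").astype(float)
        df["event_day"] = pd.to_numeric(df["event_day"], errors="raise").astype(np.int64)
        for col in ("age", "spo2", "resp_rate", "creatinine"):
            df[col] = pd.to_numeric(df[col], errors="raise").astype(float)
        df["sex"] = _coerce_sex(df["sex"])
        df["event_type"] = df["event_type"].astype(str).str.lower()
        df["admission_month"] = df["admission_month"].astype(str)
        self.df = df
        self.exclusion_log: dict[str, int] = dict(exclusion_log or {})

    def __len__(self) -> int:
        return len(self.df)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Cohort(n={len(self)}, excluded={sum(self.exclusion_log.values())})"

    @property
    def records(self) -> Iterator[PatientRecord]:
        for row in self.df.itertuples(index=False):
            t = row.treatment_day
            yield PatientRecord(
                patient_id=row.patient_id,
                age=row.age,
                sex=int(row.sex),
                spo2=row.spo2,
                resp_rate=row.resp_rate,
                creatinine=row.creatinine,
                admission_month=row.admission_month,
                treatment_day=None if pd.isna(t) else int(t),
                event_day=int(row.event_day),
                event_type=row.event_type,
            )

    def take(self, indices: Sequence[int], reassign_ids: bool = False) -> "Cohort":
        """Positional subset (with repeats allowed), e.g. a bootstrap resample.

        With ``reassign_ids`` each drawn row becomes a distinct pseudo-patient,
        which keeps the per-patient cloning bookkeeping valid under
        resampling with replacement.
        """
        sub = self.df.iloc[np.asarray(indices)].reset_index(drop=True)
        if reassign_ids:
            sub = sub.copy()
            sub["patient_id"] = np.arange(len(sub))
        return Cohort(sub)


def _coerce_sex(s: pd.Series) -> pd.Series:
    if s.dtype.kind in "ifub":
        vals = pd.to_numeric(s).astype(np.int64)
    else:
        vals = s.astype(str).str.strip().str.lower().map(_SEX_MAP)
        if vals.isna().any():
            bad = sorted(set(s[vals.isna()].astype(str)))
            raise ValueError(f"unrecognised sex codes: {bad}")
        vals = vals.astype(np.int64)
    if not vals.isin([0, 1]).all():
        raise ValueError("sex must be binary (0/1 or male/female)")
    return vals


def read_cohort(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    delimiter: str = ",",
) -> Cohort:
    """Read a delimited cohort file, applying the complete-case rule.

    ``schema`` maps canonical names to the file's column names, e.g.
    ``{"spo2": "oxygen_saturation"}``; unmapped canonical names are looked
    up verbatim.  Rows missing any covariate, the event day or the event
    type are excluded and counted in the returned ``exclusion_log``; rows
    that parse but violate a record invariant raise :class:`CohortReadError`.
    """
    path = Path(path)
    if not path.exists():
        raise CohortReadError(f"cohort file not found: {path}")
    try:
        raw = pd.read_csv(path, sep=delimiter)
    except Exception as exc:  # noqa: BLE001 - wrap any parser failure
        raise CohortReadError(f"could not parse {path}: {exc}") from exc

    schema = dict(schema or {})
    rename = {schema.get(c, c): c for c in CANONICAL_COLUMNS}
    missing = [src for src in rename if src not in raw.columns]
    if missing:
        raise CohortReadError(f"mapped columns absent from {path.name}: {missing}")
    df = raw.rename(columns=rename)

    df, log = _apply_complete_case(df)
    cohort = Cohort(df, exclusion_log=log)
    violations = validate_cohort(cohort)
    if violations:
        v = violations[0]
        raise CohortReadError(
            f"{len(violations)} invalid record(s); first: patient {v.patient_id!r}: {v.message}"
        )
    return cohort


def _apply_complete_case(df: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Drop incomplete rows, counting one reason per row (event fields first)."""
    checks = (
        ("missing_event_day", ["event_day"]),
        ("missing_event_type", ["event_type"]),
        ("missing_covariate", list(COVARIATE_COLUMNS) + ["admission_month"]),
    )
    log: dict[str, int] = {}
    keep = pd.Series(True, index=df.index)
    assigned = pd.Series(False, index=df.index)
    for reason, cols in checks:
        bad = df[cols].isna().any(axis=1) & ~assigned
        if bad.any():
            log[reason] = int(bad.sum())
            keep &= ~bad
            assigned |= bad
    return df[keep], log


def write_cohort(cohort: Cohort, path: str | Path, delimiter: str = ",") -> None:
    """Write a cohort back out in the canonical delimited layout."""
    out = cohort.df.copy()
    out["treatment_day"] = out["treatment_day"].astype("Int64")
    out.to_csv(path, sep=delimiter, index=False)


def validate_cohort(cohort: Cohort) -> list[Violation]:
    """Check every record invariant; violations are returned, never raised."""
    df = cohort.df
    out: list[Violation] = []

    dup = df["patient_id"][df["patient_id"].duplicated(keep=False)]
    for pid in dup.unique():
        out.append(Violation(pid, "unique_patient_id", f"patient_id {pid!r} appears more than once"))

    def flag(mask: pd.Series, rule: str, msg: str) -> None:
        for pid in df.loc[mask, "patient_id"]:
            out.append(Violation(pid, rule, msg))

    flag(df["event_day"] < 1, "event_day_positive", "event_day must be >= 1")
    t = df["treatment_day"]
    has_t = t.notna()
    flag(has_t & (t < 1), "treatment_day_positive", "treatment_day must be >= 1 when present")
    flag(has_t & (t > df["event_day"]), "treatment_before_event",
         "treatment_day must not exceed event_day")
    flag(~df["event_type"].isin(EVENT_TYPES), "event_type_known",
         f"event_type must be one of {EVENT_TYPES}")
    flag((df["spo2"] < 0) | (df["spo2"] > 100), "spo2_range", "spo2 must lie in [0, 100]")
    flag(df["age"] < 0, "age_nonnegative", "age must be nonnegative")
    flag(df["resp_rate"] <= 0, "resp_rate_positive", "respiratory rate must be positive")
    flag(df["creatinine"] <= 0, "creatinine_positive", "creatinine must be positive")
    return out


def baseline_table(cohort: Cohort | pd.DataFrame) -> pd.DataFrame:
    """Per-covariate baseline summary: count, mean (or proportion), sd.

    Numeric covariates get mean and standard deviation; sex is summarised as
    the proportion coded 1; admission months get one row per level whose
    counts sum to the cohort size.
    """
    df = cohort.df if isinstance(cohort, Cohort) else cohort
    if len(df) == 0:
        raise ValueError("cannot summarise an empty cohort")
    rows = []
    for col in ("age", "spo2", "resp_rate", "creatinine"):
        rows.append({"covariate": col, "count": len(df),
                     "mean": float(df[col].mean()), "sd": float(df[col].std(ddof=1))})
    rows.append({"covariate": "sex", "count": len(df),
                 "mean": float(df["sex"].mean()), "sd": float("nan")})
    month_counts = df["admission_month"].value_counts().sort_index()
    for level, cnt in month_counts.items():
        rows.append({"covariate": f"admission_month[{level}]", "count": int(cnt),
                     "mean": float(cnt / len(df)), "sd": float("nan")})
    return pd.DataFrame(rows, columns=["covariate", "count", "mean", "sd"])


def record_to_frame(records: Sequence[PatientRecord]) -> pd.DataFrame:
    """Build a canonical cohort frame from a list of records (test helper)."""
    return pd.DataFrame([dataclasses.asdict(r) for r in records], columns=CANONICAL_COLUMNS)
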