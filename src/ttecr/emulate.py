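"""Cloning and grace-period artificial censoring.

Each patient is duplicated into both strategy arms at admission ("treat
within the grace period" vs "do not treat within the grace period"), so the
arms are identical at baseline by construction.  A clone is then
artificially censored the moment its patient's observed data deviate from
the arm's strategy:

* treated within the grace period (day ``t <= g``): the untreated-arm clone
  is censored at day ``t``; the treated-arm clone keeps the outcome;
* not treated by day ``g`` (never, or later than ``g``): the treated-arm
  clone is censored at day ``g``; the untreated-arm clone keeps the outcome
  (late initiators count as untreated throughout, with no extra censoring);
* a terminal event on day ``e <= g`` before any treatment is kept by both
  clones — early deaths and discharges contribute person-time and events to
  both arms.

Tie-break: a treatment recorded on the same day as the event is deemed to
precede it (a drug administration implies the patient was still in
hospital), so the untreated-arm clone is censored rather than keeping the
event.  Follow-up is truncated administratively at ``max_followup_days``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import COVARIATE_COLUMNS, EVENT_DEATH, Cohort

ARM_TREATED = "treated"
ARM_UNTREATED = "untreated"
ARMS = (ARM_TREATED, ARM_UNTREATED)

REASON_EVENT = "event"
REASON_ARTIFICIAL = "artificial_censor"
REASON_ADMIN = "admin_censor"

#: columns of the clone table beyond the carried-over baseline covariates
CLONE_COLUMNS = ("patient_id", "arm", "end_day", "end_reason", "event_type", "weight")


@dataclass(frozen=True)
class ProtocolConfig:
    """Emulated-trial protocol: grace period and follow-up horizon (days)."""

    grace_period_days: int = 2
    max_followup_days: int = 60
    arms: tuple[str, str] = ARMS

    def __post_init__(self) -> None:
        g, tau = self.grace_period_days, self.max_followup_days
        if not (1 <= g < tau):
            raise ValueError(f"require 1 <= grace ({g}) < max follow-up ({tau})")


@dataclass(frozen=True)
class Clone:
    patient_id: object
    arm: str
    end_day: int
    end_reason: str
    event_type: str | None
    weight: float = 1.0


class ClonedCohort:
    """Both arms' clones of a source cohort, before or after censoring.

    ``df`` holds one row per clone with ``CLONE_COLUMNS`` plus the baseline
    covariates and admission month carried over for the censoring models.
    """

    def __init__(self, df: pd.DataFrame, source: Cohort, protocol: ProtocolConfig,
                 censored: bool = False):
        self.df = df.reset_index(drop=True)
        self.source = source
        self.protocol = protocol
        self.censored = censored
        self.weight_mode: str | None = None  # set by attach_weights

    def __len__(self) -> int:
        return len(self.df)

    def arm(self, arm: str) -> pd.DataFrame:
        if arm not in ARMS:
            raise ValueError(f"unknown arm {arm!r}")
        return self.df[self.df["arm"] == arm]

    @property
    def clones(self) -> list[Clone]:
        return [
            Clone(r.patient_id, r.arm, int(r.end_day), r.end_reason,
                  None if pd.isna(r.event_type) else r.event_type, float(r.weight))
            for r in self.df.itertuples(index=False)
        ]

    def with_df(self, df: pd.DataFrame, censored: bool | None = None) -> "ClonedCohort":
        return ClonedCohort(df, self.source, self.protocol,
                            self.censored if censored is None else censored)


def clone_cohort(cohort: Cohort, protocol: ProtocolConfig) -> ClonedCohort:
    """Duplicate every patient into both arms; no censoring applied yet.

    Each clone initially ends at ``min(event_day, tau)`` with the observed
    event, or with administrative censoring at ``tau``.
    """
    tau = protocol.max_followup_days
    base = cohort.df
    n = len(base)
    end_day = np.minimum(base["event_day"].to_numpy(), tau)
    admin = base["event_day"].to_numpy() > tau
    reason = np.where(admin, REASON_ADMIN, REASON_EVENT)
    event_type = base["event_type"].where(~admin, other=pd.NA)

    parts = []
    for arm in ARMS:
        part = base[["patient_id", *COVARIATE_COLUMNS, "admission_month",
                     "treatment_day", "event_day"]].copy()
        part["arm"] = arm
        part["end_day"] = end_day
        part["end_reason"] = reason
        part["event_type"] = event_type
        part["weight"] = 1.0
        parts.append(part)
    df = pd.concat(parts, ignore_index=True)
    assert len(df) == 2 * n
    return ClonedCohort(df, cohort, protocol, censored=False)


def _grace_censor_arrays(
    treatment_day: np.ndarray,
    end_day: np.ndarray,
    is_admin: np.ndarray,
    g: int,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Vectorised censoring rules; shared by the frame path and the fast path.

    ``treatment_day`` uses 0 for "never treated".  Returns, per arm, the
    clone end day and a boolean artificial-censoring flag.
    """
    treated_in_grace = (treatment_day >= 1) & (treatment_day <= g)
    event_in_grace = ~treated_in_grace & ~is_admin & (end_day <= g)

    t_keep = treated_in_grace | event_in_grace
    treated_end = np.where(t_keep, end_day, g)
    treated_art = ~t_keep

    untreated_end = np.where(treated_in_grace, treatment_day, end_day)
    untreated_art = treated_in_grace
    return {ARM_TREATED: (treated_end, treated_art),
            ARM_UNTREATED: (untreated_end, untreated_art)}


def apply_grace_censoring(cloned: ClonedCohort) -> ClonedCohort:
    """Apply the arm-specific artificial-censoring rules to fresh clones."""
    if cloned.censored:
        raise RuntimeError("grace-period censoring has already been applied")
    g = cloned.protocol.grace_period_days
    df = cloned.df.copy()
    t = df["treatment_day"].fillna(0).to_numpy()
    end = df["end_day"].to_numpy()
    is_admin = (df["end_reason"] == REASON_ADMIN).to_numpy()
    rules = _grace_censor_arrays(t, end, is_admin, g)

    for arm in ARMS:
        mask = (df["arm"] == arm).to_numpy()
        new_end, art = rules[arm]
        art = art & mask
        df.loc[mask, "end_day"] = new_end[mask].astype(np.int64)
        df.loc[art, "end_reason"] = REASON_ARTIFICIAL
        df.loc[art, "event_type"] = pd.NA
    return cloned.with_df(df, censored=True)


def arm_status_counts(cloned: ClonedCohort) -> pd.DataFrame:
    """Per-arm counts of clones still followed vs artificially censored."""
    if not cloned.censored:
        raise RuntimeError("apply_grace_censoring first")
    rows = []
    for arm in ARMS:
        part = cloned.arm(arm)
        cens = int((part["end_reason"] == REASON_ARTIFICIAL).sum())
        rows.append({"arm": arm, "followed": len(part) - cens, "artificially_censored": cens})
    return pd.DataFrame(rows)


def person_day_table(cloned: ClonedCohort) -> pd.DataFrame:
    """Expand clones into one row per clone-day for the pooled outcome models.

    A clone ending on day ``d`` contributes rows for days ``1..d``.  The
    death/discharge indicators are zero everywhere except the final row of a
    clone that ended with that event; artificially or administratively
    censored clones contribute event-free at-risk days only.

    The ``weight`` column carries the day-level censoring weight once
    :func:`ttecr.weighting.attach_weights` has run: in ladder mode each day
    has its own weight and a day the clone was not at risk (the treatment
    day of an untreated-arm censored clone) gets weight 0; in fixed mode
    the clone's single weight is repeated.  Before weighting all rows have
    weight 1.
    """
    if not cloned.censored:
        raise RuntimeError("apply_grace_censoring first")
    df = cloned.df
    end = df["end_day"].to_numpy()
    idx = np.repeat(np.arange(len(df)), end)
    day = np.concatenate([np.arange(1, d + 1) for d in end]) if len(df) else np.array([], int)

    out = df.iloc[idx][["patient_id", "arm", "admission_month",
                        *COVARIATE_COLUMNS]].reset_index(drop=True)
    out.insert(2, "day", day)
    if "w_post" in df.columns:  # weights attached
        g = cloned.protocol.grace_period_days
        w_day = df[[f"w_day_{s}" for s in range(1, g + 1)]].to_numpy()[idx]
        w = np.where(day > g, df["w_post"].to_numpy()[idx],
                     w_day[np.arange(len(day)), np.minimum(day, g) - 1])
        w = np.where(day > df["at_risk_days"].to_numpy()[idx], 0.0, w)
    else:
        w = df["weight"].to_numpy()[idx]
    out["weight"] = w
    last = np.zeros(len(out), dtype=bool)
    if len(df):
        last[np.cumsum(end) - 1] = True
    is_event = (df["end_reason"] == REASON_EVENT).to_numpy()[idx]
    is_death = (df["event_type"] == EVENT_DEATH).to_numpy()[idx]
    out["death"] = (last & is_event & is_death).astype(np.int64)
    out["discharge"] = (last & is_event & ~is_death).astype(np.int64)
    return out
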