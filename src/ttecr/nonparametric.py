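"""Weighted Nelson–Aalen, weighted Aalen–Johansen, and the naive comparator.

The nonparametric estimators act on weighted clone-level data (end day,
end reason, cause, weight).  Within a day, ties between causes are resolved
from the same at-risk set — at daily resolution any finer ordering is
unidentifiable — and every estimator is invariant to rescaling all weights
by a constant.

The naive Kaplan–Meier analysis is deliberately wrong: it runs on the
original, uncloned cohort, groups patients by eventually-received
treatment, and treats discharge as plain right-censoring.  It is included
to demonstrate the competing-risks bias (1 - KM systematically exceeds the
Aalen–Johansen death incidence once discharges occur) and, with the
``ever_treated`` grouping, immortal time bias as well.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

from .cohort import EVENT_DEATH, Cohort
from .emulate import REASON_EVENT, ClonedCohort

CAUSES = ("death", "discharge")


@dataclass
class StepFunction:
    """A right-continuous step function given by jump times and post-jump values."""

    jump_times: np.ndarray
    values: np.ndarray
    initial_value: float = 0.0

    def __post_init__(self) -> None:
        self.jump_times = np.asarray(self.jump_times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.jump_times.shape != self.values.shape:
            raise ValueError("jump_times and values differ in length")
        if np.any(np.diff(self.jump_times) <= 0):
            raise ValueError("jump_times must be strictly increasing")

    def __call__(self, t) -> np.ndarray | float:
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.jump_times, t, side="right")
        padded = np.concatenate([[self.initial_value], self.values])
        out = padded[idx]
        return float(out) if out.ndim == 0 else out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.jump_times, "estimate": self.values})


def _clone_arrays(clones: ClonedCohort | pd.DataFrame):
    df = clones.df if isinstance(clones, ClonedCohort) else clones
    end = df["end_day"].to_numpy(dtype=float)
    w = df["weight"].to_numpy(dtype=float)
    is_event = (df["end_reason"] == REASON_EVENT).to_numpy(dtype=bool)
    is_death = is_event & (df["event_type"] == EVENT_DEATH).fillna(False)\
        .to_numpy(dtype=bool)
    is_disch = is_event & ~is_death
    return end, w, is_death, is_disch


def weighted_nelson_aalen(clones: ClonedCohort | pd.DataFrame, cause: str) -> StepFunction:
    """Weighted cause-specific Nelson–Aalen cumulative hazard.

    At each event day t the increment is (weighted events of this cause at
    t) / (weighted clones with end day >= t).
    """
    if cause not in CAUSES:
        raise ValueError(f"unknown cause {cause!r}")
    end, w, is_death, is_disch = _clone_arrays(clones)
    is_cause = is_death if cause == "death" else is_disch
    event_times = np.unique(end[is_cause])
    if event_times.size == 0:
        return StepFunction(np.array([np.inf]), np.array([0.0]))
    incr = np.empty(event_times.size)
    for k, t in enumerate(event_times):
        at_risk = w[end >= t].sum()
        if at_risk <= 0:
            raise ValueError(f"empty risk set at t={t}")
        incr[k] = w[is_cause & (end == t)].sum() / at_risk
    return StepFunction(event_times, np.cumsum(incr))


def weighted_aalen_johansen(clones: ClonedCohort | pd.DataFrame) -> dict[str, StepFunction]:
    """Weighted Aalen–Johansen cumulative incidences and overall survival.

    Returns ``{"death": CIF, "discharge": CIF, "survival": S}`` where
    ``CIF_c(t) = Σ_{s<=t} S(s-) dΛ_c(s)`` and S is the all-cause
    product-limit survival.  With no external censoring mass,
    ``CIF_death + CIF_discharge + S = 1`` at every jump time.
    """
    end, w, is_death, is_disch = _clone_arrays(clones)
    event_times = np.unique(end[is_death | is_disch])
    if event_times.size == 0:
        flat = StepFunction(np.array([np.inf]), np.array([0.0]))
        return {"death": flat, "discharge": flat,
                "survival": StepFunction(np.array([np.inf]), np.array([1.0]),
                                         initial_value=1.0)}
    n_t = event_times.size
    d_death = np.empty(n_t)
    d_disch = np.empty(n_t)
    at_risk = np.empty(n_t)
    for k, t in enumerate(event_times):
        at_risk[k] = w[end >= t].sum()
        if at_risk[k] <= 0:
            raise ValueError(f"empty risk set at t={t}")
        d_death[k] = w[is_death & (end == t)].sum()
        d_disch[k] = w[is_disch & (end == t)].sum()
    h_death = d_death / at_risk
    h_disch = d_disch / at_risk
    surv = np.cumprod(1.0 - h_death - h_disch)
    surv_prev = np.concatenate([[1.0], surv[:-1]])
    cif_death = np.cumsum(surv_prev * h_death)
    cif_disch = np.cumsum(surv_prev * h_disch)
    return {
        "death": StepFunction(event_times, cif_death),
        "discharge": StepFunction(event_times, cif_disch),
        "survival": StepFunction(event_times, surv, initial_value=1.0),
    }


def naive_km_death(cohort: Cohort, grouping: str = "treated_within_grace",
                   grace_period_days: int = 2) -> dict[str, StepFunction]:
    """Naive per-group cumulative death probability, 1 - Kaplan–Meier.

    Runs on the original uncloned cohort with discharge treated as
    right-censoring.  ``grouping`` is ``"treated_within_grace"`` (default,
    mirroring the emulation's classification), ``"ever_treated"`` (which
    additionally builds in immortal time bias), or ``"overall"`` for a
    single ungrouped curve.
    """
    df = cohort.df
    t = df["treatment_day"]
    if grouping == "treated_within_grace":
        groups = {"treated": t.notna() & (t <= grace_period_days)}
    elif grouping == "ever_treated":
        groups = {"treated": t.notna()}
    elif grouping == "overall":
        groups = {"overall": pd.Series(True, index=df.index)}
    else:
        raise ValueError(f"unknown grouping {grouping!r}")
    if grouping != "overall":
        groups["untreated"] = ~groups["treated"]

    out: dict[str, StepFunction] = {}
    for label, mask in groups.items():
        part = df[mask]
        if len(part) == 0:
            raise ValueError(f"empty group {label!r} under grouping {grouping!r}")
        kmf = KaplanMeierFitter()
        kmf.fit(part["event_day"], event_observed=(part["event_type"] == EVENT_DEATH))
        sf = kmf.survival_function_
        times = sf.index.to_numpy(dtype=float)
        vals = 1.0 - sf.iloc[:, 0].to_numpy(dtype=float)
        keep = times > 0
        out[label] = StepFunction(times[keep], vals[keep])
    return out
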