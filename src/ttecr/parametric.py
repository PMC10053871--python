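"""Constant cause-specific hazards and the closed-form effect measures.

The outcome model is a three-state competing-risks model: from the initial
in-hospital state a patient moves to one of two absorbing states, death in
hospital or discharge alive, at constant cause-specific daily rates.  With
arms indexed 0 (untreated) and 1 (treated) and causes 2 (death) and 3
(discharge), the four rates are λ02, λ03, λ12, λ13.  Each rate is estimated
by a weighted pooled logistic regression on the person-day table; with an
intercept-only linear predictor the fitted daily hazard equals the
occurrence/exposure ratio Σ(w·events)/Σ(w·person-days) exactly.

All risk-scale quantities follow from the rates in closed form.  For a
single arm with total rate λ = λd + λr,

    CIF_death(t)     = (λd / λ) (1 - exp(-λ t))
    CIF_discharge(t) = (λr / λ) (1 - exp(-λ t))
    mortality risk   = λd / λ          (t → ∞)
    mean stay        = 1 / λ

Treatment contrasts are the cause-specific hazard ratios λ1j/λ0j, and risk
differences/ratios of the arm-specific CIFs over the follow-up grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .emulate import ARM_TREATED, ARM_UNTREATED, ARMS, ClonedCohort

logger = logging.getLogger(__name__)

CAUSES = ("death", "discharge")


@dataclass(frozen=True)
class HazardEstimates:
    """The four constant cause-specific daily rates of the three-state model."""

    lambda_02: float  # death, untreated
    lambda_03: float  # discharge, untreated
    lambda_12: float  # death, treated
    lambda_13: float  # discharge, treated
    detail: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        for name in ("lambda_02", "lambda_03", "lambda_12", "lambda_13"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.lambda_02 + self.lambda_03 > 1.0 or self.lambda_12 + self.lambda_13 > 1.0:
            raise ValueError("total daily hazard of an arm exceeds 1")

    @property
    def lambda_untreated(self) -> float:
        return self.lambda_02 + self.lambda_03

    @property
    def lambda_treated(self) -> float:
        return self.lambda_12 + self.lambda_13


@dataclass
class CIFCurve:
    """A cumulative incidence curve on a day grid: nondecreasing, in [0, 1]."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values differ in length")
        if np.any(np.diff(self.values) < -1e-12):
            raise ValueError("CIF must be nondecreasing")
        if np.any((self.values < -1e-12) | (self.values > 1 + 1e-12)):
            raise ValueError("CIF values must lie in [0, 1]")

    def at(self, t: float) -> float:
        return float(np.interp(t, self.times, self.values))


@dataclass
class EffectMeasures:
    """The full catalogue of constant-hazard treatment-effect measures."""

    hazards: HazardEstimates
    tau: int
    # end-of-follow-up risks (cause fractions)
    mr0: float
    mr1: float
    mortality_risk_ratio: float
    mortality_difference: float
    dr0: float
    dr1: float
    discharge_risk_ratio: float
    discharge_difference: float
    # cause-specific hazard ratios
    hr_death: float
    hr_discharge: float
    # curves on integer days 0..tau
    cif: dict[tuple[str, str], CIFCurve]
    rd_death: np.ndarray
    rd_discharge: np.ndarray
    rr_death: np.ndarray
    rr_discharge: np.ndarray
    # expected lengths of stay
    los0: float
    los1: float
    los_difference: float

    @property
    def times(self) -> np.ndarray:
        return self.cif[(ARM_UNTREATED, "death")].times

    def rd_death_at(self, t: float) -> float:
        return float(np.interp(t, self.times, self.rd_death))

    def rd_discharge_at(self, t: float) -> float:
        return float(np.interp(t, self.times, self.rd_discharge))

    def summary_frame(self) -> pd.DataFrame:
        h = self.hazards
        rows = [
            ("lambda_02", "death rate/day, untreated", h.lambda_02),
            ("lambda_03", "discharge rate/day, untreated", h.lambda_03),
            ("lambda_12", "death rate/day, treated", h.lambda_12),
            ("lambda_13", "discharge rate/day, treated", h.lambda_13),
            ("MR0", "mortality risk, untreated", self.mr0),
            ("MR1", "mortality risk, treated", self.mr1),
            ("mortality_risk_ratio", "MR1 / MR0", self.mortality_risk_ratio),
            ("mortality_difference", "MR1 - MR0", self.mortality_difference),
            ("discharge_risk_ratio", "DR1 / DR0", self.discharge_risk_ratio),
            ("discharge_difference", "DR1 - DR0", self.discharge_difference),
            ("HR_death", "lambda_12 / lambda_02", self.hr_death),
            ("HR_discharge", "lambda_13 / lambda_03", self.hr_discharge),
            (f"RD_death({self.tau})", "risk difference, death", self.rd_death_at(self.tau)),
            (f"RD_discharge({self.tau})", "risk difference, discharge",
             self.rd_discharge_at(self.tau)),
            ("LOS0", "mean stay (days), untreated", self.los0),
            ("LOS1", "mean stay (days), treated", self.los1),
            ("LOS_difference", "LOS1 - LOS0", self.los_difference),
        ]
        return pd.DataFrame(rows, columns=["measure", "description", "estimate"])


@dataclass
class PooledLogisticFit:
    """One arm x cause pooled logistic fit and its marginal daily hazard."""

    arm: str
    cause: str
    hazard: float
    params: pd.Series
    events: float  # weighted
    person_days: float  # weighted
    n_rows: int


def fit_pooled_logistic(person_days: pd.DataFrame, arm: str, cause: str,
                        adjustment: tuple[str, ...] | None = None,
                        month_distribution: pd.Series | None = None,
                        ) -> PooledLogisticFit:
    """Weighted pooled logistic regression for one arm and cause.

    Person-day rows of the arm are modelled with a daily event indicator for
    ``cause``; the competing cause counts as an event-free day.  With
    ``adjustment`` containing ``"admission_month"`` the month enters as a
    categorical covariate and the marginal hazard is the fitted per-month
    hazard averaged over ``month_distribution`` (defaults to the month
    distribution of the supplied person-day table's patients).
    """
    if cause not in CAUSES:
        raise ValueError(f"unknown cause {cause!r}")
    adjustment = tuple(adjustment or ())
    unknown = set(adjustment) - {"admission_month"}
    if unknown:
        raise ValueError(f"unsupported adjustment covariates: {sorted(unknown)}")

    part = person_days[person_days["arm"] == arm]
    if len(part) == 0:
        raise ValueError(f"no person-days in arm {arm!r}")
    y = part[cause].to_numpy(dtype=float)
    w = part["weight"].to_numpy(dtype=float)
    if float(w.sum()) <= 0:
        raise ValueError(f"no weighted person-days in arm {arm!r}")
    if float((w * y).sum()) == 0.0:
        # no events of this cause: the MLE sits on the boundary (hazard 0)
        return PooledLogisticFit(arm, cause, 0.0,
                                 pd.Series({"intercept": -np.inf}),
                                 0.0, float(w.sum()), len(part))

    if not adjustment:
        # intercept-only: MLE is the weighted occurrence/exposure ratio
        exog = np.ones((len(part), 1))
        names = ["intercept"]
    else:
        dummies = pd.get_dummies(part["admission_month"], prefix="month", drop_first=True)
        exog = np.column_stack([np.ones(len(part)), dummies.to_numpy(dtype=float)])
        names = ["intercept", *dummies.columns]

    model = sm.GLM(y, exog, family=sm.families.Binomial(), freq_weights=w)
    try:
        res = model.fit(tol=1e-12)
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(
            f"pooled logistic fit failed for arm={arm} cause={cause}; "
            "consider dropping the month adjustment"
        ) from exc
    params = pd.Series(res.params, index=names)
    if not np.isfinite(params).all() or np.abs(params).max() > 30:
        raise RuntimeError(
            f"separation suspected in adjusted fit (arm={arm}, cause={cause}); "
            "consider dropping the month adjustment"
        )

    if not adjustment:
        hazard = float(1.0 / (1.0 + np.exp(-params["intercept"])))
    else:
        hazard = _standardised_hazard(params, part, month_distribution)
    return PooledLogisticFit(arm, cause, hazard, params,
                             float((w * y).sum()), float(w.sum()), len(part))


def _standardised_hazard(params: pd.Series, part: pd.DataFrame,
                         month_distribution: pd.Series | None) -> float:
    """Average the per-month fitted hazards over the cohort month mix."""
    if month_distribution is None:
        month_distribution = (part.drop_duplicates("patient_id")["admission_month"]
                              .value_counts(normalize=True))
    total = 0.0
    for month, prob in month_distribution.items():
        eta = params["intercept"] + params.get(f"month_{month}", 0.0)
        total += prob * (1.0 / (1.0 + np.exp(-eta)))
    return float(total)


def occurrence_exposure_rate(person_days: pd.DataFrame, arm: str, cause: str) -> float:
    """Σ(w·events) / Σ(w·person-days): the closed-form intercept-only MLE."""
    part = person_days[person_days["arm"] == arm]
    w = part["weight"].to_numpy(dtype=float)
    if w.sum() == 0:
        raise ValueError(f"no person-days in arm {arm!r}")
    return float((w * part[cause].to_numpy()).sum() / w.sum())


def hazard_estimates(person_days: pd.DataFrame,
                     adjustment: tuple[str, ...] | None = None) -> HazardEstimates:
    """Assemble the four λij from per-arm, per-cause pooled logistic fits."""
    for arm in ARMS:
        if (person_days["arm"] == arm).sum() == 0:
            raise ValueError(f"no follow-up time in arm {arm!r}")
    month_dist = (person_days.drop_duplicates(["patient_id", "arm"])["admission_month"]
                  .value_counts(normalize=True)) if adjustment else None
    fits = {(arm, cause): fit_pooled_logistic(person_days, arm, cause,
                                              adjustment, month_dist)
            for arm in ARMS for cause in CAUSES}
    detail = {f"{arm}_{cause}": {"events": f.events, "person_days": f.person_days}
              for (arm, cause), f in fits.items()}
    for key, d in detail.items():
        logger.info("hazard %s: %.1f weighted events / %.1f weighted person-days",
                    key, d["events"], d["person_days"])
    return HazardEstimates(
        lambda_02=fits[(ARM_UNTREATED, "death")].hazard,
        lambda_03=fits[(ARM_UNTREATED, "discharge")].hazard,
        lambda_12=fits[(ARM_TREATED, "death")].hazard,
        lambda_13=fits[(ARM_TREATED, "discharge")].hazard,
        detail=detail,
    )


def hazard_estimates_fast(cloned: ClonedCohort) -> HazardEstimates:
    """Occurrence/exposure rates straight from clone-level data.

    Numerically identical to intercept-only :func:`hazard_estimates` on the
    person-day table — a clone's weighted person-days collapse to the sum
    of its day weights (ladder mode) or weight x end_day (fixed mode), and
    its event carries its final-day weight.  Used on the bootstrap hot path
    where materialising the person-day table would dominate the runtime.
    """
    df = cloned.df
    g = cloned.protocol.grace_period_days
    rates = {}
    for arm in ARMS:
        part = df[df["arm"] == arm]
        w = part["weight"].to_numpy(dtype=float)
        if "w_post" in part.columns:
            L = part["at_risk_days"].to_numpy()
            w_day = part[[f"w_day_{s}" for s in range(1, g + 1)]].to_numpy(dtype=float)
            in_grace = L[:, None] >= np.arange(1, g + 1)[None, :]
            pdays = float((w_day * in_grace).sum()
                          + (np.maximum(L - g, 0) * part["w_post"].to_numpy()).sum())
        else:
            pdays = float((w * part["end_day"].to_numpy()).sum())
        if pdays == 0:
            raise ValueError(f"no follow-up time in arm {arm!r}")
        for cause in CAUSES:
            is_cause = (part["event_type"] == cause).fillna(False).to_numpy(dtype=bool)
            events = float((w * is_cause).sum())
            rates[(arm, cause)] = events / pdays
    return HazardEstimates(
        lambda_02=rates[(ARM_UNTREATED, "death")],
        lambda_03=rates[(ARM_UNTREATED, "discharge")],
        lambda_12=rates[(ARM_TREATED, "death")],
        lambda_13=rates[(ARM_TREATED, "discharge")],
    )


def cif_constant(lambda_cause, lambda_total, t):
    """Closed-form cause-specific cumulative incidence under constant hazards.

    ``(λ_cause / λ_total) (1 - exp(-λ_total t))``, with the convention that a
    zero total rate gives incidence 0.  Accepts scalars or arrays in ``t``.
    """
    lambda_cause = np.asarray(lambda_cause, dtype=float)
    lambda_total = np.asarray(lambda_total, dtype=float)
    t = np.asarray(t, dtype=float)
    if np.any(lambda_cause < 0) or np.any(lambda_total < 0):
        raise ValueError("rates must be nonnegative")
    if np.any(lambda_cause > lambda_total):
        raise ValueError("lambda_cause may not exceed lambda_total")
    if np.any(t < 0):
        raise ValueError("t must be nonnegative")
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(lambda_total > 0, lambda_cause / np.where(lambda_total > 0,
                                                                  lambda_total, 1.0), 0.0)
    out = frac * (1.0 - np.exp(-lambda_total * t))
    return float(out) if out.ndim == 0 else out


def _safe_ratio(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def effect_measures(h: HazardEstimates, tau: int = 60) -> EffectMeasures:
    """Compute the complete effect-measure catalogue from the four rates.

    Ratios with a zero denominator are reported as NaN ("undefined") rather
    than raising.
    """
    if tau < 1:
        raise ValueError("tau must be at least 1 day")
    lam0, lam1 = h.lambda_untreated, h.lambda_treated
    mr0 = _safe_ratio(h.lambda_02, lam0)
    mr1 = _safe_ratio(h.lambda_12, lam1)
    dr0 = _safe_ratio(h.lambda_03, lam0)
    dr1 = _safe_ratio(h.lambda_13, lam1)

    grid = np.arange(0, tau + 1, dtype=float)
    cif = {
        (ARM_UNTREATED, "death"): CIFCurve(grid, cif_constant(h.lambda_02, lam0, grid)),
        (ARM_UNTREATED, "discharge"): CIFCurve(grid, cif_constant(h.lambda_03, lam0, grid)),
        (ARM_TREATED, "death"): CIFCurve(grid, cif_constant(h.lambda_12, lam1, grid)),
        (ARM_TREATED, "discharge"): CIFCurve(grid, cif_constant(h.lambda_13, lam1, grid)),
    }
    rd_death = cif[(ARM_TREATED, "death")].values - cif[(ARM_UNTREATED, "death")].values
    rd_disch = (cif[(ARM_TREATED, "discharge")].values
                - cif[(ARM_UNTREATED, "discharge")].values)
    with np.errstate(divide="ignore", invalid="ignore"):
        rr_death = cif[(ARM_TREATED, "death")].values / cif[(ARM_UNTREATED, "death")].values
        rr_disch = (cif[(ARM_TREATED, "discharge")].values
                    / cif[(ARM_UNTREATED, "discharge")].values)

    los0 = 1.0 / lam0 if lam0 > 0 else float("inf")
    los1 = 1.0 / lam1 if lam1 > 0 else float("inf")
    return EffectMeasures(
        hazards=h, tau=tau,
        mr0=mr0, mr1=mr1,
        mortality_risk_ratio=_safe_ratio(mr1, mr0),
        mortality_difference=mr1 - mr0,
        dr0=dr0, dr1=dr1,
        discharge_risk_ratio=_safe_ratio(dr1, dr0),
        discharge_difference=dr1 - dr0,
        hr_death=_safe_ratio(h.lambda_12, h.lambda_02),
        hr_discharge=_safe_ratio(h.lambda_13, h.lambda_03),
        cif=cif,
        rd_death=rd_death, rd_discharge=rd_disch,
        rr_death=rr_death, rr_discharge=rr_disch,
        los0=los0, los1=los1, los_difference=los1 - los0,
    )


def measures_from_mortality_risks(mr1: float, mr0: float, mean_stay_days: float = 8.0,
                                  tau: int = 60) -> EffectMeasures:
    """Effect measures from end-of-follow-up mortality risks alone.

    Convenience for worked contrasts when only the two mortality risks are
    known: with both absorbing states exhausting probability, the discharge
    risks are the one-minus complements, and a common mean stay pins the
    total rates.
    """
    lam = 1.0 / mean_stay_days
    h = HazardEstimates(lambda_02=mr0 * lam, lambda_03=(1 - mr0) * lam,
                        lambda_12=mr1 * lam, lambda_13=(1 - mr1) * lam)
    return effect_measures(h, tau=tau)


def hazard_ratio_ci(cohort, protocol=None, covariates=None, adjustment=None,
                    B: int = 500, seed: int = 0):
    """Cause-specific hazard ratios with bootstrap percentile intervals.

    Point estimates are λ12/λ02 and λ13/λ03 from the full-data pipeline;
    intervals come from :func:`ttecr.inference.bootstrap_ci`, which re-runs
    cloning, censoring, weighting and estimation on each patient resample.
    """
    from .inference import bootstrap_ci  # local import avoids a cycle
    from .pipeline import estimate_effects

    def pipe(c):
        return estimate_effects(c, protocol=protocol, covariates=covariates,
                                adjustment=adjustment)

    stats = {"hr_death": lambda r: r.measures.hr_death,
             "hr_discharge": lambda r: r.measures.hr_discharge}
    return bootstrap_ci(cohort, pipe, stats, B=B, seed=seed)
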