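"""End-to-end orchestration: emulate, weight, estimate, compare, report.

:func:`estimate_effects` is the canonical estimator used everywhere —
directly, inside the bootstrap, and in sensitivity re-runs: clone the
cohort into both arms, apply grace-period censoring, fit per-arm censoring
models, attach inverse-probability weights, estimate the four constant
cause-specific hazards from weighted person-time, and derive the closed-
form effect measures.

:func:`run_pipeline` wraps that estimator with everything a reported
analysis needs: baseline table, arm bookkeeping, weight summary, bootstrap
intervals, nonparametric comparators (weighted Nelson-Aalen and
Aalen-Johansen), the deliberately naive Kaplan-Meier analysis, grace-period
sensitivity re-runs, plots, and delimited/JSON artifacts on disk.  All
randomness flows from a single master seed recorded in the report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import nonparametric as npar
from .cohort import Cohort, baseline_table
from .emulate import (ARM_TREATED, ARM_UNTREATED, ARMS, ProtocolConfig,
                      apply_grace_censoring, arm_status_counts, clone_cohort,
                      person_day_table)
from .inference import bootstrap_ci
from .parametric import (EffectMeasures, HazardEstimates, effect_measures,
                         hazard_estimates, hazard_estimates_fast)
from .weighting import (DEFAULT_CENSORING_COVARIATES, attach_weights,
                        fit_censoring_model, weight_summary)

logger = logging.getLogger(__name__)


@dataclass
class PipelineEstimate:
    """Everything produced by one pass of the clone-censor-weight estimator."""

    hazards: HazardEstimates
    measures: EffectMeasures
    cloned: object  # weighted ClonedCohort
    censoring_models: dict


def estimate_effects(
    cohort: Cohort,
    protocol: ProtocolConfig | None = None,
    covariates=None,
    adjustment: tuple[str, ...] | None = None,
    weighted: bool = True,
    weight_mode: str = "ladder",
    survival_method: str = "exp",
) -> PipelineEstimate:
    """Run the full clone-censor-weight estimator on one cohort.

    With ``adjustment`` empty the hazards are taken straight from weighted
    clone-level occurrence/exposure ratios, which is numerically identical
    to the intercept-only pooled logistic fits on the person-day table;
    with an adjustment list the pooled logistic models are fitted on the
    expanded table and marginalised.  ``weighted=False`` keeps all weights
    at 1 (the biased comparator); ``weight_mode`` selects the day-by-day
    weight ladder (default) or the single fixed per-clone weight (see
    :mod:`ttecr.weighting`).
    """
    protocol = protocol or ProtocolConfig()
    covariates = tuple(covariates) if covariates is not None else DEFAULT_CENSORING_COVARIATES
    cloned = apply_grace_censoring(clone_cohort(cohort, protocol))
    models = {}
    if weighted:
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # degenerate arms already logged
            models = {arm: fit_censoring_model(cloned, arm, covariates) for arm in ARMS}
        cloned = attach_weights(cloned, models, mode=weight_mode, method=survival_method)
    if adjustment:
        pdays = person_day_table(cloned)
        hz = hazard_estimates(pdays, adjustment=tuple(adjustment))
    else:
        hz = hazard_estimates_fast(cloned)
    return PipelineEstimate(
        hazards=hz,
        measures=effect_measures(hz, tau=protocol.max_followup_days),
        cloned=cloned,
        censoring_models=models,
    )


# --- array fast path ---------------------------------------------------------
#
# The patient-level bootstrap refits the whole pipeline tens of thousands of
# times; the frame-based path below the public API spends most of that in
# DataFrame bookkeeping.  ArrayCohort + fast_hazard_estimates run the
# identical estimator (same censoring rules, same Cox fit, same ladder
# weights via CensoringModel.day_hazards) on bare numpy arrays; an
# equivalence test pins the two routes together.

class ArrayCohort:
    """A cohort reduced to the arrays the estimator needs (bootstrap view)."""

    __slots__ = ("X", "treatment_day", "event_day", "is_death")

    def __init__(self, X, treatment_day, event_day, is_death):
        self.X = X
        self.treatment_day = treatment_day
        self.event_day = event_day
        self.is_death = is_death

    @classmethod
    def from_cohort(cls, cohort: Cohort, covariates=DEFAULT_CENSORING_COVARIATES):
        df = cohort.df
        return cls(
            X=df[list(covariates)].to_numpy(dtype=float),
            treatment_day=df["treatment_day"].fillna(0).to_numpy(dtype=np.int64),
            event_day=df["event_day"].to_numpy(dtype=np.int64),
            is_death=(df["event_type"] == "death").to_numpy(dtype=bool),
        )

    def __len__(self) -> int:
        return len(self.event_day)

    def take(self, indices, reassign_ids: bool = True) -> "ArrayCohort":
        idx = np.asarray(indices)
        return ArrayCohort(self.X[idx], self.treatment_day[idx],
                           self.event_day[idx], self.is_death[idx])


def fast_hazard_estimates(ac: ArrayCohort, protocol: ProtocolConfig | None = None,
                          weighted: bool = True) -> HazardEstimates:
    """The clone-censor-weight (ladder) hazard estimator on bare arrays.

    Numerically identical to ``estimate_effects(...).hazards`` with default
    settings; exists because the bootstrap cannot afford the frame layer.
    """
    from .cox import fit_cox_breslow
    from .emulate import _grace_censor_arrays
    from .weighting import PROBABILITY_FLOOR, CensoringModel

    protocol = protocol or ProtocolConfig()
    g, tau = protocol.grace_period_days, protocol.max_followup_days
    end0 = np.minimum(ac.event_day, tau)
    admin = ac.event_day > tau
    rules = _grace_censor_arrays(ac.treatment_day, end0, admin, g)

    rates = {}
    for arm in ARMS:
        end, art = rules[arm]
        has_event = ~art & ~admin
        death_w = has_event & ac.is_death
        disch_w = has_event & ~ac.is_death
        n = len(end)
        if weighted:
            dur = np.minimum(end, g).astype(float)
            fit = fit_cox_breslow(ac.X if art.any() else np.empty((n, 0)), dur, art)
            model = CensoringModel(arm, (), fit, g, degenerate=not art.any())
            alpha = model.day_hazards(ac.X)
            surv = np.cumprod(1.0 - alpha, axis=1)
            if arm == ARM_UNTREATED:
                rho = surv
            else:
                rho = np.column_stack([np.ones(n), surv[:, :-1]])
            rho = np.clip(rho, PROBABILITY_FLOOR, 1.0)
            w_day = 1.0 / rho
            w_post = 1.0 / np.clip(surv[:, -1], PROBABILITY_FLOOR, 1.0)
        else:
            w_day = np.ones((n, g))
            w_post = np.ones(n)
        L = end.astype(np.int64)
        if arm == ARM_UNTREATED:
            L = np.where(art, L - 1, L)
        in_grace = L[:, None] >= np.arange(1, g + 1)[None, :]
        pdays = float((w_day * in_grace).sum() + (np.maximum(L - g, 0) * w_post).sum())
        if pdays == 0:
            raise ValueError(f"no follow-up time in arm {arm!r}")
        w_event = np.where(end > g, w_post,
                           w_day[np.arange(n), np.minimum(end, g) - 1])
        rates[(arm, "death")] = float((w_event * death_w).sum() / pdays)
        rates[(arm, "discharge")] = float((w_event * disch_w).sum() / pdays)
    return HazardEstimates(
        lambda_02=rates[(ARM_UNTREATED, "death")],
        lambda_03=rates[(ARM_UNTREATED, "discharge")],
        lambda_12=rates[(ARM_TREATED, "death")],
        lambda_13=rates[(ARM_TREATED, "discharge")],
    )


def fast_bootstrap(cohort: Cohort, statistics, protocol: ProtocolConfig | None = None,
                   B: int = 500, seed: int = 0,
                   covariates=DEFAULT_CENSORING_COVARIATES) -> dict:
    """Patient-level bootstrap using the array fast path.

    ``statistics`` maps names to extractors of an
    :class:`~ttecr.parametric.EffectMeasures`; resampling and interval
    construction are delegated to :func:`ttecr.inference.bootstrap_ci`.
    """
    protocol = protocol or ProtocolConfig()
    ac = ArrayCohort.from_cohort(cohort, covariates)

    def pipe(view: ArrayCohort):
        return effect_measures(fast_hazard_estimates(view, protocol),
                               tau=protocol.max_followup_days)

    return bootstrap_ci(ac, pipe, statistics, B=B, seed=seed)


@dataclass
class RunConfig:
    """Configuration of a complete reported analysis."""

    input_path: str | None = None
    schema: dict = field(default_factory=dict)
    simulation: object | None = None  # SimulationConfig alternative to input_path
    grace_period_days: int = 2
    max_followup_days: int = 60
    covariates: tuple[str, ...] = DEFAULT_CENSORING_COVARIATES
    adjustment: tuple[str, ...] = ()
    bootstrap_B: int = 500
    seed: int = 0
    sensitivity_grace: tuple[int, ...] = (1, 3)
    output_dir: str = "ttecr_run"
    make_plots: bool = True

    def __post_init__(self) -> None:
        for g in (self.grace_period_days, *self.sensitivity_grace):
            if not (1 <= g < self.max_followup_days):
                raise ValueError(f"grace period {g} must satisfy 1 <= g < tau")


def _bootstrap_statistics(tau: int):
    return {
        "mortality_difference": lambda r: r.measures.mortality_difference,
        "mortality_risk_ratio": lambda r: r.measures.mortality_risk_ratio,
        "discharge_risk_ratio": lambda r: r.measures.discharge_risk_ratio,
        "hr_death": lambda r: r.measures.hr_death,
        "hr_discharge": lambda r: r.measures.hr_discharge,
        "rd_death_tau": lambda r: r.measures.rd_death_at(tau),
        "rd_discharge_tau": lambda r: r.measures.rd_discharge_at(tau),
        "los_difference": lambda r: r.measures.los_difference,
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute the whole analysis plan and write artifacts to the output dir.

    Returns a report dictionary whose every number is also written to a
    stage artifact (delimited table or JSON) under ``config.output_dir``.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    protocol = ProtocolConfig(config.grace_period_days, config.max_followup_days)

    if config.simulation is not None:
        from .simulate import simulate_cohort

        cohort = simulate_cohort(config.simulation, seed=config.seed)
        source = f"simulated(n={config.simulation.n}, seed={config.seed})"
    elif config.input_path:
        from .cohort import read_cohort

        cohort = read_cohort(config.input_path, schema=config.schema)
        source = str(config.input_path)
    else:
        raise ValueError("RunConfig needs either input_path or simulation")

    report: dict = {"source": source, "n": len(cohort), "seed": config.seed,
                    "exclusions": cohort.exclusion_log,
                    "protocol": {"grace_period_days": protocol.grace_period_days,
                                 "max_followup_days": protocol.max_followup_days}}

    baseline = baseline_table(cohort)
    baseline.to_csv(out / "baseline.csv", index=False)

    est = estimate_effects(cohort, protocol, config.covariates, config.adjustment)
    counts = arm_status_counts(est.cloned)
    counts.to_csv(out / "arm_status.csv", index=False)
    report["arm_status"] = counts.to_dict(orient="records")

    weight_summary(est.cloned).to_csv(out / "weights.csv", index=False)
    person_day_table(est.cloned).to_csv(out / "person_days.csv", index=False)
    est.cloned.df.to_csv(out / "clones.csv", index=False)

    report["hazards"] = {
        "lambda_02": est.hazards.lambda_02, "lambda_03": est.hazards.lambda_03,
        "lambda_12": est.hazards.lambda_12, "lambda_13": est.hazards.lambda_13,
    }
    est.measures.summary_frame().to_csv(out / "effect_measures.csv", index=False)

    # bootstrap intervals around every headline measure
    def pipe(c: Cohort):
        return estimate_effects(c, protocol, config.covariates, config.adjustment)

    boot = bootstrap_ci(cohort, pipe, _bootstrap_statistics(protocol.max_followup_days),
                        B=config.bootstrap_B, seed=config.seed)
    report["estimates"] = {
        name: {"estimate": b.estimate, "ci_low": b.ci_low, "ci_high": b.ci_high,
               "B": b.B, "failed_replicates": b.n_failed}
        for name, b in boot.items()
    }

    # nonparametric comparators on the weighted clones
    curves = {}
    for arm in ARMS:
        aj = npar.weighted_aalen_johansen(est.cloned.arm(arm))
        for cause in ("death", "discharge"):
            curves[f"aj_{arm}_{cause}"] = aj[cause]
            curves[f"na_{arm}_{cause}"] = npar.weighted_nelson_aalen(
                est.cloned.arm(arm), cause)
    naive = npar.naive_km_death(cohort, grouping="treated_within_grace",
                                grace_period_days=protocol.grace_period_days)
    for label, sf in naive.items():
        curves[f"naive_km_{label}"] = sf
    curve_frames = []
    for name, sf in curves.items():
        fr = sf.to_frame()
        fr.insert(0, "curve", name)
        curve_frames.append(fr)
    pd.concat(curve_frames, ignore_index=True).to_csv(out / "curves.csv", index=False)

    # grace-period sensitivity re-runs (point estimates only)
    sens_rows = []
    for g in (protocol.grace_period_days, *config.sensitivity_grace):
        p = ProtocolConfig(g, protocol.max_followup_days)
        e = estimate_effects(cohort, p, config.covariates, config.adjustment)
        sens_rows.append({
            "grace_period_days": g,
            "mortality_difference": e.measures.mortality_difference,
            "hr_death": e.measures.hr_death,
            "hr_discharge": e.measures.hr_discharge,
            "rd_death_tau": e.measures.rd_death_at(protocol.max_followup_days),
        })
    sens = pd.DataFrame(sens_rows)
    sens.to_csv(out / "sensitivity.csv", index=False)
    report["sensitivity"] = sens.to_dict(orient="records")

    if config.make_plots:
        _write_plots(out, est, curves, protocol)

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    logger.info("pipeline run written to %s", out)
    return report


def _write_plots(out: Path, est: PipelineEstimate, curves: dict,
                 protocol: ProtocolConfig, plot_horizon: int = 30) -> None:
    """Overlay plots cut at 30 days; estimates elsewhere remain at tau."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    days = np.arange(0, plot_horizon + 1)
    fig, axes = plt.subplots(1, 2, figsize=(10, 4), sharex=True)
    for ax, cause in zip(axes, ("death", "discharge")):
        for arm, style in ((ARM_TREATED, "-"), (ARM_UNTREATED, "--")):
            cif = est.measures.cif[(arm, cause)]
            ax.plot(days, cif.values[: plot_horizon + 1], style, label=f"{arm} (model)")
            aj = curves[f"aj_{arm}_{cause}"]
            ax.step(days, aj(days), style, alpha=0.5, where="post",
                    label=f"{arm} (Aalen-Johansen)")
        ax.set_title(f"Cumulative incidence: {cause}")
        ax.set_xlabel("days since admission")
        ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(out / "cif.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(days, est.measures.rd_death[: plot_horizon + 1], label="death")
    ax.plot(days, est.measures.rd_discharge[: plot_horizon + 1], label="discharge")
    ax.axhline(0.0, color="grey", lw=0.5)
    ax.set_xlabel("days since admission")
    ax.set_ylabel("risk difference (treated - untreated)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out / "risk_differences.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(6, 4))
    for label, sf in ((k, v) for k, v in curves.items() if k.startswith("naive_km")):
        ax.step(days, sf(days), where="post", label=label.replace("naive_km_", "naive KM: "))
    aj_all = curves.get("aj_untreated_death")
    if aj_all is not None:
        ax.step(days, aj_all(days), where="post", ls="--", label="AJ death (untreated arm)")
    ax.set_xlabel("days since admission")
    ax.set_ylabel("cumulative death probability")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(out / "naive_km.png", dpi=120)
    plt.close(fig)
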