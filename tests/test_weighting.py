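"""Censoring models, uncensored-probability forms, and weight attachment.

The in-house Breslow Cox fit is checked against lifelines' CoxPHFitter
(which also uses Breslow ties) as an independent oracle.
"""

import warnings

import numpy as np
import pandas as pd
import pytest
from statsmodels.duration.hazard_regression import PHReg

from ttecr.cox import CoxFit, fit_cox_breslow
from ttecr.emulate import (ARM_TREATED, ARM_UNTREATED, ProtocolConfig,
                           apply_grace_censoring, clone_cohort)
from ttecr.simulate import simulate_cohort, unconfounded_config
from ttecr.weighting import (CensoringModel, attach_weights,
                             censoring_process_data, fit_censoring_model,
                             prob_uncensored)

from conftest import make_cohort

ARMS = (ARM_TREATED, ARM_UNTREATED)


def _cloned(cohort, g=2):
    return apply_grace_censoring(clone_cohort(cohort, ProtocolConfig(g, 60)))


@pytest.fixture(scope="module")
def sim_cloned():
    return _cloned(simulate_cohort(unconfounded_config(n=2000, seed=8)))


@pytest.fixture(scope="module")
def sim_models(sim_cloned):
    return {arm: fit_censoring_model(sim_cloned, arm) for arm in ARMS}


class TestCoxAgainstStatsmodels:
    def test_coefficients_and_baseline_match(self, sim_cloned):
        """Partial-likelihood fit and Breslow baseline agree with
        statsmodels PHReg (ties="breslow") on the same grace-period data.

        PHReg reports the left-limit baseline cumulative hazard at each
        event time, so its value at the k-th event time equals ours at the
        (k-1)-th, after moving our baseline from the covariate means to
        x = 0.
        """
        covs = ("age", "sex", "spo2", "resp_rate", "creatinine")
        for arm in ARMS:
            X, dur, ev = censoring_process_data(sim_cloned, arm, covs)
            fit = fit_cox_breslow(X, dur, ev)
            ph = PHReg(dur, X, status=ev.astype(int), ties="breslow").fit()
            np.testing.assert_allclose(fit.coef, ph.params, atol=1e-6)

            times, cumhaz, _ = ph.baseline_cumulative_hazard[0]
            mine_at_zero = fit.baseline_cumhaz * np.exp(-fit.x_mean @ fit.coef)
            np.testing.assert_allclose(times, fit.baseline_times)
            np.testing.assert_allclose(cumhaz[1:], mine_at_zero[:-1], rtol=1e-8)

    def test_no_covariates_reduces_to_nelson_aalen(self):
        """With p=0 the baseline cumulative hazard is the Nelson-Aalen
        estimator of the censoring process."""
        dur = np.array([1, 1, 2, 2, 2, 2], dtype=float)
        ev = np.array([True, False, True, True, False, False])
        fit = fit_cox_breslow(np.empty((6, 0)), dur, ev)
        # day 1: 1 censoring / 6 at risk; day 2: 2 / 4 at risk
        np.testing.assert_allclose(fit.baseline_cumhaz, [1 / 6, 1 / 6 + 2 / 4])

    def test_null_effect_coefficients_near_zero(self, sim_models):
        """Covariates that do not drive treatment produce ~zero effects."""
        for arm in ARMS:
            coef = sim_models[arm].coefficients
            scale = np.array([15.0, 0.5, 6.0, 5.0, 0.5])  # rough covariate sds
            assert np.all(np.abs(coef.to_numpy() * scale) < 0.15)


class TestProbUncensored:
    def _manual_model(self, cumhaz, coef=()):
        p = len(coef)
        fit = CoxFit(coef=np.asarray(coef, float), x_mean=np.zeros(p),
                     baseline_times=np.array([2.0]),
                     baseline_cumhaz=np.array([cumhaz]),
                     loglik=0.0, n_events=1, n=10, converged=True)
        return CensoringModel("treated", tuple(f"x{i}" for i in range(p)), fit, 2)

    def test_zero_hazard_gives_one(self):
        model = self._manual_model(0.0)
        model.fit.baseline_times = np.array([])
        model.fit.baseline_cumhaz = np.array([])
        assert prob_uncensored(model, np.array([])) == 1.0

    def test_log_two_hazard_gives_half(self):
        model = self._manual_model(np.log(2.0))
        assert prob_uncensored(model, np.array([])) == pytest.approx(0.5)

    def test_doubling_relative_hazard_squares_probability(self):
        model = self._manual_model(0.3, coef=[np.log(2.0)])
        p1 = prob_uncensored(model, np.array([0.0]))
        p2 = prob_uncensored(model, np.array([1.0]))  # doubles exp(x beta)
        assert p2 == pytest.approx(p1 ** 2)

    def test_product_limit_matches_km_oracle(self):
        """Covariate-free censoring survival in product-limit form equals
        the Kaplan-Meier product over the same censoring events."""
        cohort = make_cohort([
            {"treatment_day": 1, "event_day": 9, "event_type": "death"},
            {"treatment_day": 2, "event_day": 8, "event_type": "discharge"},
            {"event_day": 10, "event_type": "death"},
            {"event_day": 7, "event_type": "discharge"},
            {"event_day": 1, "event_type": "death"},
        ])
        cloned = _cloned(cohort)
        model = fit_censoring_model(cloned, ARM_UNTREATED, covariates=())
        # censoring process, untreated arm: day 1 -> 1 censor / 5 at risk
        # (one patient exits with a day-1 death); day 2 -> 1 censor / 3
        expected = (1 - 1 / 5) * (1 - 1 / 3)
        got = model.prob_uncensored(np.empty((1, 0)), method="product-limit")
        assert got[0] == pytest.approx(expected, rel=1e-12)


class TestAttachWeights:
    def test_fixed_mode_inverts_probability(self, protocol):
        cohort = make_cohort([
            {"treatment_day": 1, "event_day": 9, "event_type": "death"},
            {"event_day": 10, "event_type": "discharge"},
        ])
        cloned = _cloned(cohort)
        fit = CoxFit(coef=np.zeros(0), x_mean=np.zeros(0),
                     baseline_times=np.array([2.0]),
                     baseline_cumhaz=np.array([np.log(2.0)]),
                     loglik=0.0, n_events=1, n=2, converged=True)
        models = {arm: CensoringModel(arm, (), fit, 2) for arm in ARMS}
        out = attach_weights(cloned, models, mode="fixed", method="exp")
        past = out.df[out.df["end_day"] > 2]
        assert np.allclose(past["weight"], 2.0)  # P = 1/2 everywhere
        within = out.df[out.df["end_day"] <= 2]
        assert np.allclose(within["weight"], 1.0)

    def test_degenerate_models_leave_analysis_unweighted(self, protocol):
        nobody = make_cohort([{"event_day": 9, "event_type": "death"},
                              {"event_day": 8, "event_type": "discharge"}])
        cloned = _cloned(nobody)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            models = {arm: fit_censoring_model(cloned, arm) for arm in ARMS}
        assert models[ARM_UNTREATED].degenerate  # nobody was ever treated
        out = attach_weights(cloned, models, mode="ladder")
        assert np.allclose(out.arm(ARM_UNTREATED)["weight"], 1.0)

    def test_missing_model_rejected(self, sim_cloned, sim_models):
        with pytest.raises(ValueError, match="missing censoring model"):
            attach_weights(sim_cloned, {ARM_TREATED: sim_models[ARM_TREATED]})

    def test_weights_at_least_one(self, sim_cloned, sim_models):
        for mode in ("ladder", "fixed"):
            out = attach_weights(sim_cloned, sim_models, mode=mode)
            assert (out.df["weight"] >= 1.0 - 1e-12).all()
            assert (out.df["w_post"] >= 1.0 - 1e-12).all()

    def test_zero_coefficients_give_equal_weights_within_arm(self, sim_cloned,
                                                             sim_models):
        models = {}
        for arm, m in sim_models.items():
            fit = CoxFit(coef=np.zeros_like(m.fit.coef), x_mean=m.fit.x_mean,
                         baseline_times=m.fit.baseline_times,
                         baseline_cumhaz=m.fit.baseline_cumhaz,
                         loglik=0.0, n_events=m.fit.n_events, n=m.fit.n,
                         converged=True)
            models[arm] = CensoringModel(arm, m.covariate_list, fit, 2)
        out = attach_weights(sim_cloned, models, mode="ladder")
        for arm in ARMS:
            past = out.arm(arm).query("end_day > 2")["weight"]
            assert past.nunique() == 1

    def test_ladder_mass_conservation(self, sim_cloned, sim_models):
        """Weighted pseudo-patients at risk after the grace period track the
        number of patients actually still in hospital then.

        The untreated arm reconstructs the count almost exactly.  In the
        treated arm, grace-period events sit in the day-g censoring risk
        set, so the inverse weight understates the survivors by the within-
        grace event mass (~10% here) — a structural feature of daily
        resolution, hence the looser band.
        """
        out = attach_weights(sim_cloned, sim_models, mode="ladder")
        alive_past_g = (sim_cloned.source.df["event_day"] > 2).sum()
        pseudo = {arm: out.arm(arm).query("end_day > 2")["w_post"].sum()
                  for arm in ARMS}
        assert pseudo[ARM_UNTREATED] == pytest.approx(alive_past_g, rel=0.03)
        assert pseudo[ARM_TREATED] == pytest.approx(alive_past_g, rel=0.15)

    def test_weighted_balance_after_grace(self, sim_cloned, sim_models):
        """Without confounding, weighting restores baseline covariate means
        among clones followed past the grace period."""
        out = attach_weights(sim_cloned, sim_models, mode="ladder")
        base = sim_cloned.source.df["spo2"].mean()
        for arm in ARMS:
            part = out.arm(arm).query("end_day > 2")
            w_mean = np.average(part["spo2"], weights=part["w_post"])
            assert w_mean == pytest.approx(base, abs=0.5)
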