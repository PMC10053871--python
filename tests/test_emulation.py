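"""Cloning, grace-period censoring rules, and person-day bookkeeping."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ttecr.cohort import baseline_table
from ttecr.emulate import (ARM_TREATED, ARM_UNTREATED, ProtocolConfig,
                           apply_grace_censoring, arm_status_counts,
                           clone_cohort, person_day_table)

from conftest import make_cohort


def _arm_row(cloned, arm, patient_id):
    part = cloned.arm(arm)
    return part[part["patient_id"] == patient_id].iloc[0]


class TestCloneCohort:
    def test_doubles_and_balances(self, fig1_cohort, protocol):
        cloned = clone_cohort(fig1_cohort, protocol)
        assert len(cloned) == 2 * len(fig1_cohort)
        for arm in (ARM_TREATED, ARM_UNTREATED):
            assert len(cloned.arm(arm)) == len(fig1_cohort)
        ba_t = baseline_table(cloned.arm(ARM_TREATED))
        ba_u = baseline_table(cloned.arm(ARM_UNTREATED))
        pd.testing.assert_frame_equal(ba_t, ba_u)

    def test_administrative_censoring_at_tau(self):
        cohort = make_cohort([{"event_day": 75, "event_type": "discharge"}])
        cloned = clone_cohort(cohort, ProtocolConfig(2, 60))
        assert (cloned.df["end_day"] == 60).all()
        assert (cloned.df["end_reason"] == "admin_censor").all()

    def test_protocol_validation(self):
        with pytest.raises(ValueError):
            ProtocolConfig(grace_period_days=0)
        with pytest.raises(ValueError):
            ProtocolConfig(grace_period_days=60, max_followup_days=60)


class TestGraceCensoring:
    def test_treated_within_grace(self, protocol):
        """Early initiator: outcome kept in the treated arm, the untreated
        clone censored at the treatment day."""
        cohort = make_cohort([{"treatment_day": 1, "event_day": 9,
                               "event_type": "discharge"}])
        cloned = apply_grace_censoring(clone_cohort(cohort, protocol))
        t = _arm_row(cloned, ARM_TREATED, 1)
        u = _arm_row(cloned, ARM_UNTREATED, 1)
        assert (t.end_day, t.end_reason, t.event_type) == (9, "event", "discharge")
        assert (u.end_day, u.end_reason) == (1, "artificial_censor")

    def test_never_treated(self, protocol):
        """Non-initiator: outcome kept untreated, treated clone cut at day g."""
        cohort = make_cohort([{"event_day": 10, "event_type": "death"}])
        cloned = apply_grace_censoring(clone_cohort(cohort, protocol))
        t = _arm_row(cloned, ARM_TREATED, 1)
        u = _arm_row(cloned, ARM_UNTREATED, 1)
        assert (t.end_day, t.end_reason) == (2, "artificial_censor")
        assert (u.end_day, u.end_reason, u.event_type) == (10, "event", "death")

    def test_event_inside_grace_counts_in_both_arms(self, protocol):
        cohort = make_cohort([{"event_day": 1, "event_type": "death"}])
        cloned = apply_grace_censoring(clone_cohort(cohort, protocol))
        for arm in (ARM_TREATED, ARM_UNTREATED):
            row = _arm_row(cloned, arm, 1)
            assert (row.end_day, row.end_reason, row.event_type) == (1, "event", "death")

    def test_same_day_treatment_and_event_tie_break(self, protocol):
        """Treatment is deemed to precede a same-day event, so the untreated
        clone is censored and only the treated arm keeps the event."""
        cohort = make_cohort([{"treatment_day": 2, "event_day": 2,
                               "event_type": "death"}])
        cloned = apply_grace_censoring(clone_cohort(cohort, protocol))
        t = _arm_row(cloned, ARM_TREATED, 1)
        u = _arm_row(cloned, ARM_UNTREATED, 1)
        assert (t.end_day, t.end_reason, t.event_type) == (2, "event", "death")
        assert (u.end_day, u.end_reason) == (2, "artificial_censor")

    def test_late_treatment_counts_as_untreated(self, protocol):
        cohort = make_cohort([{"treatment_day": 5, "event_day": 9,
                               "event_type": "death"}])
        cloned = apply_grace_censoring(clone_cohort(cohort, protocol))
        t = _arm_row(cloned, ARM_TREATED, 1)
        u = _arm_row(cloned, ARM_UNTREATED, 1)
        assert (t.end_day, t.end_reason) == (2, "artificial_censor")
        assert (u.end_day, u.end_reason, u.event_type) == (9, "event", "death")

    def test_double_censoring_rejected(self, fig1_cohort, protocol):
        cloned = apply_grace_censoring(clone_cohort(fig1_cohort, protocol))
        with pytest.raises(RuntimeError):
            apply_grace_censoring(cloned)


class TestArmStatusCounts:
    def test_complementary_counts(self, fig1_cohort, protocol):
        cloned = apply_grace_censoring(clone_cohort(fig1_cohort, protocol))
        counts = arm_status_counts(cloned).set_index("arm")
        n = len(fig1_cohort)
        assert (counts["followed"] + counts["artificially_censored"] == n).all()
        # no grace-period events here, so the arms mirror each other
        assert counts.loc[ARM_TREATED, "followed"] == \
            counts.loc[ARM_UNTREATED, "artificially_censored"] == 4

    def test_degenerate_uptake(self, protocol):
        nobody = make_cohort([{"event_day": 9, "event_type": "death"},
                              {"event_day": 8, "event_type": "discharge"}])
        counts = arm_status_counts(
            apply_grace_censoring(clone_cohort(nobody, protocol))).set_index("arm")
        assert counts.loc[ARM_TREATED, "followed"] == 0

        everyone = make_cohort([{"treatment_day": 1, "event_day": 9,
                                 "event_type": "death"},
                                {"treatment_day": 1, "event_day": 8,
                                 "event_type": "discharge"}])
        counts = arm_status_counts(
            apply_grace_censoring(clone_cohort(everyone, protocol))).set_index("arm")
        assert counts.loc[ARM_UNTREATED, "followed"] == 0


class TestPersonDayTable:
    def test_rows_and_indicators(self, protocol):
        cohort = make_cohort([{"event_day": 3, "event_type": "death"},
                              {"treatment_day": 1, "event_day": 6,
                               "event_type": "discharge"}])
        cloned = apply_grace_censoring(clone_cohort(cohort, protocol))
        table = person_day_table(cloned)
        assert len(table) == cloned.df["end_day"].sum()

        death_clone = table[(table["patient_id"] == 1) & (table["arm"] == ARM_UNTREATED)]
        assert list(death_clone["death"]) == [0, 0, 1]
        assert list(death_clone["discharge"]) == [0, 0, 0]

        censored = table[(table["patient_id"] == 2) & (table["arm"] == ARM_UNTREATED)]
        assert len(censored) == 1  # censored at treatment on day 1
        assert censored[["death", "discharge"]].to_numpy().sum() == 0

    def test_event_totals_match_clone_level(self, fig1_cohort, protocol):
        cloned = apply_grace_censoring(clone_cohort(fig1_cohort, protocol))
        table = person_day_table(cloned)
        for arm in (ARM_TREATED, ARM_UNTREATED):
            part = cloned.arm(arm)
            tab = table[table["arm"] == arm]
            for cause in ("death", "discharge"):
                clone_events = (part["event_type"] == cause).sum()
                assert tab[cause].sum() == clone_events


@st.composite
def patients(draw):
    event_day = draw(st.integers(1, 80))
    treated = draw(st.booleans())
    treatment_day = draw(st.integers(1, event_day)) if treated else None
    event_type = draw(st.sampled_from(["death", "discharge"]))
    return {"treatment_day": treatment_day, "event_day": event_day,
            "event_type": event_type}


class TestCensoringInvariants:
    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(st.lists(patients(), min_size=1, max_size=25))
    def test_per_patient_bookkeeping(self, rows):
        """Two clones per patient; exactly one arm censored unless the
        terminal event fell inside the grace period before treatment."""
        protocol = ProtocolConfig(2, 60)
        cohort = make_cohort(rows)
        cloned = apply_grace_censoring(clone_cohort(cohort, protocol))
        df = cloned.df
        g = protocol.grace_period_days
        assert len(df) == 2 * len(rows)
        for pid, grp in df.groupby("patient_id"):
            assert set(grp["arm"]) == {ARM_TREATED, ARM_UNTREATED}
            art = (grp["end_reason"] == "artificial_censor").sum()
            src = cohort.df[cohort.df["patient_id"] == pid].iloc[0]
            t = src["treatment_day"]
            grace_event = (src["event_day"] <= g) and (pd.isna(t) or t > g)
            assert art == (0 if grace_event else 1)
            art_rows = grp[grp["end_reason"] == "artificial_censor"]
            assert (art_rows["end_day"] <= g).all()
        table = person_day_table(cloned)
        assert len(table) == df["end_day"].sum()
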