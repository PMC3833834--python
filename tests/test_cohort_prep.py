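"""Eligibility, interval discretisation, LOCF and LTFU censoring."""

import numpy as np
import pandas as pd
import pytest

from artstart import (SimParams, generate_cohort, filter_eligible, discretise,
                      apply_locf, flag_ltfu)
from conftest import make_raw


def one_child_raw(**kw):
    child = {"id": 0, "age": 3.0,
             "visits": [(0.0, 900, 30, -1.0), (3.0, 850, 28, -1.1)]}
    child.update(kw)
    return make_raw([child])


class TestFilterEligible:
    def test_age_window(self):
        raw = make_raw([
            {"id": 0, "age": 23.9 / 12, "visits": [(0, 900, 30, -1), (3, 800, 28, -1)]},
            {"id": 1, "age": 24.0 / 12, "visits": [(0, 900, 30, -1), (3, 800, 28, -1)]},
            {"id": 2, "age": 60.0 / 12, "visits": [(0, 900, 30, -1), (3, 800, 28, -1)]},
            {"id": 3, "age": 60.1 / 12, "visits": [(0, 900, 30, -1), (3, 800, 28, -1)]},
        ])
        out, log = filter_eligible(raw)
        assert sorted(out.baseline.child) == [1, 2]
        assert log["age_ineligible"] == 2

    def test_not_art_naive_excluded(self):
        raw = make_raw([
            {"id": 0, "art_start": -2.0,
             "visits": [(0, 900, 30, -1), (3, 800, 28, -1)]},
            {"id": 1, "art_start": 6.0,
             "visits": [(0, 900, 30, -1), (3, 800, 28, -1)]},
        ])
        out, log = filter_eligible(raw)
        assert list(out.baseline.child) == [1]
        assert log["not_art_naive"] == 1

    def test_no_followup_excluded(self):
        raw = make_raw([
            {"id": 0, "visits": [(0, 900, 30, -1)]},
            {"id": 1, "visits": [(0, 900, 30, -1), (1.1, 880, 29, -1)]},
        ])
        out, log = filter_eligible(raw)
        assert list(out.baseline.child) == [1]
        assert log["no_followup"] == 1


class TestDiscretise:
    def test_closest_to_nominal_wins(self):
        raw = one_child_raw(visits=[(0.0, 900, 30, -1.0), (5.0, 700, 25, -1.2),
                                    (6.8, 650, 24, -1.3)])
        panel = discretise(raw)
        row = panel.data.query("child == 0 and t == 6.0").iloc[0]
        assert row.cd4 == 650  # |6.8-6| = 0.8 beats |5.0-6| = 1.0

    def test_tie_breaks_to_earlier(self):
        raw = one_child_raw(visits=[(0.0, 900, 30, -1.0), (5.2, 700, 25, -1.2),
                                    (6.8, 650, 24, -1.3)])
        panel = discretise(raw)
        row = panel.data.query("child == 0 and t == 6.0").iloc[0]
        assert row.cd4 == 700  # 0.8 vs 0.8 -> earlier observation wins

    def test_death_bookkeeping(self):
        raw = one_child_raw(death_month=7.5)
        panel = discretise(raw)
        d = panel.data.query("child == 0")
        assert d.loc[d.t == 9.0, "death"].item() == 1
        assert d.t.max() == 9.0  # absorbing: no rows after the death row
        assert np.isnan(d.loc[d.t == 9.0, "cd4"].item())

    def test_art_indicator_from_next_grid_time(self):
        raw = one_child_raw(art_start=4.0)
        panel = discretise(raw)
        d = panel.data.query("child == 0").set_index("t")["art"]
        assert d.loc[3.0] == 0 and d.loc[6.0] == 1 and d.loc[36.0] == 1

    def test_empty_window_is_missing(self):
        raw = one_child_raw()
        panel = discretise(raw)
        assert np.isnan(panel.data.query("child == 0 and t == 12.0")["cd4"].item())

    def test_beyond_horizon_warns(self):
        raw = one_child_raw(visits=[(0.0, 900, 30, -1.0), (3.0, 850, 28, -1.1),
                                    (40.0, 800, 27, -1.2)])
        with pytest.warns(UserWarning, match="beyond the horizon"):
            discretise(raw)


class TestLocf:
    def test_nine_month_window(self):
        raw = one_child_raw(visits=[(0.0, 900, 30, -1.0), (3.0, 850, 28, -1.1)])
        panel = apply_locf(discretise(raw))
        d = panel.data.query("child == 0").set_index("t")
        # observed at 3; gaps 3, 6, 9 filled; gap 12 not
        for t in (6.0, 9.0, 12.0):
            assert d.loc[t, "cd4"] == 850 and d.loc[t, "carried_cd4"]
        assert np.isnan(d.loc[15.0, "cd4"]) and not d.loc[15.0, "carried_cd4"]

    def test_no_backward_carry(self):
        raw = make_raw([{"id": 0, "visits": [(0.0, np.nan, np.nan, np.nan),
                                             (3.0, 850, 28, -1.1)]}])
        panel = apply_locf(discretise(raw))
        d = panel.data.query("child == 0").set_index("t")
        assert np.isnan(d.loc[0.0, "cd4"]) and not d.loc[0.0, "carried_cd4"]

    def test_fully_observed_unchanged(self):
        p = SimParams(n_children=30, seed=9, missing_rate=0.0,
                      ltfu_hazard=0.0, visit_jitter=0.0)
        panel = discretise(generate_cohort(p))
        out = apply_locf(panel)
        carried = out.data[["carried_cd4", "carried_cd4pct", "carried_waz"]]
        alive = out.data["death"] == 0
        assert not carried[alive].any().any()
        pd.testing.assert_frame_equal(out.data[alive][["cd4", "cd4pct", "waz"]],
                                      panel.data[alive][["cd4", "cd4pct", "waz"]])


class TestFlagLtfu:
    def test_ltfu_rule(self):
        base_visits = [(0.0, 900, 30, -1.0), (3.0, 850, 28, -1.1)]
        raw = make_raw([
            {"id": 0, "visits": base_visits, "last_contact": 27.4},  # 10.1 mo before closure
            {"id": 1, "visits": base_visits, "last_contact": 29.5},  # 8 mo before closure
            {"id": 2, "visits": base_visits, "last_contact": 3.0, "death_month": 7.5},
        ])
        panel = flag_ltfu(apply_locf(discretise(raw)), closure=37.5)
        d = panel.data
        c0 = d.query("child == 0")
        assert c0.censor.max() == 1
        assert c0.loc[c0.censor == 1, "t"].item() == 30.0  # first grid after contact
        assert c0.loc[c0.censor == 1, "censor_reason"].item() == "ltfu"
        assert d.query("child == 1").censor.max() == 0  # inside the 9-month window
        c2 = d.query("child == 2")
        assert c2.censor.max() == 0 and c2.death.max() == 1  # death beats censoring

    def test_closure_before_horizon(self):
        raw = make_raw([{"id": 0, "visits": [(0.0, 900, 30, -1.0), (3.0, 850, 28, -1.1)],
                         "last_contact": 18.0}])
        panel = flag_ltfu(apply_locf(discretise(raw)), closure=20.0)
        d = panel.data.query("child == 0")
        assert d.loc[d.censor == 1, "t"].item() == 21.0
        assert d.loc[d.censor == 1, "censor_reason"].item() == "admin"


class TestRoundTrip:
    def test_jitter_free_cohort_matches_truth(self):
        """With visits exactly on the grid and no observation noise the
        discretised panel reproduces the generator's internal truth table."""
        p = SimParams(n_children=150, seed=5, missing_rate=0.0,
                      ltfu_hazard=0.0, visit_jitter=0.0)
        coh = generate_cohort(p, return_truth=True)
        panel = discretise(coh)
        got = (panel.data[["child", "t", "cd4", "cd4pct", "waz", "art", "death"]]
               .sort_values(["child", "t"]).reset_index(drop=True))
        want = (coh.truth[["child", "t", "cd4", "cd4pct", "waz", "art", "death"]]
                .sort_values(["child", "t"]).reset_index(drop=True))
        pd.testing.assert_frame_equal(got, want, check_dtype=False)

    def test_panel_invariants_on_generated_data(self):
        p = SimParams(n_children=300, seed=13)
        coh, _ = filter_eligible(generate_cohort(p))
        panel = flag_ltfu(apply_locf(discretise(coh)), closure=37.5)
        panel.validate()  # absorbing death/censor, monotone ART, carried flags
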