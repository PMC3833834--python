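"""EM-bootstrap multiple imputation and Rubin's rules."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from artstart import (SimParams, generate_cohort, filter_eligible, discretise,
                      apply_locf, flag_ltfu, ImputationSpec, impute_panel,
                      build_imputation_matrix, em_mvnorm, em_bootstrap_impute,
                      rubin_combine)


@pytest.fixture(scope="module")
def locf_panel():
    p = SimParams(n_children=250, seed=21, missing_rate=0.25)
    coh, _ = filter_eligible(generate_cohort(p))
    return flag_ltfu(apply_locf(discretise(coh)), closure=37.5)


class TestBuildMatrix:
    def test_sqrt_transform(self, locf_panel):
        df, colmap = build_imputation_matrix(locf_panel)
        d0 = locf_panel.data.query("t == 0")
        child = d0.loc[d0.cd4.notna(), "child"].iloc[0]
        cd4 = d0.set_index("child").loc[child, "cd4"]
        assert df.loc[child, "sqrt_cd4_t0"] == pytest.approx(np.sqrt(cd4))

    def test_complete_round_trip(self):
        """A panel without missing cells maps to a complete matrix and the
        inverse map reproduces it exactly (no cells altered)."""
        p = SimParams(n_children=80, seed=3, missing_rate=0.0, ltfu_hazard=0.0)
        coh, _ = filter_eligible(generate_cohort(p))
        panel = flag_ltfu(apply_locf(discretise(coh)), closure=37.5)
        out = impute_panel(panel, ImputationSpec(m=3), seed=0)
        assert out.m == 3
        for imp in out.panels:
            a = imp.data.sort_values(["child", "t"]).reset_index(drop=True)
            b = panel.data.sort_values(["child", "t"]).reset_index(drop=True)
            pd.testing.assert_frame_equal(a[["cd4", "cd4pct", "waz"]],
                                          b[["cd4", "cd4pct", "waz"]])

    def test_long_layout_lags(self, locf_panel):
        df, _ = build_imputation_matrix(locf_panel, ImputationSpec(layout="long"))
        child = locf_panel.data.child.iloc[0]
        v3 = df.loc[(child, 3.0), "sqrt_cd4"]
        lag6 = df.loc[(child, 6.0), "sqrt_cd4_lag1"]
        if np.isnan(v3):
            assert np.isnan(lag6)
        else:
            assert lag6 == pytest.approx(v3)
        lead3 = df.loc[(child, 3.0), "sqrt_cd4_lead1"]
        v6 = df.loc[(child, 6.0), "sqrt_cd4"]
        assert (np.isnan(lead3) and np.isnan(v6)) or lead3 == pytest.approx(v6)


class TestEm:
    def test_monotone_loglik(self):
        rng = np.random.default_rng(0)
        x = rng.multivariate_normal([0, 0, 0], np.array([[1, .5, .2], [.5, 1, .4],
                                                         [.2, .4, 1.]]), size=400)
        x[rng.random(400) < 0.3, 0] = np.nan
        x[rng.random(400) < 0.2, 2] = np.nan
        fit = em_mvnorm(x, track_loglik=True)
        lls = np.asarray(fit["loglik_trace"])
        assert np.all(np.diff(lls) >= -1e-6)
        assert fit["converged"]

    def test_requires_observed_rows(self):
        x = np.full((5, 2), np.nan)
        x[:, 0] = 1.0
        with pytest.raises(ValueError):
            em_mvnorm(x)

    def test_bivariate_recovery(self):
        """rho=0.8 fixture: imputed mean/variance track the pre-masking data."""
        rng = np.random.default_rng(7)
        n = 2000
        full = rng.multivariate_normal([0, 0], [[1, .8], [.8, 1]], size=n)
        masked = full.copy()
        masked[rng.random(n) < 0.2, 1] = np.nan
        comp, diags = em_bootstrap_impute(pd.DataFrame(masked, columns=["x", "y"]),
                                          ImputationSpec(m=10), seed=1)
        assert len(comp) == 10
        mean = np.mean([c["y"].mean() for c in comp])
        var = np.mean([c["y"].var(ddof=1) for c in comp])
        assert abs(mean - full[:, 1].mean()) < 0.05 * full[:, 1].std()
        assert abs(var - full[:, 1].var(ddof=1)) < 0.05 * full[:, 1].var(ddof=1)

    def test_fully_observed_short_circuit(self):
        df = pd.DataFrame({"a": [1.0, 2, 3], "b": [4.0, 5, 6]})
        comp, diags = em_bootstrap_impute(df, ImputationSpec(m=4), seed=0)
        assert all(c.equals(df) for c in comp)

    def test_m_defaults_to_ten(self):
        assert ImputationSpec().m == 10


class TestImputePanel:
    def test_observed_cells_never_altered(self, locf_panel):
        out = impute_panel(locf_panel, ImputationSpec(m=3), seed=5)
        orig = locf_panel.data.sort_values(["child", "t"]).reset_index(drop=True)
        for imp in out.panels:
            d = imp.data.sort_values(["child", "t"]).reset_index(drop=True)
            for c in ("cd4", "cd4pct", "waz"):
                obs = orig[c].notna()
                np.testing.assert_allclose(d.loc[obs, c], orig.loc[obs, c])

    def test_no_missing_remains_and_bounds(self, locf_panel):
        out = impute_panel(locf_panel, ImputationSpec(m=3), seed=5)
        for imp in out.panels:
            alive = imp.data["death"] == 0
            assert not imp.data.loc[alive, ["cd4", "cd4pct", "waz"]].isna().any().any()
            assert (imp.data.loc[alive, "cd4"] >= 0).all()
            assert imp.data.loc[alive, "cd4pct"].between(0, 100).all()
            assert not imp.baseline[["cd4_0", "cd4pct_0", "waz_0", "haz_0"]].isna().any().any()

    def test_imputations_differ_across_m(self, locf_panel):
        out = impute_panel(locf_panel, ImputationSpec(m=2), seed=5)
        a, b = (p.data.sort_values(["child", "t"]).reset_index(drop=True)
                for p in out.panels)
        was_missing = locf_panel.data.sort_values(["child", "t"]).reset_index(drop=True)["cd4"].isna()
        alive = a["death"] == 0
        sel = was_missing & alive
        if sel.sum() > 3:
            assert not np.allclose(a.loc[sel, "cd4"], b.loc[sel, "cd4"])


class TestRubin:
    def test_hand_example(self):
        pooled, total, between, within = rubin_combine([0.02, 0.04], [0.0, 0.0])
        assert pooled == pytest.approx(0.03)
        assert between == pytest.approx(2e-4)
        assert total == pytest.approx(3e-4)

    def test_identical_estimates(self):
        pooled, total, between, within = rubin_combine([0.1] * 5, [0.02] * 5)
        assert between == 0.0 and total == pytest.approx(0.02)

    def test_single_imputation(self):
        pooled, total, between, _ = rubin_combine([0.5], [0.01])
        assert pooled == 0.5 and total == 0.01 and between == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            rubin_combine([], [])

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.tuples(st.floats(-10, 10), st.floats(0, 5)),
                    min_size=1, max_size=8))
    def test_pooling_properties(self, pairs):
        est = [p[0] for p in pairs]
        wv = [p[1] for p in pairs]
        pooled, total, between, within = rubin_combine(est, wv)
        assert pooled == pytest.approx(np.mean(est))
        assert total >= within - 1e-12 and between >= 0.0


class TestOverimpute:
    def test_overimputation_rmse_scale(self):
        """Hidden observed cells are re-imputed to within the conditional
        SD implied by the correlation structure."""
        from artstart.imputation import overimpute
        rng = np.random.default_rng(12)
        n = 1500
        full = rng.multivariate_normal([0, 0], [[1, .8], [.8, 1]], size=n)
        masked = full.copy()
        masked[rng.random(n) < 0.1, 1] = np.nan
        df = pd.DataFrame(masked, columns=["x", "y"])
        diag = overimpute(df, ImputationSpec(m=3), seed=2, frac=0.1)
        # conditional SD of y given x is sqrt(1 - 0.8^2) = 0.6
        assert diag["y"]["rmse"] < 0.8
        assert diag["y"]["n_hidden"] > 50
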