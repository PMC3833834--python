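"""P-spline additive models, GCV selection, and per-time model sets."""

import numpy as np
import pandas as pd
import pytest
from dataclasses import replace

from artstart import (SimParams, StateLogit, TransitionCoefs, generate_cohort,
                      filter_eligible, discretise, apply_locf, flag_ltfu,
                      SmoothTerm, pspline_design, AdditiveSpec, fit_additive,
                      gcv_select, ModelRecipe, fit_model_set)
from artstart.regime_models import PSplineBasis, DegenerateBasisError
from artstart.experiments import randomised_params, prepare_panel


class TestPsplineDesign:
    def test_degenerate_covariate(self):
        with pytest.raises(DegenerateBasisError):
            pspline_design(np.ones(50), SmoothTerm("x"))

    def test_shapes_and_centring(self):
        rng = np.random.default_rng(0)
        x = rng.random(200)
        design, penalty = pspline_design(x, SmoothTerm("x", n_basis=8))
        assert design.shape == (200, 7)  # one column lost to the constraint
        assert penalty.shape == (7, 7)
        assert abs(design.sum(axis=0)).max() < 1e-8  # sum-to-zero over the data

    def test_huge_lambda_is_linear(self):
        """An order-2 difference penalty shrinks the smooth to a straight
        line, so the penalized fit matches ordinary least squares."""
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 10, 300)
        y = 2.0 + 0.5 * x + rng.normal(0, 0.3, 300)
        df = pd.DataFrame({"x": x})
        fit = fit_additive(df, y, AdditiveSpec(smooth=(SmoothTerm("x", lam=1e8),)),
                           search=False)
        beta = np.polyfit(x, y, 1)
        ols_pred = beta[1] + beta[0] * x
        assert np.abs(fit.predict(df) - ols_pred).max() < 1e-4

    def test_zero_lambda_interpolates(self):
        x = np.linspace(0, 1, 10)
        y = np.sin(2 * np.pi * x)
        df = pd.DataFrame({"x": x})
        fit = fit_additive(df, y, AdditiveSpec(smooth=(SmoothTerm("x", n_basis=12, lam=0.0),)),
                           search=False, ridge=1e-12)
        assert np.abs(fit.predict(df) - y).max() < 1e-6

    def test_gcv_recovers_sine(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(0, 2 * np.pi, 500)
        y = np.sin(x) + rng.normal(0, 0.1, 500)
        df = pd.DataFrame({"x": x})
        fit = fit_additive(df, y, AdditiveSpec(smooth=(SmoothTerm("x", n_basis=12),)))
        rmse = np.sqrt(np.mean((fit.predict(df) - np.sin(x)) ** 2))
        assert rmse < 0.05

    def test_linear_extrapolation(self):
        x = np.linspace(0, 1, 100)
        basis = PSplineBasis(x, SmoothTerm("x"))
        inside = basis.design(np.array([0.9, 1.0]))
        out = basis.design(np.array([1.1, 1.2]))
        slope = out[1] - out[0]
        # beyond the boundary the basis continues along its tangent
        np.testing.assert_allclose(out[0] + slope, out[1], atol=1e-10)
        np.testing.assert_allclose(basis.design(np.array([1.0])), inside[1:2], atol=1e-12)


class TestFitAdditive:
    def test_constant_target(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame({"x": rng.random(100)})
        y = np.full(100, 4.2)
        fit = fit_additive(df, y, AdditiveSpec(smooth=(SmoothTerm("x"),)))
        assert fit.sigma == pytest.approx(0.0, abs=1e-6)
        np.testing.assert_allclose(fit.predict(df), 4.2, atol=1e-8)

    def test_mean_preservation_gaussian(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame({"x": rng.random(400), "z": rng.random(400)})
        y = df.x * 2 + np.sin(6 * df.z) + rng.normal(0, 0.5, 400)
        fit = fit_additive(df, y.to_numpy(),
                           AdditiveSpec(linear=("x",), smooth=(SmoothTerm("z"),)))
        assert fit.predict(df).mean() == pytest.approx(y.mean(), abs=1e-8)

    def test_mean_preservation_binomial(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame({"x": rng.random(600)})
        y = (rng.random(600) < 0.2 + 0.3 * df.x).astype(float)
        fit = fit_additive(df, y.to_numpy(),
                           AdditiveSpec(smooth=(SmoothTerm("x"),), family="binomial"))
        p = fit.predict(df)
        assert np.all((p > 0) & (p < 1))
        assert p.mean() == pytest.approx(y.mean(), abs=1e-6)

    def test_constant_binomial_response_rejected(self):
        from artstart.regime_models import FittingError
        df = pd.DataFrame({"x": np.random.default_rng(0).random(50)})
        with pytest.raises(FittingError):
            fit_additive(df, np.zeros(50),
                         AdditiveSpec(smooth=(SmoothTerm("x"),), family="binomial"))


class TestGcvSelect:
    def _simulate(self, rng, n, interaction_effect):
        x = rng.uniform(-1, 1, n)
        g = (rng.random(n) < 0.5).astype(float)
        y = 1.0 + x + interaction_effect * x * g + rng.normal(0, 1.0, n)
        return pd.DataFrame({"x": x, "g": g}), y

    def test_null_interaction_rejected(self):
        """Without a category-specific slope the plain model wins GCV."""
        rng = np.random.default_rng(6)
        base = AdditiveSpec(linear=("g",), smooth=(SmoothTerm("x", n_basis=6),))
        wins = 0
        for _ in range(100):
            df, y = self._simulate(rng, 1000, 0.0)
            best = gcv_select([base, base.with_interaction(SmoothTerm("x", n_basis=6), "g")],
                              df, y)
            wins += all(t.by is None for t in best.design.smooth)
        assert wins >= 90

    def test_strong_interaction_detected(self):
        rng = np.random.default_rng(7)
        base = AdditiveSpec(linear=("g",), smooth=(SmoothTerm("x", n_basis=6),))
        wins = 0
        for _ in range(100):
            # category-specific slope far above the noise level
            df, y = self._simulate(rng, 1000, 1.0)
            best = gcv_select([base, base.with_interaction(SmoothTerm("x", n_basis=6), "g")],
                              df, y)
            wins += any(t.by is not None for t in best.design.smooth)
        assert wins >= 90

    def test_tie_breaks_to_first(self):
        rng = np.random.default_rng(8)
        df = pd.DataFrame({"x": rng.random(200)})
        y = df.x.to_numpy() + rng.normal(0, 0.1, 200)
        spec = AdditiveSpec(smooth=(SmoothTerm("x", lam=1.0),))
        a = gcv_select([spec, spec], df, y)
        b = fit_additive(df, y, spec, search=False)
        assert a.gcv == b.gcv


@pytest.fixture(scope="module")
def randomized_panel():
    return prepare_panel(randomised_params(2500, seed=31))


class TestModelSet:
    def test_ar_coefficient_recovery(self):
        """sqrt-CD4 transitions: slope and residual SD recovered."""
        rng = np.random.default_rng(9)
        n = 2000
        lag = rng.uniform(5, 40, n)
        y = 0.9 * lag + rng.normal(0, 2.0, n)
        df = pd.DataFrame({"lag": lag})
        fit = fit_additive(df, y, AdditiveSpec(smooth=(SmoothTerm("lag"),)))
        x1, x2 = 15.0, 30.0
        slope = (fit.predict(pd.DataFrame({"lag": [x2]}))[0]
                 - fit.predict(pd.DataFrame({"lag": [x1]}))[0]) / (x2 - x1)
        assert 0.85 <= slope <= 0.95
        assert 1.8 <= fit.sigma <= 2.2

    def test_waz_art_effect_recovery(self):
        """A +1.5 ART shift added to the WAZ transition is recovered within
        two standard errors by the WAZ confounder model."""
        p = replace(randomised_params(3000, seed=17),
                    waz_trans=TransitionCoefs(0.72, -0.518, 1.5, 0.60))
        panel = prepare_panel(p)
        ms = fit_model_set(panel)
        ests = []
        for t in (6.0, 12.0, 18.0, 24.0):
            m = ms.model(t, "waz")
            est, se = m.linear_coef("art_lag")
            ests.append((est, se))
        pooled = np.mean([e for e, s in ests])
        pooled_se = np.sqrt(np.mean([s ** 2 for e, s in ests]) / len(ests))
        assert abs(pooled - 1.5) <= 2 * pooled_se + 0.1

    def test_null_art_death_coefficient(self):
        """Randomised treatment with a null effect: the pooled death model's
        ART log-odds is near zero."""
        panel = prepare_panel(randomised_params(10000, seed=19, art_effect=1.0))
        ms = fit_model_set(panel)
        dm = ms.model(3.0, "death")
        est, se = dm.linear_coef("art_lag")
        assert abs(est) <= 0.2 + 2 * se

    def test_model_set_complete_and_fallback(self, randomized_panel):
        ms = fit_model_set(randomized_panel)
        assert ms.complete
        # with ~30 deaths in total the per-time death fits are all pooled
        assert all(ms.models[t]["death"].pooled for t in ms.models)

    def test_pooled_vs_per_time_predictions_agree(self, randomized_panel):
        """The generator is time-homogeneous, so pooled-with-time-smooth and
        per-time confounder fits give similar predictions."""
        from artstart.regime_models import make_fit_frame
        ms = fit_model_set(randomized_panel)
        pooled = fit_model_set(randomized_panel, ModelRecipe(min_rows=10 ** 9))
        frame = make_fit_frame(randomized_panel)
        frame = frame[(frame.t == 12.0) & (frame.death == 0)].dropna()
        a = ms.model(12.0, "sqrt_cd4").predict(frame)
        b = pooled.model(12.0, "sqrt_cd4").predict(frame)
        scale = np.std(frame["sqrt_cd4"])
        assert np.mean(np.abs(a - b)) < 0.10 * scale


class TestOverfittingGuard:
    def test_noise_covariates_do_not_degrade_out_of_sample(self):
        """Adding pure-noise smooth covariates must not worsen held-out
        RMSE by more than noise (GCV guards against overfitting)."""
        rng = np.random.default_rng(11)
        n = 1200
        x = rng.uniform(0, 1, n)
        noise1, noise2 = rng.random(n), rng.random(n)
        y = np.sin(4 * x) + rng.normal(0, 0.3, n)
        df = pd.DataFrame({"x": x, "n1": noise1, "n2": noise2})
        train, test = slice(0, 800), slice(800, None)
        base = fit_additive(df.iloc[train], y[train],
                            AdditiveSpec(smooth=(SmoothTerm("x"),)))
        noisy = fit_additive(df.iloc[train], y[train],
                             AdditiveSpec(smooth=(SmoothTerm("x"), SmoothTerm("n1"),
                                                  SmoothTerm("n2"))))
        rmse_base = np.sqrt(np.mean((base.predict(df.iloc[test]) - y[test]) ** 2))
        rmse_noisy = np.sqrt(np.mean((noisy.predict(df.iloc[test]) - y[test]) ** 2))
        assert rmse_noisy <= rmse_base + 0.05


class TestModelSummary:
    def test_summary_serialisable(self, randomized_panel):
        import json
        ms = fit_model_set(randomized_panel)
        s = ms.summary()
        json.dumps(s)  # must be JSON-serialisable
        assert "t36" in s and "death" in s["t36"]
        assert s["t36"]["sqrt_cd4"]["sigma"] > 0
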