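"""Range regressions: fitting, VIF, AIC selection, means and correlations."""

import numpy as np
import pandas as pd
import pytest

from itvar.ranges import (
    RangeDesign,
    RangeRegression,
    backward_select,
    build_range_design,
    exhaustive_select,
    mean_itv_correlation,
    mean_trait_response,
    vif,
)


def _design(n=60, p=3, seed=0, coefs=None, noise=0.5):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(rng.standard_normal((n, p)), columns=[f"x{j}" for j in range(p)])
    beta = np.zeros(p) if coefs is None else np.asarray(coefs, float)
    y = pd.Series(X.to_numpy() @ beta + noise * rng.standard_normal(n))
    return RangeDesign(y, X)


class TestBuildDesign:
    def _tables(self, n_species=10):
        species = [f"sp{i}" for i in range(n_species)]
        rng = np.random.default_rng(3)
        resp = pd.DataFrame({"species": species, "log_itv_star": rng.normal(-3, 0.5, n_species)})
        ranges = pd.DataFrame(
            {
                "species": species,
                "pet_range": rng.uniform(100, 500, n_species),
                "elevation_range": rng.uniform(50, 800, n_species),
                "geology_count": rng.integers(1, 5, n_species),
            }
        )
        return resp, ranges

    def test_shape_and_standardization(self):
        resp, ranges = self._tables()
        d = build_range_design(resp, ranges, ("pet_range", "elevation_range", "geology_count"))
        assert d.X.shape == (10, 3)
        np.testing.assert_allclose(d.X.mean(), 0.0, atol=1e-12)
        np.testing.assert_allclose(d.X.std(ddof=1), 1.0, rtol=1e-12)

    def test_unmatched_species_dropped(self, caplog):
        resp, ranges = self._tables()
        d = build_range_design(resp.iloc[:-1], ranges, ("pet_range", "elevation_range"))
        assert len(d.y) == 9

    def test_under_determined_raises(self):
        resp, ranges = self._tables(n_species=4)
        with pytest.raises(ValueError, match="under-determined"):
            build_range_design(resp, ranges, ("pet_range", "elevation_range", "geology_count"))


class TestFit:
    def test_noiseless_exact_recovery(self):
        d = _design(n=50, p=2, coefs=[2.0, -1.0], noise=1e-8)
        fit = RangeRegression(d).fit(seed=1)
        assert fit.params["x0"] == pytest.approx(2.0, abs=1e-3)
        assert fit.params["x1"] == pytest.approx(-1.0, abs=1e-3)
        assert fit.r2 == pytest.approx(1.0, abs=1e-6)

    def test_duplicate_column_collinearity_error(self):
        d = _design(n=30, p=2)
        X = d.X.copy()
        X["dup"] = X["x0"]
        with pytest.raises(ValueError, match="singular|collinear"):
            RangeRegression(RangeDesign(d.y, X))

    def test_ols_limit_on_random_designs(self):
        import statsmodels.api as sm

        for seed in range(3):
            d = _design(n=120, p=4, seed=seed, coefs=[1.0, -0.5, 0.0, 0.3])
            fit = RangeRegression(d).fit(seed=seed, draws=4000)
            ols = sm.OLS(d.y.to_numpy(), sm.add_constant(d.X.to_numpy())).fit()
            np.testing.assert_allclose(fit.params.to_numpy(), ols.params, atol=0.02)

    def test_aic_identity(self):
        d = _design(n=40, p=3, coefs=[1.0, 0.0, 0.0])
        fit = RangeRegression(d).fit(seed=2)
        assert fit.aic == pytest.approx(2 * fit.k - 2 * fit.loglik, rel=1e-12)
        assert fit.k == 3 + 1 + 1  # slopes + intercept + residual sd

    def test_ci_level_monotonicity(self):
        d = _design(n=40, p=3, coefs=[0.5, 0.0, -0.2])
        fit = RangeRegression(d).fit(seed=3)
        for term in fit.terms:
            lo90, hi90 = fit.credible_interval(term, 0.90)
            lo95, hi95 = fit.credible_interval(term, 0.95)
            assert lo95 <= lo90 <= hi90 <= hi95

    def test_null_coverage_calibration(self):
        # pure-noise response: 90% CIs should cover 0 close to nominally
        cover = 0
        reps = 40
        for seed in range(reps):
            d = _design(n=200, p=1, seed=seed, coefs=[0.0], noise=1.0)
            fit = RangeRegression(d).fit(seed=seed, draws=1000, warmup=100)
            lo, hi = fit.credible_interval("x0", 0.90)
            cover += lo <= 0 <= hi
        assert cover / reps >= 0.8


class TestVif:
    def test_orthogonal_predictors_unity(self, rng):
        # mutually orthogonal, mean-zero columns: no shared variance
        A = np.column_stack([np.ones(20), rng.standard_normal((20, 4))])
        Q, _ = np.linalg.qr(A)
        X = pd.DataFrame(Q[:, 1:], columns=list("abcd"))
        v = vif(X)
        np.testing.assert_allclose(v, 1.0, atol=1e-10)

    def test_known_correlation_closed_form(self):
        rng = np.random.default_rng(5)
        n = 200_000
        a = rng.standard_normal(n)
        b = 0.9 * a + np.sqrt(1 - 0.81) * rng.standard_normal(n)
        v = vif(pd.DataFrame({"a": a, "b": b}))
        assert v["a"] == pytest.approx(1 / (1 - 0.81), rel=0.02)

    def test_matches_statsmodels_oracle(self, rng):
        from statsmodels.stats.outliers_influence import variance_inflation_factor
        import statsmodels.api as sm

        for _ in range(5):
            X = pd.DataFrame(rng.standard_normal((60, 4)) @ rng.normal(size=(4, 4)),
                             columns=list("abcd"))
            mine = vif(X)
            Xc = sm.add_constant(X.to_numpy())
            for j, col in enumerate(X.columns):
                ref = variance_inflation_factor(Xc, j + 1)
                assert mine[col] == pytest.approx(ref, rel=1e-8)

    def test_perfect_collinearity_flagged_infinite(self):
        X = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [2.0, 4, 6, 8]})
        assert np.isinf(vif(X)).all()


class TestSelection:
    def test_single_active_predictor_selected(self):
        d = _design(n=500, p=3, seed=1, coefs=[0.8, 0.0, 0.0], noise=1.0)
        trace, final = backward_select(d, seed=1, draws=1000, warmup=100)
        assert "x0" in trace.final_predictors
        assert final.aic <= trace.steps[0].aic

    def test_all_strong_predictors_kept(self):
        d = _design(n=300, p=3, seed=2, coefs=[1.0, -1.0, 0.8], noise=0.5)
        trace, _ = backward_select(d, seed=2, draws=1000, warmup=100)
        assert set(trace.final_predictors) == {"x0", "x1", "x2"}

    def test_aic_non_increasing_along_accepted_steps(self):
        d = _design(n=200, p=5, seed=3, coefs=[0.5, 0, 0, 0.3, 0], noise=1.0)
        trace, _ = backward_select(d, seed=3, draws=1000, warmup=100)
        aics = [s.aic for s in trace.steps]
        assert all(b < a for a, b in zip(aics, aics[1:]))

    def test_matches_exhaustive_search(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            d = _design(n=100, p=4, seed=seed,
                        coefs=rng.choice([0.0, 0.6], size=4), noise=1.0)
            trace, final = backward_select(d, seed=seed, draws=1000, warmup=100)
            best_set, best_aic = exhaustive_select(d, seed=seed, draws=1000, warmup=100)
            assert set(trace.final_predictors) == set(best_set)
            assert final.aic == pytest.approx(best_aic, abs=1e-9)

    def test_final_candidates_are_leave_one_out_aics(self):
        d = _design(n=200, p=3, seed=4, coefs=[1.0, -0.8, 0.9], noise=0.5)
        trace, final = backward_select(d, seed=4, draws=1000, warmup=100)
        assert set(trace.steps[-1].candidates) == set(trace.final_predictors)
        assert all(a > final.aic for a in trace.steps[-1].candidates.values())


class TestMeansAndCorrelation:
    def test_mean_log_trait(self):
        obs = pd.DataFrame(
            {
                "site": ["S1", "S2"],
                "species": "spA",
                "trait": "lma",
                "value": [np.e**2, np.e**4],
            }
        )
        out = mean_trait_response(obs)
        assert out.loc[0, "mean_log_trait"] == pytest.approx(3.0)

    def test_pooled_mean_equals_weighted_cell_means(self, rng):
        n1, n2 = 7, 13
        obs = pd.DataFrame(
            {
                "site": ["S1"] * n1 + ["S2"] * n2,
                "species": "spA",
                "trait": "lma",
                "value": rng.lognormal(0, 0.3, n1 + n2),
            }
        )
        pooled = mean_trait_response(obs)["mean_log_trait"].iloc[0]
        cell_means = obs.groupby("site")["value"].apply(lambda v: np.mean(np.log(v)))
        weighted = (cell_means["S1"] * n1 + cell_means["S2"] * n2) / (n1 + n2)
        assert pooled == pytest.approx(weighted, rel=1e-12)

    def test_perfect_correlation(self):
        r, p = mean_itv_correlation([1, 2, 3, 4], [2, 4, 6, 8])
        assert r == pytest.approx(1.0)

    def test_matches_covariance_formula(self):
        x = np.array([1.0, 2, 3, 4])
        y = np.array([2.0, 1, 3, 4])
        r, _ = mean_itv_correlation(x, y)
        by_hand = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
        )
        assert r == pytest.approx(by_hand, rel=1e-12)

    def test_affine_invariance(self, rng):
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        r1, _ = mean_itv_correlation(x, y)
        r2, _ = mean_itv_correlation(3 * x + 7, 0.5 * y - 2)
        assert r1 == pytest.approx(r2, rel=1e-10)

    def test_zero_variance_error(self):
        with pytest.raises(ValueError):
            mean_itv_correlation([1, 1, 1], [1, 2, 3])
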