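"""NB2 fitting, screening, AICc averaging and contrasts."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from railbat.count_models import (ModelSpec, aicc, fit_nb,
                                  lr_test_random_effect, pairwise_contrasts,
                                  quantile_residuals, rank_and_average,
                                  screen_univariate)

from nb_oracle import fit_nb_irls


class TestAICc:
    def test_direct_formula(self):
        # -2(-100) + 2*2 + 2*2*3/97
        assert aicc(-100.0, 2, 100) == pytest.approx(204.12371134, abs=1e-6)

    def test_limits(self):
        assert aicc(-50.0, 0, 10) == pytest.approx(100.0)
        # large n: correction vanishes, AICc -> AIC
        assert aicc(-100.0, 3, 10 ** 9) == pytest.approx(206.0, abs=1e-6)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            aicc(-10.0, 5, 6)


class TestFitNB:
    def test_intercept_only_closed_form(self):
        y = np.array([0, 1, 2, 3, 4, 5, 2, 3] * 10)
        tab = pd.DataFrame({"count": y})
        fit = fit_nb(ModelSpec(), tab)
        assert fit.coef[0] == pytest.approx(math.log(y.mean()), abs=1e-8)

    def test_poisson_limit(self):
        """Poisson data: theta explodes, coefficients match a Poisson GLM."""
        rng = np.random.default_rng(5)
        x = rng.normal(size=1500)
        y = rng.poisson(np.exp(1.0 + 0.4 * x))
        tab = pd.DataFrame({"count": y, "x": x})
        fit = fit_nb(ModelSpec(fixed_terms=("x",)), tab)
        # theta is weakly identified at the Poisson limit; "large" means
        # the quadratic variance term is negligible at these means
        assert fit.theta > 50
        import statsmodels.api as sm
        pois = sm.GLM(y, sm.add_constant(x), family=sm.families.Poisson()).fit()
        np.testing.assert_allclose(fit.coef, pois.params, rtol=0.01)

    def test_matches_irls_oracle_on_simulated_tables(self):
        """Dual-route check on 10 small tables: agreement to 1e-6."""
        rng = np.random.default_rng(77)
        for _ in range(10):
            n = int(rng.integers(80, 200))
            x = rng.normal(size=n)
            mu = np.exp(rng.uniform(0, 1.2) + rng.uniform(-0.6, 0.6) * x)
            y = rng.poisson(mu * rng.gamma(1.5, 1 / 1.5, size=n))
            tab = pd.DataFrame({"count": y, "x": x})
            fit = fit_nb(ModelSpec(fixed_terms=("x",)), tab)
            X = np.column_stack([np.ones(n), x])
            beta_o, theta_o, ll_o = fit_nb_irls(X, y.astype(float))
            np.testing.assert_allclose(fit.coef, beta_o, atol=1e-6)
            assert fit.loglik == pytest.approx(ll_o, abs=1e-6)

    def test_negative_counts_rejected(self):
        tab = pd.DataFrame({"count": [-1, 2, 3]})
        with pytest.raises(ValueError):
            fit_nb(ModelSpec(), tab)

    def test_zero_variance_random_effect_removed(self, small_count_table):
        """Identical groups: the intercept variance hits the floor."""
        fit = fit_nb(ModelSpec(fixed_terms=("x",), random_intercept="site_id"),
                     small_count_table)
        # no true site effect was simulated
        assert fit.re_removed
        assert fit.random_effect is None

    def test_strong_site_effect_detected(self):
        rng = np.random.default_rng(9)
        n_g, per = 10, 80
        u = rng.normal(0, 1.0, size=n_g)
        g = np.repeat(np.arange(n_g), per)
        y = rng.poisson(np.exp(0.5 + u[g]))
        tab = pd.DataFrame({"count": y, "site_id": [f"s{i}" for i in g]})
        fit = fit_nb(ModelSpec(random_intercept="site_id"), tab, re_lrt=True)
        assert not fit.re_removed
        assert fit.re_sd == pytest.approx(1.0, abs=0.45)
        assert fit.re_p < 0.01

    def test_quantile_residuals_uniform_when_well_specified(self):
        rng = np.random.default_rng(21)
        n = 2000
        x = rng.normal(size=n)
        y = rng.poisson(np.exp(0.3 + 0.5 * x) * rng.gamma(2.0, 0.5, size=n))
        tab = pd.DataFrame({"count": y, "x": x})
        spec = ModelSpec(fixed_terms=("x",))
        fit = fit_nb(spec, tab)
        r = quantile_residuals(fit, spec, tab, seed=0)
        assert stats.kstest(r, "uniform").pvalue > 0.01


class TestLRT:
    def test_identical_loglik_gives_half(self, small_count_table):
        from railbat.count_models import FitResult
        a = FitResult(names=["i"], coef=np.zeros(1), se=np.ones(1),
                      cov=np.eye(1), theta=1, loglik=-100.0, n=50, k=3,
                      aicc=206.0, random_effect="site_id")
        b = FitResult(names=["i"], coef=np.zeros(1), se=np.ones(1),
                      cov=np.eye(1), theta=1, loglik=-100.0, n=50, k=2,
                      aicc=204.0)
        assert lr_test_random_effect(a, b) == pytest.approx(0.5)

    def test_non_nested_rejected(self):
        from railbat.count_models import FitResult
        a = FitResult(names=["i"], coef=np.zeros(1), se=np.ones(1),
                      cov=np.eye(1), theta=1, loglik=-100.0, n=50, k=3,
                      aicc=206.0)
        with pytest.raises(ValueError):
            lr_test_random_effect(a, a)


class TestScreening:
    def _table(self, seed, slope=0.0, n=500):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=n)
        y = rng.poisson(np.exp(0.5 + slope * x))
        return pd.DataFrame({"count": y, "x": x})

    def test_noise_covariate_excluded_about_90pct(self):
        kept = sum("x" in screen_univariate(["x"], self._table(s), alpha=0.1)
                   for s in range(120))
        # binomial(120, 0.1): 3 sigma band around 12
        assert 2 <= kept <= 24

    def test_strong_covariate_always_kept(self):
        for s in range(25):
            assert screen_univariate(["x"], self._table(s, slope=0.4)) == ["x"]


class TestAveraging:
    def _category_table(self, seed=3, n_gap=250, effect=-0.7):
        rng = np.random.default_rng(seed)
        cat = pd.Categorical(["between", "before", "after"] * n_gap,
                             categories=["between", "before", "after"])
        eta = np.where(np.asarray(cat) == "after", effect, 0.0)
        y = rng.poisson(np.exp(0.2 + eta) * rng.gamma(3, 1 / 3, size=3 * n_gap))
        return pd.DataFrame({"count": y, "category": cat,
                             "noise": rng.normal(size=3 * n_gap)})

    def test_dominant_model_equals_its_estimate(self):
        tab = self._category_table()
        avg = rank_and_average(["category"], tab)
        # the category model dominates the null by far: weights collapse
        assert avg.weights.max() > 0.999
        only = avg.members[int(np.argmax(avg.weights))]
        i = avg.names.index("category[after]")
        assert avg.coef[i] == pytest.approx(only.coef[only.names.index("category[after]")],
                                            abs=1e-3)

    def test_equal_aicc_gives_equal_weights(self):
        tab = self._category_table()
        tab["x1"] = np.linspace(-1, 1, len(tab))
        tab["x2"] = -tab["x1"]  # mirror image: identical single-term fits
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            avg = rank_and_average(["x1", "x2"], tab)
        w = {tuple(f.terms): wt for f, wt in zip(avg.members, avg.weights)}
        assert w[("x1",)] == pytest.approx(w[("x2",)], abs=1e-6)

    def test_null_covariate_shrunk_toward_zero(self):
        tab = self._category_table(seed=8)
        avg = rank_and_average(["category", "noise"], tab)
        full = fit_nb(ModelSpec(fixed_terms=("category", "noise")), tab)
        i_avg = avg.names.index("noise")
        i_full = full.names.index("noise")
        assert abs(avg.coef[i_avg]) <= abs(full.coef[i_full]) + 1e-12

    def test_full_set_weights_sum_to_one(self):
        avg = rank_and_average(["category"], self._category_table())
        assert avg.full_set_weights.sum() == pytest.approx(1.0)
        assert np.all(avg.delta_aicc <= 6.0)


class TestContrasts:
    def test_irr_is_exp_of_estimate(self):
        tab = TestAveraging()._category_table()
        fit = fit_nb(ModelSpec(fixed_terms=("category",)), tab)
        con = pairwise_contrasts(fit)
        for _, row in con.iterrows():
            assert row.irr == pytest.approx(math.exp(row.estimate), rel=1e-12)

    def test_zero_estimate_gives_unit_irr(self):
        tab = TestAveraging()._category_table(effect=-0.7)
        fit = fit_nb(ModelSpec(fixed_terms=("category",)), tab)
        con = pairwise_contrasts(fit).set_index("contrast")
        # before and between share the same true rate
        assert con.loc["before vs between", "irr"] == pytest.approx(1.0, abs=0.25)
        assert con.loc["after vs before", "irr"] == pytest.approx(math.exp(-0.7),
                                                                  abs=0.15)

    def test_contrast_consistency(self):
        tab = TestAveraging()._category_table()
        fit = fit_nb(ModelSpec(fixed_terms=("category",)), tab)
        con = pairwise_contrasts(fit).set_index("contrast")
        assert con.loc["after vs before", "estimate"] == pytest.approx(
            con.loc["after vs between", "estimate"]
            - con.loc["before vs between", "estimate"], abs=1e-10)

    def test_averaged_contrast_equals_relevelled_averaging(self):
        """Linear-combination route == literal re-level + re-average."""
        tab = TestAveraging()._category_table(seed=13)
        avg = rank_and_average(["category", "noise"], tab)
        con = pairwise_contrasts(avg).set_index("contrast")
        base_b = ModelSpec(reference_level="before")
        avg_b = rank_and_average(["category", "noise"], tab, base_b)
        i = avg_b.names.index("category[after]")
        assert con.loc["after vs before", "estimate"] == pytest.approx(
            avg_b.coef[i], abs=5e-4)

    def test_two_level_category_rejected(self):
        rng = np.random.default_rng(0)
        tab = pd.DataFrame({"count": rng.poisson(2, 100),
                            "category": ["a", "b"] * 50})
        fit = fit_nb(ModelSpec(fixed_terms=("category",), reference_level="a"), tab)
        with pytest.raises(ValueError):
            pairwise_contrasts(fit, reference="a")
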