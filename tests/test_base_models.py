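"""Candidate-form fitting, splitting, collinearity screening, ranking."""

import math

import numpy as np
import pandas as pd
import pytest
import scipy.optimize
import statsmodels.api as sm

from fircompat.base_models import (
    FORMS,
    SplitSpec,
    compute_vif,
    fit_base,
    fit_from_params,
    rank_models,
    split,
    stepwise_select,
)
from fircompat.metrics import aic
from fircompat.published import BASE_MODEL_FITS


class TestSplit:
    def test_exact_seven_three_on_ten_records(self):
        df = pd.DataFrame({"age_group": [1] * 10, "x": range(10)})
        train, test = split(df, SplitSpec(seed=0))
        assert (len(train), len(test)) == (7, 3)

    def test_deterministic_given_seed(self, small_stand):
        a = split(small_stand, SplitSpec(seed=5))
        b = split(small_stand, SplitSpec(seed=5))
        pd.testing.assert_frame_equal(a[0], b[0])
        pd.testing.assert_frame_equal(a[1], b[1])

    def test_study_size_train_count(self):
        # single stratum at the published sample size: 70% of 20,836
        df = pd.DataFrame({"age_group": np.ones(20836, dtype=int)})
        train, test = split(df, SplitSpec(seed=1))
        assert abs(len(train) - 14585) <= 1
        assert len(train) + len(test) == 20836

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_partition_is_disjoint_and_exhaustive(self, small_stand, seed):
        train, test = split(small_stand, SplitSpec(seed=seed))
        ids = set(zip(train.plot_id, train.tree_id)) | set(zip(test.plot_id, test.tree_id))
        assert len(train) + len(test) == len(small_stand)
        assert len(ids) == len(small_stand)
        # per-stratum share within one tree of 70%
        for g, sub in small_stand.groupby("age_group"):
            n_tr = (train.age_group == g).sum()
            assert abs(n_tr - 0.7 * len(sub)) <= 1.0

    def test_too_few_records_rejected(self):
        with pytest.raises(ValueError):
            split(pd.DataFrame({"age_group": [1] * 5}), SplitSpec())


class TestVIF:
    def test_orthogonal_predictors_have_unit_vif(self):
        df = pd.DataFrame({"x1": [1.0, 1.0, -1.0, -1.0], "x2": [1.0, -1.0, 1.0, -1.0]})
        vifs = compute_vif(df, ["x1", "x2"])
        assert vifs["x1"] == pytest.approx(1.0)
        assert vifs["x2"] == pytest.approx(1.0)

    def test_correlation_point_nine_closed_form(self):
        # exact sample correlation 0.9 via orthonormal construction
        z1 = np.array([1.0, 1.0, -1.0, -1.0]) / 2
        z2 = np.array([1.0, -1.0, 1.0, -1.0]) / 2
        df = pd.DataFrame({"x1": z1, "x2": 0.9 * z1 + math.sqrt(1 - 0.81) * z2})
        vifs = compute_vif(df, ["x1", "x2"])
        assert vifs["x1"] == pytest.approx(1.0 / (1.0 - 0.81), rel=1e-9)

    def test_duplicated_column_is_infinite(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=30)
        df = pd.DataFrame({"x1": x, "x2": x})
        vifs = compute_vif(df, ["x1", "x2"])
        assert math.isinf(vifs["x1"]) and math.isinf(vifs["x2"])

    def test_agrees_with_statsmodels_on_generic_data(self, small_stand):
        sub = small_stand.head(500)
        df = pd.DataFrame({"x1": np.log(sub.lh), "x2": np.log(sub.lcd),
                           "x3": np.log(sub.lh) + 0.3 * np.log(sub.lcd)})
        names = ["x1", "x2", "x3"]
        ours = compute_vif(df, names)
        X = sm.add_constant(df[names].to_numpy())
        from statsmodels.stats.outliers_influence import variance_inflation_factor
        for j, name in enumerate(names):
            assert ours[name] == pytest.approx(
                variance_inflation_factor(X, j + 1), rel=1e-8)


class TestStepwise:
    def test_both_true_covariates_selected(self, small_stand):
        assert stepwise_select(small_stand, "m_total", ["lh", "lcd"]) == ["lh", "lcd"]

    def test_pure_noise_column_excluded(self, small_stand):
        rng = np.random.default_rng(3)
        df = small_stand.assign(noise=rng.lognormal(0.0, 0.5, len(small_stand)))
        selected = stepwise_select(df, "m_total", ["lh", "noise"])
        # oracle: direct AIC comparison of the two log-linear candidates
        ly = np.log(df.m_total.to_numpy())
        X1 = sm.add_constant(np.log(df[["lh"]].to_numpy()))
        X2 = sm.add_constant(np.log(df[["lh", "noise"]].to_numpy()))
        assert sm.OLS(ly, X1).fit().aic < sm.OLS(ly, X2).fit().aic
        assert selected == ["lh"]

    def test_exact_copy_removed_by_vif_rule(self, small_stand):
        df = small_stand.assign(lh_copy=small_stand.lh)
        selected = stepwise_select(df, "m_total", ["lh", "lh_copy"])
        assert selected == ["lh"]


class TestFitBase:
    def test_noise_free_power_recovery(self, noise_free_stand):
        # response generated exactly from the published all-data power law
        p = BASE_MODEL_FITS["power"]["total"]["params"]
        df = noise_free_stand.assign(
            m_total=p["a"] * noise_free_stand.lh ** p["b"]
            * noise_free_stand.lcd ** p["c"])
        fit = fit_base(df, "power", "total")
        assert fit.converged
        for k, v in p.items():
            assert fit.params[k] == pytest.approx(v, rel=1e-6)

    def test_linear_data_on_a_plane_is_exact(self, noise_free_stand):
        df = noise_free_stand.assign(
            m_total=2.0 * noise_free_stand.lh + 3.0 * noise_free_stand.lcd - 4.0)
        fit = fit_base(df, "linear", "total")
        assert fit.rss == pytest.approx(0.0, abs=1e-14)
        assert fit.params["a"] == pytest.approx(2.0)
        assert fit.params["c"] == pytest.approx(4.0)

    def test_degenerate_logistic_flags_non_identifiability(self, noise_free_stand):
        # c = d = 0 truth makes the response constant: the covariate-effect
        # parameters are unidentifiable, and their standard errors must
        # swamp the estimates rather than report false precision
        rng = np.random.default_rng(3)
        df = noise_free_stand.assign(
            m_total=5.0 + 0.1 * rng.standard_normal(len(noise_free_stand)))
        fit = fit_base(df, "logistic", "total")
        assert fit.se["b"] > abs(fit.params["b"])
        assert fit.se["c"] > 0.5 * abs(fit.params["c"])
        assert fit.se["d"] > 0.5 * abs(fit.params["d"])

    def test_positive_covariate_precondition_for_power(self, noise_free_stand):
        df = noise_free_stand.copy()
        df.loc[0, "lh"] = -1.0
        with pytest.raises(ValueError, match="positive"):
            fit_base(df, "power", "total")

    def test_rss_trajectory_never_increases(self, small_stand):
        for form in FORMS:
            fit = fit_base(small_stand, form, "total")
            hist = np.array(fit.rss_history)
            assert np.all(np.diff(hist) <= 0)

    def test_agrees_with_scipy_least_squares(self, small_stand):
        # independent optimizer on the identical objective
        lh = small_stand.lh.to_numpy()
        lcd = small_stand.lcd.to_numpy()
        y = small_stand.m_trunk.to_numpy()
        form = FORMS["power"]
        fit = fit_base(small_stand, "power", "trunk")
        res = scipy.optimize.least_squares(
            lambda p: y - form.func(p, lh, lcd), form.init(lh, lcd, y),
            method="lm", xtol=1e-14, ftol=1e-14)
        ours = np.array([fit.params[k] for k in form.param_names])
        np.testing.assert_allclose(ours, res.x, rtol=1e-6)

    def test_power_solution_matches_grid_refinement_oracle(self, noise_free_stand):
        # brute-force RSS minimisation by iterative grid refinement, n <= 30
        df = noise_free_stand.head(30)
        rng = np.random.default_rng(12)
        y = (0.3551 * df.lh ** 1.8102 * df.lcd ** 0.2109
             * np.exp(0.05 * rng.standard_normal(len(df)))).to_numpy()
        lh, lcd = df.lh.to_numpy(), df.lcd.to_numpy()

        def rss(a, b, c):
            r = y - a * lh ** b * lcd ** c
            return r @ r

        center = np.array([0.5, 1.5, 0.3])
        width = np.array([0.45, 1.0, 0.4])
        for _ in range(30):
            grids = [np.linspace(c - w, c + w, 11) for c, w in zip(center, width)]
            best = min(
                ((rss(a, b, c), (a, b, c))
                 for a in grids[0] for b in grids[1] for c in grids[2]),
                key=lambda t: t[0])
            center = np.array(best[1])
            width = width * 0.35
        fit = fit_base(df.assign(m_total=y), "power", "total")
        ours = np.array([fit.params[k] for k in ("a", "b", "c")])
        np.testing.assert_allclose(ours, center, atol=1e-3)


class TestRankModels:
    @staticmethod
    def _mk(form, rss, n=100):
        from dataclasses import replace
        base = fit_from_params(form, "total",
                               dict.fromkeys(FORMS[form].param_names, 1.0))
        return replace(base, rss=rss, n=n)

    def test_lower_aic_wins_outright(self):
        # choose RSS values far apart: clearly different AIC
        table, selected = rank_models([self._mk("power", 100.0), self._mk("linear", 500.0)])
        assert selected == "power"
        assert table.iloc[0]["form"] == "power"

    def test_near_tie_resolves_to_fewer_parameters(self):
        n = 100
        rss_power = 100.0
        # logistic (4 params) beating power (3 params) by 1 AIC unit
        target = aic(rss_power, n, 3) - 1.0
        rss_logistic = n / (2 * math.pi) * math.exp((target - 2 * 4) / n - 1.0)
        fits = [self._mk("logistic", rss_logistic), self._mk("power", rss_power)]
        table, selected = rank_models(fits)
        assert table.iloc[0]["form"] == "logistic"
        assert selected == "power"

    def test_single_form_is_selected_trivially(self):
        _, selected = rank_models([self._mk("power", 50.0)])
        assert selected == "power"

    def test_non_converged_fits_are_excluded(self):
        from dataclasses import replace
        bad = replace(self._mk("linear", 10.0), converged=False)
        _, selected = rank_models([bad, self._mk("power", 500.0)])
        assert selected == "power"
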