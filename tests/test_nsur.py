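"""Additivity-constrained SUR system: covariance, prediction, IFGLS."""

import numpy as np
import pytest

from fircompat import nsur
from fircompat.dummy_models import fit_dummy
from fircompat.nsur import SURSystemFit, estimate_sigma, fit_nsur, predict_system
from fircompat.published import COMPONENTS, SUR_SYSTEM_FIT
from fircompat.synthetic import default_config, generate_stand


def _published_system() -> SURSystemFit:
    return SURSystemFit(
        scales={c: dict(SUR_SYSTEM_FIT[c]["scales"]) for c in COMPONENTS},
        exponents={c: (SUR_SYSTEM_FIT[c]["exp_lh"], SUR_SYSTEM_FIT[c]["exp_lcd"])
                   for c in COMPONENTS},
        se_scales={c: {} for c in COMPONENTS},
        se_exponents={c: (np.nan, np.nan) for c in COMPONENTS},
        sigma=np.eye(4), param_cov=np.eye(28), n=0,
        outer_iterations=0, converged=True,
    )


class TestEstimateSigma:
    def test_zero_residuals_give_zero_matrix(self):
        assert np.all(estimate_sigma(np.zeros((10, 4))) == 0.0)

    def test_orthogonal_unit_variance_streams(self):
        # columns orthogonal with squared norm n: R'R/n is exactly identity
        n = 8
        H = np.array([[1, 1, 1, 1], [1, -1, 1, -1], [1, 1, -1, -1], [1, -1, -1, 1]]).T
        R = np.vstack([H, -H])  # 8 x 4, orthogonal columns, norm^2 = 8
        np.testing.assert_allclose(estimate_sigma(R), np.eye(4), atol=1e-12)

    def test_duplicated_streams_are_rank_deficient_but_factorable(self):
        rng = np.random.default_rng(0)
        col = rng.normal(size=50)
        R = np.column_stack([col, col, rng.normal(size=50), rng.normal(size=50)])
        sigma = estimate_sigma(R)
        assert np.linalg.matrix_rank(sigma) < 4
        Linv = nsur._chol_inv_factor(sigma)  # ridge path must not raise
        assert np.all(np.isfinite(Linv))

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            estimate_sigma(np.zeros((4, 4)))


class TestPredictSystem:
    def test_published_coefficients_at_unit_covariates(self):
        pred = predict_system(_published_system(), 1.0, 1.0, 1)
        assert pred["trunk"] == pytest.approx(0.2124)
        assert pred["bark"] == pytest.approx(0.1098)
        assert pred["branch"] == pytest.approx(0.2901)
        assert pred["leaf"] == pytest.approx(0.3401)
        assert pred["total"] == pytest.approx(0.9524)

    def test_total_is_the_exact_component_sum(self, small_stand):
        pred = predict_system(_published_system(), small_stand.lh,
                              small_stand.lcd, small_stand.age_group)
        resid = pred["total"] - (pred["bark"] + pred["trunk"]
                                 + pred["branch"] + pred["leaf"])
        assert np.all(resid == 0.0)

    def test_linearity_in_scale_coefficients(self):
        fit = _published_system()
        doubled = SURSystemFit(
            scales={c: {g: 2 * v for g, v in fit.scales[c].items()}
                    for c in COMPONENTS},
            exponents=fit.exponents, se_scales=fit.se_scales,
            se_exponents=fit.se_exponents, sigma=fit.sigma,
            param_cov=fit.param_cov, n=0, outer_iterations=0, converged=True)
        a = predict_system(fit, 7.0, 2.0, 3)
        b = predict_system(doubled, 7.0, 2.0, 3)
        for key in a:
            assert b[key] == pytest.approx(2 * a[key], rel=1e-12)

    def test_nonpositive_covariates_rejected(self):
        with pytest.raises(ValueError):
            predict_system(_published_system(), -1.0, 1.0, 1)


class TestFitNSUR:
    def test_noise_free_recovery_of_the_generating_system(self, noise_free_stand):
        fit = fit_nsur(noise_free_stand)
        assert fit.converged
        for c in COMPONENTS:
            pub = SUR_SYSTEM_FIT[c]
            for g in range(1, 6):
                assert fit.scales[c][g] == pytest.approx(pub["scales"][g], rel=1e-6)
            assert fit.exponents[c][0] == pytest.approx(pub["exp_lh"], rel=1e-6)
            assert fit.exponents[c][1] == pytest.approx(pub["exp_lcd"], rel=1e-6)

    def test_gls_criterion_non_increasing_within_each_outer_stage(self, small_stand):
        fit = fit_nsur(small_stand)
        assert fit.converged
        for start, end in fit.gls_history:
            assert end <= start * (1 + 1e-12)

    def test_sigma_is_symmetric_psd(self, small_stand):
        fit = fit_nsur(small_stand)
        np.testing.assert_allclose(fit.sigma, fit.sigma.T, atol=1e-12)
        assert np.linalg.eigvalsh(fit.sigma).min() >= -1e-10

    def test_estimated_sigma_recovers_generating_correlation(self, small_stand):
        # pairwise error correlation 0.5 in the generator; the residual
        # correlation estimate should land in the neighbourhood
        fit = fit_nsur(small_stand)
        d = np.sqrt(np.diag(fit.sigma))
        corr = fit.sigma / np.outer(d, d)
        off = corr[~np.eye(4, dtype=bool)]
        assert 0.3 < off.mean() < 0.7

    def test_missing_age_group_rejected(self, small_stand):
        with pytest.raises(ValueError, match="stratified"):
            fit_nsur(small_stand[small_stand.age_group != 5])

    def test_minimum_sample_size(self, small_stand):
        with pytest.raises(ValueError, match="50"):
            fit_nsur(small_stand.groupby("age_group").head(4).reset_index(drop=True))

    def test_known_diagonal_sigma_reduces_to_equationwise_fits(self):
        cfg = default_config(
            n_per_age_group={g: 300 for g in range(1, 6)},
            error_corr=np.eye(4), seed=11)
        df = generate_stand(cfg)
        dfits = {c: fit_dummy(df, c) for c in COMPONENTS}
        diag = np.diag([dfits[c].rss / len(df) for c in COMPONENTS])
        fit = fit_nsur(df, start=dfits, fixed_sigma=diag)
        for c in COMPONENTS:
            for g in range(1, 6):
                assert fit.scales[c][g] == pytest.approx(dfits[c].scales[g], rel=1e-4)

    def test_estimated_sigma_on_uncorrelated_data_agrees_loosely(self):
        # with Sigma estimated, sampling noise in its off-diagonals moves
        # the GLS solution away from equationwise NLS by O(1/sqrt(n))
        cfg = default_config(
            n_per_age_group={g: 300 for g in range(1, 6)},
            error_corr=np.eye(4), seed=13)
        df = generate_stand(cfg)
        fit = fit_nsur(df)
        for c in COMPONENTS:
            dfit = fit_dummy(df, c)
            for g in range(1, 6):
                assert fit.scales[c][g] == pytest.approx(dfit.scales[g], rel=0.05)
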