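import numpy as np
import pytest
from hypothesis import given, strategies as st

from _oracles import inverse_variance_mean, scalar_empirical_bayes_blup
from tempyll.meta import (
    MetaFit,
    MetaInput,
    aic,
    blup,
    cochran_q,
    i_squared,
    mvmeta_fit,
    wald_test,
)


def random_input(k, v, seed, psi_scale=0.0, predictor=False):
    rng = np.random.default_rng(seed)
    A = rng.normal(0, 0.3, (k, v, v))
    covs = np.einsum("kij,klj->kil", A, A) + 0.5 * np.eye(v)[None]
    mu = rng.normal(0, 1, v)
    etas = mu + rng.normal(0, np.sqrt(psi_scale) if psi_scale else 0.0, (k, v))
    etas = etas + np.einsum("kij,kj->ki", np.linalg.cholesky(covs), rng.normal(size=(k, v)))
    preds = {"u": rng.normal(0, 1, k)} if predictor else None
    return MetaInput(etas=etas, covs=covs, predictors=preds)


class TestPooling:
    def test_single_city_with_psi_zero_returns_its_own_estimate(self):
        eta = np.array([[1.0, -2.0, 0.5, 3.0]])
        covs = np.eye(4)[None] * 0.2
        fit = mvmeta_fit(MetaInput(etas=eta, covs=covs), psi="zero")
        assert np.allclose(fit.pooled, eta[0])

    def test_scalar_fixed_effects_matches_inverse_variance_mean(self):
        rng = np.random.default_rng(0)
        y = rng.normal(2.0, 0.5, (9, 1))
        variances = rng.uniform(0.3, 2.0, 9)
        covs = variances[:, None, None] * np.ones((9, 1, 1))
        fit = mvmeta_fit(MetaInput(etas=y, covs=covs), psi="zero")
        assert fit.pooled[0] == pytest.approx(inverse_variance_mean(y[:, 0], variances), abs=1e-8)

    def test_ml_psi_at_zero_boundary_equals_fixed_effects_gls(self):
        # homogeneous data: the ML Psi collapses and the pooled estimate
        # approaches the fixed-effects solution
        mi = random_input(k=12, v=2, seed=1, psi_scale=0.0)
        fit_ml = mvmeta_fit(mi)
        fit_fe = mvmeta_fit(mi, psi="zero")
        assert np.allclose(fit_ml.pooled, fit_fe.pooled, atol=0.05)

    def test_too_few_cities_raise(self):
        mi = random_input(k=2, v=2, seed=2, predictor=True)
        with pytest.raises(ValueError, match="cities"):
            mvmeta_fit(mi, predictor="u")

    def test_deterministic_given_input(self):
        mi = random_input(k=8, v=3, seed=3, psi_scale=0.4)
        f1 = mvmeta_fit(mi)
        f2 = mvmeta_fit(mi)
        assert f1.loglik == f2.loglik
        assert np.array_equal(f1.psi, f2.psi)


class TestCochranQ:
    def test_identical_cities_give_zero(self):
        eta = np.tile([1.0, 2.0], (6, 1))
        covs = np.tile(np.eye(2) * 0.3, (6, 1, 1))
        q, df, p = cochran_q(MetaInput(etas=eta, covs=covs))
        assert q == pytest.approx(0.0, abs=1e-10)
        assert df == 10
        assert p == pytest.approx(1.0)

    @given(st.integers(3, 8), st.integers(1, 4), st.booleans())
    def test_degrees_of_freedom_arithmetic(self, k, v, with_predictor):
        if with_predictor and k <= 2:
            return
        mi = random_input(k=k, v=v, seed=17, predictor=True)
        q, df, _ = cochran_q(mi, predictor="u" if with_predictor else None)
        p = 2 if with_predictor else 1
        assert df == k * v - p * v

    def test_heterogeneity_grows_with_between_city_spread(self):
        qs = []
        for scale in (0.0, 0.5, 2.0):
            mi = random_input(k=10, v=2, seed=4, psi_scale=scale)
            qs.append(cochran_q(mi)[0])
        assert qs[0] < qs[1] < qs[2]

    def test_singular_within_city_covariance_named(self):
        covs = np.tile(np.eye(2) * 0.3, (4, 1, 1))
        covs[2] = 0.0
        mi = MetaInput(etas=np.zeros((4, 2)), covs=covs, city_ids=["a", "b", "c", "d"])
        with pytest.raises(ValueError, match="c"):
            cochran_q(mi)


class TestISquared:
    @pytest.mark.parametrize(
        "q,df,expected",
        [(115.8, 60, 48.2), (83.0, 56, 32.5), (87.6, 56, 36.1), (109.3, 56, 48.8),
         (105.1, 56, 46.7), (90.0, 56, 37.8), (111.1, 56, 49.6), (100.5, 56, 44.3),
         (102.2, 56, 45.2), (108.2, 56, 48.3), (105.3, 56, 46.8), (93.3, 56, 40.0)],
    )
    def test_reproduces_heterogeneity_percentages(self, q, df, expected):
        # both Q and I2 are quoted rounded to one decimal, so recomputing
        # I2 from a rounded Q can drift by ~0.1 in the last digit
        assert i_squared(q, df) == pytest.approx(expected, abs=0.1)

    def test_floors_at_zero_when_q_below_df(self):
        assert i_squared(30.0, 56) == 0.0
        assert i_squared(0.0, 5) == 0.0

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            i_squared(-1.0, 5)
        with pytest.raises(ValueError):
            i_squared(1.0, 0)


class TestWald:
    def test_zero_predictor_coefficients_give_null_statistic(self):
        fit = MetaFit(
            mu=np.array([[1.0, 2.0], [0.0, 0.0]]),
            mu_vcov=np.eye(4) * 0.1,
            psi=np.zeros((2, 2)), loglik=0.0, aic=0.0, q=0.0, q_df=1, q_p=1.0,
            i2_percent=0.0, predictor="u",
        )
        W, df, p = wald_test(fit)
        assert W == 0.0 and df == 2 and p == pytest.approx(1.0)

    def test_scalar_case_equals_z_squared(self):
        mi = random_input(k=10, v=1, seed=5, psi_scale=0.3, predictor=True)
        fit = mvmeta_fit(mi, predictor="u")
        W, df, _ = fit.wald
        b = fit.mu[1, 0]
        se = np.sqrt(fit.mu_vcov[1, 1])
        assert df == 1
        assert W == pytest.approx((b / se) ** 2, rel=1e-8)

    def test_requires_a_predictor_fit(self):
        mi = random_input(k=6, v=2, seed=6)
        fit = mvmeta_fit(mi)
        with pytest.raises(ValueError, match="predictor"):
            wald_test(fit)


class TestAic:
    def test_definitional_identity_between_nested_fits(self):
        mi = random_input(k=10, v=2, seed=7, psi_scale=0.3, predictor=True)
        f0 = mvmeta_fit(mi)
        f1 = mvmeta_fit(mi, predictor="u")
        d_par = 2  # one extra predictor row of 2 coefficients
        assert f1.aic - f0.aic == pytest.approx(
            -2.0 * (f1.loglik - f0.loglik) + 2 * d_par, abs=1e-9
        )
        assert aic(f1) == f1.aic

    def test_same_fit_evaluated_twice_is_identical(self):
        mi = random_input(k=8, v=2, seed=8, psi_scale=0.2)
        assert mvmeta_fit(mi).aic == mvmeta_fit(mi).aic

    def test_useless_predictor_usually_increases_aic(self):
        worse = 0
        n = 60
        for rep in range(n):
            mi = random_input(k=10, v=1, seed=100 + rep, psi_scale=0.2, predictor=True)
            f0 = mvmeta_fit(mi)
            f1 = mvmeta_fit(mi, predictor="u")  # predictor is pure noise
            worse += f1.aic > f0.aic
        assert worse > n / 2


class TestBlup:
    def test_psi_zero_shrinks_completely_to_pooled_mean(self):
        mi = random_input(k=6, v=2, seed=9)
        fit = mvmeta_fit(mi, psi="zero")
        for eta_b, _ in blup(mi, fit):
            assert np.allclose(eta_b, fit.pooled)

    def test_vanishing_within_city_variance_keeps_own_estimate(self):
        rng = np.random.default_rng(10)
        etas = rng.normal(0, 1, (5, 2))
        covs = np.tile(np.eye(2) * 0.5, (5, 1, 1))
        covs[3] = np.eye(2) * 1e-10
        mi = MetaInput(etas=etas, covs=covs)
        fit = mvmeta_fit(mi)
        eta_b, _ = blup(mi, fit)[3]
        assert np.allclose(eta_b, etas[3], atol=1e-4)

    def test_scalar_matches_empirical_bayes_closed_form(self):
        mi = random_input(k=9, v=1, seed=11, psi_scale=0.5)
        fit = mvmeta_fit(mi)
        preds = blup(mi, fit)
        for i, (eta_b, _) in enumerate(preds):
            expected = scalar_empirical_bayes_blup(
                mi.etas[i, 0], mi.covs[i, 0, 0], fit.pooled[0], fit.psi[0, 0]
            )
            assert eta_b[0] == pytest.approx(expected, abs=1e-8)

    def test_scalar_blup_lies_between_estimate_and_pooled_mean(self):
        mi = random_input(k=9, v=1, seed=12, psi_scale=0.5)
        fit = mvmeta_fit(mi)
        for i, (eta_b, _) in enumerate(blup(mi, fit)):
            lo, hi = sorted((mi.etas[i, 0], fit.pooled[0]))
            assert lo - 1e-9 <= eta_b[0] <= hi + 1e-9

    def test_shrinkage_map_eigenvalues_in_unit_interval(self):
        mi = random_input(k=7, v=3, seed=13, psi_scale=0.4)
        fit = mvmeta_fit(mi)
        for i in range(mi.k):
            A = fit.psi @ np.linalg.inv(fit.psi + mi.covs[i])
            eig = np.linalg.eigvals(A)
            assert np.all(eig.real >= -1e-9) and np.all(eig.real <= 1 + 1e-9)
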