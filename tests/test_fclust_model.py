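import numpy as np
import pytest
from scipy.stats import multivariate_normal
from scipy.special import logsumexp
from sklearn.metrics import adjusted_rand_score

import curveclust as cc
from conftest import random_dataset, random_params


def brute_force_loglik(params, ds, basis):
    """Independent dense oracle: per curve, explicit mixture of multivariate
    normal densities built from full covariance matrices."""
    total = 0.0
    mu = params.lambda0[None, :] + params.alpha @ params.Lambda.T
    for c in ds.curves:
        S = basis.design(c.times)
        cov = S @ params.Gamma @ S.T + params.sigma2 * np.eye(c.n_obs)
        comps = [np.log(params.pi[k])
                 + multivariate_normal.logpdf(c.values, S @ mu[k], cov)
                 for k in range(params.G)]
        total += logsumexp(comps)
    return float(total)


class TestLoglik:
    def test_zero_residual_unit_noise_closed_form(self, unit_basis):
        # G=1, Gamma=0, sigma2=1, values exactly on the mean curve:
        # each observation contributes -log(2*pi)/2
        rng = np.random.default_rng(0)
        lam0 = rng.normal(0, 1, unit_basis.p)
        curves = []
        n_total = 0
        for i in range(5):
            t = np.sort(rng.uniform(0, 1, 6))
            curves.append(cc.CurveObservations(f"c{i}", t, unit_basis.design(t) @ lam0))
            n_total += 6
        ds = cc.LongitudinalDataset(tuple(curves))
        params = cc.FCMParameters(1, unit_basis.p, 0, lam0,
                                  np.zeros((unit_basis.p, 0)), np.zeros((1, 0)),
                                  np.zeros((unit_basis.p, unit_basis.p)), 1.0,
                                  np.ones(1))
        ll = cc.loglik(params, ds, unit_basis)
        np.testing.assert_allclose(ll, -0.5 * n_total * np.log(2 * np.pi), rtol=1e-12)

    def test_matches_dense_oracle(self, unit_basis):
        rng = np.random.default_rng(7)
        ds = random_dataset(rng, unit_basis, n_curves=15)
        for _ in range(5):
            params = random_params(rng, G=3, p=unit_basis.p, h=2)
            ours = cc.loglik(params, ds, unit_basis)
            np.testing.assert_allclose(ours, brute_force_loglik(params, ds, unit_basis),
                                       rtol=1e-10, atol=1e-8)

    def test_doubling_noise_decreases_loglik_at_zero_residual(self, unit_basis):
        rng = np.random.default_rng(1)
        lam0 = rng.normal(0, 1, unit_basis.p)
        t = np.linspace(0.1, 0.9, 5)
        ds = cc.LongitudinalDataset((
            cc.CurveObservations("a", t, unit_basis.design(t) @ lam0),))
        mk = lambda s2: cc.FCMParameters(
            1, unit_basis.p, 0, lam0, np.zeros((unit_basis.p, 0)),
            np.zeros((1, 0)), np.zeros((unit_basis.p, unit_basis.p)), s2, np.ones(1))
        assert cc.loglik(mk(2.0), ds, unit_basis) < cc.loglik(mk(1.0), ds, unit_basis)


class TestFitFCM:
    def test_two_level_groups_recovered_exactly(self, affine_basis):
        rng = np.random.default_rng(3)
        curves = []
        labels = []
        for i in range(30):
            level = 0.0 if i % 2 == 0 else 10.0
            labels.append(i % 2)
            t = np.sort(rng.uniform(0, 1, 5))
            curves.append(cc.CurveObservations(
                f"c{i}", t, level + rng.normal(0, 0.1, 5)))
        ds = cc.LongitudinalDataset(tuple(curves))
        fit = cc.fit_fcm(ds, affine_basis, G=2, h=1, n_starts=2, seed=11)
        assert adjusted_rand_score(labels, fit.assignments) == 1.0

    def test_single_cluster_posteriors_all_one(self, unit_basis):
        rng = np.random.default_rng(4)
        ds = random_dataset(rng, unit_basis, n_curves=12)
        fit = cc.fit_fcm(ds, unit_basis, G=1, n_starts=1, seed=0)
        np.testing.assert_array_equal(fit.posteriors, 1.0)
        assert fit.params.h == 0

    def test_same_seed_reproduces_trace(self, ws3):
        spec, ds, truth, fit = ws3
        again = cc.fit_fcm(ds, spec.basis, G=3, h=2, n_starts=3, seed=1)
        np.testing.assert_array_equal(fit.loglik_trace, again.loglik_trace)
        np.testing.assert_array_equal(fit.posteriors, again.posteriors)

    def test_trace_monotone_and_posteriors_normalized(self, ws3):
        _, _, _, fit = ws3
        tr = fit.loglik_trace
        assert np.all(np.diff(tr) >= -1e-8 * np.abs(tr[:-1]))
        np.testing.assert_allclose(fit.posteriors.sum(axis=1), 1.0, atol=1e-10)
        assert np.all(fit.params.pi >= 1.0 / (10 * len(fit.curve_ids)) - 1e-12)
        np.testing.assert_allclose(fit.params.pi.sum(), 1.0, atol=1e-12)

    def test_identifiability_constraints_hold(self, ws3):
        spec, _, _, fit = ws3
        M0 = spec.basis.gram(0)
        L = fit.params.Lambda
        np.testing.assert_allclose(L.T @ M0 @ L, np.eye(fit.params.h), atol=1e-10)
        np.testing.assert_allclose(fit.params.pi @ fit.params.alpha, 0.0, atol=1e-8)

    def test_h_bound_enforced(self, unit_basis):
        rng = np.random.default_rng(5)
        ds = random_dataset(rng, unit_basis, n_curves=12)
        with pytest.raises(ValueError):
            cc.fit_fcm(ds, unit_basis, G=2, h=2, seed=0)  # h > G-1

    def test_permuting_cluster_labels_leaves_loglik_unchanged(self, ws3):
        spec, ds, _, fit = ws3
        p = fit.params
        perm = [2, 0, 1]
        permuted = cc.FCMParameters(p.G, p.p, p.h, p.lambda0, p.Lambda,
                                    p.alpha[perm], p.Gamma, p.sigma2, p.pi[perm])
        np.testing.assert_allclose(cc.loglik(permuted, ds, spec.basis),
                                   cc.loglik(p, ds, spec.basis), rtol=1e-12)


class TestClusterMeans:
    def test_single_cluster_mean_is_lambda0_curve(self, unit_basis):
        rng = np.random.default_rng(6)
        ds = random_dataset(rng, unit_basis, n_curves=10)
        fit = cc.fit_fcm(ds, unit_basis, G=1, n_starts=1, seed=0)
        t = np.linspace(0, 1, 20)
        np.testing.assert_allclose(
            cc.cluster_mean_curves(fit, t)[0],
            unit_basis.design(t) @ fit.params.lambda0, atol=1e-12)

    def test_matches_design_matrix_product(self, ws3):
        spec, _, _, fit = ws3
        t = spec.basis.knots
        expected = fit.params.means() @ spec.basis.design(t).T
        np.testing.assert_allclose(cc.cluster_mean_curves(fit, t), expected, atol=1e-12)


class TestPredictCurve:
    def test_vanishing_noise_interpolates_least_squares_spline(self, unit_basis):
        # sigma2 -> 0 with n_i >= p distinct times: the reconstruction equals
        # the regression spline through the observations
        rng = np.random.default_rng(8)
        t = np.linspace(0.02, 0.98, 9)
        y = np.sin(2 * t) + rng.normal(0, 0.05, t.size)
        curve = cc.CurveObservations("x", t, y)
        params = cc.FCMParameters(
            1, unit_basis.p, 0, np.zeros(unit_basis.p), np.zeros((unit_basis.p, 0)),
            np.zeros((1, 0)), 10.0 * np.eye(unit_basis.p), 1e-10, np.ones(1))
        fit = cc.FCMFit(params, unit_basis, ["x"], np.ones((1, 1)),
                        np.zeros(1, int), np.zeros((1, unit_basis.p)),
                        np.array([-1.0]), True, 0)
        grid = np.linspace(0, 1, 31)
        est = cc.predict_curve(fit, curve, grid)
        S = unit_basis.design(t)
        beta = np.linalg.lstsq(S, y, rcond=None)[0]
        np.testing.assert_allclose(est.mean, unit_basis.design(grid) @ beta, atol=1e-4)

    def test_vanishing_prior_collapses_to_cluster_mean(self, unit_basis):
        rng = np.random.default_rng(9)
        lam0 = rng.normal(0, 1, unit_basis.p)
        t = np.linspace(0.1, 0.9, 6)
        curve = cc.CurveObservations("x", t, rng.normal(5, 2, t.size))
        params = cc.FCMParameters(
            1, unit_basis.p, 0, lam0, np.zeros((unit_basis.p, 0)),
            np.zeros((1, 0)), 1e-14 * np.eye(unit_basis.p), 1.0, np.ones(1))
        fit = cc.FCMFit(params, unit_basis, ["x"], np.ones((1, 1)),
                        np.zeros(1, int), np.zeros((1, unit_basis.p)),
                        np.array([-1.0]), True, 0)
        grid = np.linspace(0, 1, 11)
        est = cc.predict_curve(fit, curve, grid)
        np.testing.assert_allclose(est.mean, unit_basis.design(grid) @ lam0, atol=1e-5)

    def test_band_ordering_and_width_growth(self, ws3):
        spec, ds, _, fit = ws3
        curve = ds.curves[0]
        inner = cc.predict_curve(fit, curve, curve.times)
        outer = cc.predict_curve(fit, curve, [spec.basis.boundary[1] + 30.0])
        assert np.all(inner.lower <= inner.mean) and np.all(inner.mean <= inner.upper)
        width_obs = (inner.upper - inner.lower).max()
        width_far = (outer.upper - outer.lower)[0]
        assert width_far > width_obs


class TestFitArchive:
    def test_roundtrip_bit_exact(self, ws3, tmp_path):
        _, _, _, fit = ws3
        cc.save_fit(fit, tmp_path / "arch")
        back = cc.load_fit(tmp_path / "arch")
        assert back.curve_ids == fit.curve_ids
        assert back.cluster_labels == fit.cluster_labels
        np.testing.assert_array_equal(back.posteriors, fit.posteriors)
        np.testing.assert_array_equal(back.coef_hat, fit.coef_hat)
        np.testing.assert_array_equal(back.params.Lambda, fit.params.Lambda)
        np.testing.assert_array_equal(back.params.Gamma, fit.params.Gamma)
        np.testing.assert_array_equal(back.params.alpha, fit.params.alpha)
        assert back.params.sigma2 == fit.params.sigma2
        np.testing.assert_array_equal(back.loglik_trace, fit.loglik_trace)
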