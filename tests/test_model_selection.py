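import numpy as np
import pytest
from sklearn.metrics import davies_bouldin_score

import curveclust as cc
from curveclust.errors import DegenerateClusteringError, FitFailureError
from curveclust import model_selection as msel
from conftest import random_dataset


def constant_fit(levels, labels, cluster_levels, basis):
    """Hand-built fit of constant curves: coefficient vectors of a constant c
    are c at every knot, so tightness and fDB reduce to scalar arithmetic."""
    levels = np.asarray(levels, float)
    labels = np.asarray(labels, int)
    G = len(cluster_levels)
    p = basis.p
    centers = np.asarray(cluster_levels, float)
    lam0 = np.full(p, centers.mean())
    if G > 1:
        alpha = (centers - centers.mean())[:, None]
        Lambda = np.full((p, 1), 1.0)
        h = 1
    else:
        alpha, Lambda, h = np.zeros((1, 0)), np.zeros((p, 0)), 0
    params = cc.FCMParameters(G, p, h, lam0, Lambda, alpha,
                              np.zeros((p, p)), 1.0, np.full(G, 1.0 / G))
    n = len(levels)
    post = np.zeros((n, G))
    post[np.arange(n), labels] = 1.0
    coef = np.repeat(levels[:, None], p, axis=1)
    return cc.FCMFit(params, basis, [f"c{i}" for i in range(n)], post, labels,
                     coef, np.array([0.0]), True, 0)


class TestDistance:
    def test_identity(self, unit_basis):
        f = np.array([1.0, -2.0, 0.5, 3.0])
        assert cc.distance_Dq(f, f, unit_basis, 0) == 0.0

    def test_linear_closed_forms(self, affine_basis):
        f = affine_basis.knots  # coefficients of f(t) = t
        g = np.zeros(2)
        np.testing.assert_allclose(cc.distance_Dq(f, g, affine_basis, 0), 1 / 3,
                                   rtol=1e-12)
        np.testing.assert_allclose(cc.distance_Dq(f, g, affine_basis, 1), 1.0,
                                   rtol=1e-12)

    def test_mismatched_basis(self, unit_basis):
        with pytest.raises(ValueError):
            cc.distance_Dq(np.zeros(3), np.zeros(3), unit_basis, 0)

    @pytest.mark.parametrize("q", [0, 1, 2])
    def test_matches_dense_numerical_integration(self, unit_basis, q):
        rng = np.random.default_rng(13)
        x = np.linspace(0, 1, 100001)
        Sq = unit_basis.design(x, q)
        for _ in range(10):
            f = rng.normal(0, 1, unit_basis.p)
            g = rng.normal(0, 1, unit_basis.p)
            dense = np.trapezoid((Sq @ (f - g)) ** 2, x)
            ours = cc.distance_Dq(f, g, unit_basis, q)
            np.testing.assert_allclose(ours, dense, rtol=1e-8, atol=1e-12)


class TestTightness:
    def test_hand_example_two_constants(self, affine_basis):
        # curves at levels 0 and 2, one cluster centered at 1, on [0,1]:
        # T = 1^2 + 1^2 = 2
        fit = constant_fit([0.0, 2.0], [0, 0], [1.0], affine_basis)
        np.testing.assert_allclose(cc.total_tightness(fit), 2.0, rtol=1e-12)

    def test_zero_when_curves_equal_their_means(self, affine_basis):
        fit = constant_fit([1.0, 1.0, 5.0], [0, 0, 1], [1.0, 5.0], affine_basis)
        assert cc.total_tightness(fit) == 0.0

    def test_zero_when_every_curve_its_own_cluster(self, affine_basis):
        levels = [0.0, 2.0, 5.0, 9.0]
        fit = constant_fit(levels, [0, 1, 2, 3], levels, affine_basis)
        assert cc.total_tightness(fit) == 0.0


class TestFDB:
    def test_hand_example(self, affine_basis):
        # clusters {0,2} (center 1) and {4,6} (center 5): S1=S2=1, M=4
        fit = constant_fit([0, 2, 4, 6], [0, 0, 1, 1], [1.0, 5.0], affine_basis)
        np.testing.assert_allclose(cc.fdb_index(fit, 0), 0.5, rtol=1e-12)

    def test_zero_dispersion(self, affine_basis):
        fit = constant_fit([1, 1, 5, 5], [0, 0, 1, 1], [1.0, 5.0], affine_basis)
        assert cc.fdb_index(fit, 0) == 0.0

    def test_single_cluster_rejected(self, affine_basis):
        fit = constant_fit([0.0, 2.0], [0, 0], [1.0], affine_basis)
        with pytest.raises(ValueError):
            cc.fdb_index(fit, 0)

    def test_identical_means_degenerate(self, affine_basis):
        fit = constant_fit([0, 2, 0, 2], [0, 0, 1, 1], [1.0, 1.0], affine_basis)
        with pytest.raises(DegenerateClusteringError):
            cc.fdb_index(fit, 0)

    def test_equals_classical_davies_bouldin_on_scalars(self, affine_basis):
        # clusters built from symmetric pairs, where the classical index's
        # mean dispersion equals our root-mean-square dispersion
        levels = np.array([0.0, 2.0, 5.0, 7.0, 11.0, 15.0])
        labels = np.array([0, 0, 1, 1, 2, 2])
        centers = [1.0, 6.0, 13.0]
        fit = constant_fit(levels, labels, centers, affine_basis)
        classical = davies_bouldin_score(levels[:, None], labels)
        np.testing.assert_allclose(cc.fdb_index(fit, 0), classical, atol=1e-10)


@pytest.fixture(scope="module")
def small_ds():
    spec = cc.get_scenario("well-separated-3")
    spec = cc.SimulationSpec(spec.name, spec.params, spec.basis, n_curves=40,
                             n_obs_range=(5, 8), seed=5)
    ds, _ = cc.simulate_dataset(spec)
    return ds


@pytest.fixture(scope="module")
def stability_result():
    spec = cc.get_scenario("well-separated-3")
    spec = cc.SimulationSpec(spec.name, spec.params, spec.basis, n_curves=36,
                             n_obs_range=(5, 8), seed=9)
    ds, truth = cc.simulate_dataset(spec)
    stab, per_run, modal = cc.stability_runs(ds, spec.basis, G=3, n_runs=5,
                                             seed=2, n_starts=2, max_iter=150)
    return ds, truth, stab, per_run, modal


class TestCrossValidation:
    def test_folds_partition_curves(self, small_ds, monkeypatch):
        held_out = []

        real_loglik = msel.loglik

        def spy(params, ds, basis):
            held_out.extend(ds.curve_ids)
            return real_loglik(params, ds, basis)

        monkeypatch.setattr(msel, "loglik", spy)
        cc.cross_validate_basis(small_ds, [3], G_cv=3, folds=5, seed=0, n_starts=1,
                                max_iter=60)
        assert sorted(held_out) == sorted(small_ds.curve_ids)

    def test_deterministic_given_seed(self, small_ds):
        a, _ = cc.cross_validate_basis(small_ds, [3, 4], G_cv=3, folds=5, seed=3,
                                       n_starts=1, max_iter=60)
        b, _ = cc.cross_validate_basis(small_ds, [3, 4], G_cv=3, folds=5, seed=3,
                                       n_starts=1, max_iter=60)
        for p in a:
            np.testing.assert_array_equal(a[p], b[p])

    def test_infeasible_p_flagged_not_fatal(self, small_ds):
        # p above the number of distinct pooled times cannot be built
        p_bad = sum(c.n_obs for c in small_ds.curves) + 1
        cv, knots = cc.cross_validate_basis(small_ds, [3, p_bad], G_cv=3, folds=5,
                                            seed=0, n_starts=1, max_iter=60)
        assert np.isnan(cv[p_bad]).all()
        assert knots[p_bad] is None
        assert np.isfinite(cv[3]).any()


class TestStability:
    def test_matrix_invariants(self, stability_result):
        _, _, stab, _, _ = stability_result
        assert np.array_equal(stab, stab.T)
        np.testing.assert_array_equal(np.diag(stab), 1.0)
        assert stab.min() >= 0.0 and stab.max() <= 1.0

    def test_separated_data_gives_binary_blocks(self, stability_result):
        _, truth, stab, _, _ = stability_result
        same = truth.labels[:, None] == truth.labels[None, :]
        np.testing.assert_array_equal(stab[same], 1.0)
        np.testing.assert_array_equal(stab[~same], 0.0)

    def test_modal_partition_when_all_runs_agree(self, stability_result):
        _, _, _, per_run, modal = stability_result
        parts = {rec["partition"] for rec in per_run}
        assert len(parts) == 1
        assert tuple(modal) in parts


class TestSelectH:
    def test_returns_hmax_on_abundant_data(self):
        spec = cc.get_scenario("well-separated-3")
        ds, _ = cc.simulate_dataset(spec, seed=12)
        h = cc.select_h(ds, spec.basis, G=3, freq_threshold=0.8, n_runs=3, seed=0,
                        max_iter=150)
        assert h == 2 == min(spec.basis.p, 3 - 1)

    def test_fault_injection_decrements_h(self, monkeypatch):
        spec = cc.get_scenario("well-separated-3")
        ds, _ = cc.simulate_dataset(spec, seed=12)
        real_fit = msel.fit_fcm
        calls = {"n": 0}

        def crippled(ds_, basis_, G, h=None, **kw):
            calls["n"] += 1
            if h == 2 and calls["n"] == 1:
                raise FitFailureError("injected failure")
            return real_fit(ds_, basis_, G, h=h, **kw)

        monkeypatch.setattr(msel, "fit_fcm", crippled)
        h = cc.select_h(ds, spec.basis, G=3, freq_threshold=1.0, n_runs=2, seed=0,
                        max_iter=120)
        assert h == 1

    def test_bounds(self):
        spec = cc.get_scenario("well-separated-3")
        ds, _ = cc.simulate_dataset(spec, seed=12)
        for G in (2, 3):
            h = cc.select_h(ds, spec.basis, G=G, freq_threshold=0.5, n_runs=2,
                            seed=1, max_iter=100)
            assert 1 <= h <= min(spec.basis.p, G - 1)
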