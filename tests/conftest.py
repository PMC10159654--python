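import numpy as np
import pytest

import curveclust as cc


@pytest.fixture(scope="session")
def unit_basis():
    """p=4 natural cubic basis on [0, 1]."""
    return cc.SplineBasis(p=4, interior_knots=np.array([1 / 3, 2 / 3]),
                          boundary=(0.0, 1.0))


@pytest.fixture(scope="session")
def affine_basis():
    """p=2 basis on [0, 1]: spans exactly the affine functions."""
    return cc.SplineBasis(p=2, interior_knots=np.empty(0), boundary=(0.0, 1.0))


@pytest.fixture(scope="session")
def ws3():
    """One simulated draw of the well-separated three-cluster scenario plus a
    converged fit at the true (G, h) — shared by the recovery-flavored tests."""
    spec = cc.get_scenario("well-separated-3")
    ds, truth = cc.simulate_dataset(spec, seed=42)
    fit = cc.fit_fcm(ds, spec.basis, G=3, h=2, n_starts=3, seed=1)
    return spec, ds, truth, fit


def random_params(rng, G, p, h, coef_scale=1.0):
    """Valid random model parameters for likelihood-level tests."""
    lambda0 = rng.normal(0, coef_scale, p)
    Lambda = rng.normal(0, coef_scale, (p, h))
    alpha = rng.normal(0, 1.0, (G, h))
    A = rng.normal(0, coef_scale, (p, p))
    Gamma = A @ A.T / p
    pi = rng.dirichlet(np.full(G, 5.0))
    return cc.FCMParameters(G, p, h, lambda0, Lambda, alpha, Gamma,
                            float(rng.uniform(0.5, 2.0)), pi)


def random_dataset(rng, basis, n_curves=20, n_obs=(4, 8), scale=1.0):
    """Small irregular dataset with no particular cluster structure."""
    a, b = basis.boundary
    curves = []
    for i in range(n_curves):
        m = int(rng.integers(n_obs[0], n_obs[1] + 1))
        t = np.sort(rng.uniform(a, b, m))
        while np.any(np.diff(t) <= 0):
            t = np.sort(rng.uniform(a, b, m))
        curves.append(cc.CurveObservations(f"c{i}", t, rng.normal(0, scale, m)))
    return cc.LongitudinalDataset(tuple(curves))
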