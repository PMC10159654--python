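"""Generative sampler from the spline random-effects mixture.

Draws datasets exactly from the fitted model's own data-generating process:
z_i ~ Categorical(pi), gamma_i ~ N(0, Gamma), per-curve observation times
from a sparse irregular sampling law, eps_i ~ N(0, sigma2 I), and
Y_i = S_i (lambda0 + Lambda alpha_{z_i} + gamma_i) + eps_i.

The shipped scenarios emulate weekly caliper measurements of engrafted tumor
volumes over a three-week treatment window: a [0, 21]-day window, 4-10
irregular observations per curve, replicate curves per parental sample, and
cluster-structured mean dynamics (regression, slow growth, fast growth).
Volumes are in mm^3.  Real caliper data additionally show value-dependent
noise, missing-not-at-random dropout of large tumors and occasional recording
errors, none of which the sampler reproduces.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np

from .data_io import CurveObservations, LongitudinalDataset
from .fclust_model import FCMParameters
from .spline_basis import SplineBasis

__all__ = ["SimulationSpec", "SimulationTruth", "simulate_dataset",
           "scenario_library", "params_from_mean_curves",
           "equidistant_mean_curves"]


@dataclass(frozen=True)
class SimulationSpec:
    """Complete description of one synthetic study.

    ``n_obs_range`` is the inclusive (low, high) range of per-curve
    observation counts.  ``time_sampling`` is ``"uniform"`` (times i.i.d.
    uniform on the window, then sorted — the sparse irregular regime) or
    ``"jitter"`` (a common equispaced grid, e.g. weekly measurements, with
    Gaussian jitter of sd ``jitter_sd``).  ``replicates`` > 1 groups curves
    under parental samples: the cluster label is drawn per parent and shared
    by its member curves, which keep independent random effects and noise.
    """

    name: str
    params: FCMParameters
    basis: SplineBasis
    n_curves: int
    n_obs_range: tuple[int, int] = (4, 10)
    time_sampling: str = "uniform"
    jitter_sd: float = 0.5
    replicates: int = 1
    seed: int = 0

    def validate(self) -> None:
        self.params.validate(allow_zero_noise=True)
        lo, hi = self.n_obs_range
        if not 1 <= lo <= hi:
            raise ValueError("n_obs_range must satisfy 1 <= low <= high")
        if self.n_curves < 1:
            raise ValueError("n_curves must be >= 1")
        if self.time_sampling not in ("uniform", "jitter"):
            raise ValueError(f"unknown time sampling law {self.time_sampling!r}")
        if self.replicates < 1 or self.n_curves % self.replicates:
            raise ValueError("replicates must divide n_curves")
        a, b = self.basis.boundary
        if not a < b:
            raise ValueError("degenerate window")


@dataclass(frozen=True)
class SimulationTruth:
    """Ground truth accompanying a simulated dataset, for recovery scoring."""

    labels: np.ndarray            # (n,) true cluster index per curve
    eta: np.ndarray               # (n, p) true coefficient vectors
    mean_coefs: np.ndarray        # (G, p) true cluster mean coefficients
    basis: SplineBasis
    params: FCMParameters
    parents: dict | None = None   # curve_id -> parent_id when replicated

    def mean_curves(self, eval_times) -> np.ndarray:
        return self.mean_coefs @ self.basis.design(eval_times).T


def _sample_times(rng, spec: SimulationSpec, n_obs: int) -> np.ndarray:
    a, b = spec.basis.boundary
    if spec.time_sampling == "uniform":
        t = np.sort(rng.uniform(a, b, size=n_obs))
        # enforce strictly increasing times (ties have probability ~0)
        while np.any(np.diff(t) <= 0):
            t = np.sort(rng.uniform(a, b, size=n_obs))
        return t
    grid = np.linspace(a, b, n_obs)
    t = np.clip(grid + rng.normal(0.0, spec.jitter_sd, size=n_obs), a, b)
    t = np.sort(t)
    if np.any(np.diff(t) <= 0):  # jitter collapsed two times: fall back
        return np.sort(rng.uniform(a, b, size=n_obs))
    return t


def simulate_dataset(spec: SimulationSpec, seed: int | None = None):
    """Draw one dataset from the model; returns (dataset, truth).

    Fully reproducible: the same spec and seed yield byte-identical data.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    params = spec.params
    mu = params.means()
    n = spec.n_curves
    n_parents = n // spec.replicates
    parent_labels = rng.choice(params.G, size=n_parents, p=params.pi)
    labels = np.repeat(parent_labels, spec.replicates)
    chol = np.linalg.cholesky(
        params.Gamma + 1e-12 * np.trace(params.Gamma + np.eye(params.p)) * np.eye(params.p)
    )
    width = len(str(n))
    curves, eta_all, parents = [], [], {}
    for i in range(n):
        eta = mu[labels[i]] + chol @ rng.standard_normal(params.p)
        n_obs = int(rng.integers(spec.n_obs_range[0], spec.n_obs_range[1] + 1))
        t = _sample_times(rng, spec, n_obs)
        S = spec.basis.design(t)
        y = S @ eta + np.sqrt(params.sigma2) * rng.standard_normal(n_obs)
        cid = f"c{str(i + 1).zfill(width)}"
        curves.append(CurveObservations(cid, t, y))
        eta_all.append(eta)
        if spec.replicates > 1:
            parents[cid] = f"s{str(i // spec.replicates + 1).zfill(len(str(n_parents)))}"
    ds = LongitudinalDataset(
        tuple(curves),
        annotations={c.curve_id: {"true_cluster": string.ascii_uppercase[k]}
                     for c, k in zip(curves, labels)},
        grouping=parents or None,
        time_window=spec.basis.boundary,
    )
    truth = SimulationTruth(labels=labels, eta=np.stack(eta_all), mean_coefs=mu,
                            basis=spec.basis, params=params,
                            parents=parents or None)
    return ds, truth


def params_from_mean_curves(knot_values, Gamma, sigma2, basis: SplineBasis,
                            h: int | None = None, pi=None) -> FCMParameters:
    """Build exact model parameters whose cluster mean curves are the natural
    cubic splines through the given values at the basis knots.

    The cardinal basis makes this direct: a curve's coefficient vector equals
    its values at the knots.  The requested means must be representable at
    rank h; the pi-centered knot-value matrix of G curves has rank at most
    min(p, G-1), so the default h is exact and a smaller h projects the means
    onto the best-fitting h-dimensional mean space.
    """
    mbar = np.asarray(knot_values, float)
    G, p = mbar.shape
    if p != basis.p:
        raise ValueError("one knot value per basis function is required")
    pi = np.full(G, 1.0 / G) if pi is None else np.asarray(pi, float)
    if h is None:
        h = min(p, G - 1)
    lambda0 = pi @ mbar
    C = mbar - lambda0
    if h > 0:
        _, _, Vt = np.linalg.svd(np.sqrt(pi)[:, None] * C, full_matrices=False)
        Vh = Vt[:h].T
        Lambda, alpha = Vh, C @ Vh
    else:
        Lambda, alpha = np.zeros((p, 0)), np.zeros((G, 0))
    return FCMParameters(G, p, h, lambda0, Lambda, alpha,
                         np.asarray(Gamma, float), float(sigma2), pi)


def equidistant_mean_curves(basis: SplineBasis, center, separation: float,
                            dir1, dir2) -> np.ndarray:
    """Three mean-coefficient vectors pairwise equidistant (distance
    ``separation``) in the L2 curve metric, arranged around ``center`` in the
    plane spanned by two shape directions (orthonormalized in the Gram
    metric).  Used to build cluster configurations with a single, exactly
    calibrated separation."""
    M0 = basis.gram(0)
    v1 = np.asarray(dir1, float)
    v2 = np.asarray(dir2, float)
    u1 = v1 / np.sqrt(v1 @ M0 @ v1)
    v2p = v2 - (v2 @ M0 @ u1) * u1
    u2 = v2p / np.sqrt(v2p @ M0 @ v2p)
    radius = separation / np.sqrt(3.0)
    angles = np.deg2rad([90.0, 210.0, 330.0])
    c = np.asarray(center, float)
    return np.stack([c + radius * (np.cos(a) * u1 + np.sin(a) * u2) for a in angles])


def scenario_library() -> dict[str, SimulationSpec]:
    """Fixed named scenarios used throughout the test battery.

    * ``well-separated-3``: three growth regimes (regression, growth, fast
      growth) with mean curves at least 8 noise-units apart in L2 — the
      parameter-recovery benchmark.
    * ``sparse-irregular``: the realistic regime — 4-10 irregular
      observations per curve, 4 replicate curves per parental sample,
      moderate noise.
    * ``equidistant-3``: three clusters whose mean curves are pairwise
      equidistant at exactly 8 noise-units in L2, with within-cluster
      coefficient sd about three times the noise sd — the cluster-number
      selection study, where a tightness/fDB scan over G should point at
      G = 3.
    * ``hierarchical-6``: three well-separated super-groups each splitting
      into two nearby sub-groups, for the two-stage sub-clustering workflow.
    * ``single-cluster``: the null case, one cluster and no mean space.
    """
    basis = SplineBasis(p=4, interior_knots=np.array([7.0, 14.0]), boundary=(0.0, 21.0))

    def spec(name, knot_values, sigma2, gamma_scale, n_curves, h=None, *,
             replicates=1, n_obs_range=(5, 8), seed=0):
        params = params_from_mean_curves(
            np.asarray(knot_values, float), gamma_scale * np.eye(4), sigma2, basis, h=h
        )
        return SimulationSpec(name=name, params=params, basis=basis,
                              n_curves=n_curves, n_obs_range=n_obs_range,
                              replicates=replicates, seed=seed)

    lib = {
        "well-separated-3": spec(
            "well-separated-3",
            [[100.0, 70.0, 50.0, 30.0],
             [100.0, 150.0, 200.0, 250.0],
             [100.0, 300.0, 600.0, 1000.0]],
            sigma2=25.0, gamma_scale=100.0, n_curves=150, h=2,
        ),
        "sparse-irregular": spec(
            "sparse-irregular",
            [[100.0, 75.0, 55.0, 40.0],
             [100.0, 140.0, 190.0, 240.0],
             [100.0, 250.0, 480.0, 800.0]],
            sigma2=225.0, gamma_scale=225.0, n_curves=200, h=2,
            replicates=4, n_obs_range=(4, 10),
        ),
        "equidistant-3": spec(
            "equidistant-3",
            equidistant_mean_curves(
                basis,
                center=[100.0, 130.0, 170.0, 220.0],
                separation=8.0 * np.sqrt(25.0 * 21.0),
                dir1=[0.0, -1.0, -2.0, -3.0],
                dir2=[0.0, 1.0, 3.0, 8.0],
            ),
            sigma2=25.0, gamma_scale=200.0, n_curves=90, h=2,
        ),
        "hierarchical-6": spec(
            "hierarchical-6",
            # three super-groups (regression / growth / fast growth), each
            # split into two nearby sub-groups at +- a fixed shape offset;
            # within-super distances stay well below between-super distances
            np.stack([
                c + s * np.array([0.0, 15.0, 25.0, 40.0])
                for c in np.array([[100.0, 70.0, 48.0, 35.0],
                                   [100.0, 150.0, 203.0, 255.0],
                                   [100.0, 335.0, 665.0, 1045.0]])
                for s in (+1.0, -1.0)
            ]),
            sigma2=64.0, gamma_scale=36.0, n_curves=120,
            n_obs_range=(6, 9),
        ),
        "single-cluster": spec(
            "single-cluster",
            [[100.0, 120.0, 140.0, 160.0]],
            sigma2=100.0, gamma_scale=100.0, n_curves=60, h=0,
        ),
    }
    return lib


def get_scenario(name: str) -> SimulationSpec:
    lib = scenario_library()
    try:
        return lib[name]
    except KeyError:
        raise KeyError(f"unknown scenario {name!r}; available: {sorted(lib)}") from None
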