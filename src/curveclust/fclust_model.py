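"""Gaussian spline random-effects mixture for curve clustering, fitted by EM.

Model
-----
Each curve i is observed at its own times t_i1..t_in_i with values
Y_i = S_i (lambda0 + Lambda alpha_{z_i} + gamma_i) + eps_i, where

* S_i is the n_i x p natural cubic spline design matrix of the curve,
* z_i is the latent cluster label with mixing weights pi_k,
* cluster means live in a reduced-rank affine subspace of coefficient
  space: mu_k = lambda0 + Lambda alpha_k with Lambda p x h,
  h <= min(p, G - 1),
* gamma_i ~ N(0, Gamma) is a per-curve spline-coefficient random effect
  with a single Gamma shared by all clusters,
* eps_i ~ N(0, sigma2 I) is i.i.d. measurement noise.

Marginally Y_i | z_i = k ~ N(S_i mu_k, S_i Gamma S_i^T + sigma2 I), which is
what the observed-data log-likelihood and the E-step responsibilities use.

Estimation is EM with closed-form conditional M-steps: responsibilities and
posterior moments of the per-curve coefficients in the E-step; then (i) the
reduced-rank mean structure by a weighted rank-h fit of the cluster posterior
means in the Gamma^-1 metric, (ii) Gamma and sigma2 from expected
complete-data sufficient statistics, (iii) pi_k as mean responsibility.
After every M-step the parameterization is normalized (pi-weighted mean of
the alpha_k set to zero, Lambda columns orthonormal in the L2 Gram metric)
so that independent runs are comparable; this is a pure reparameterization
and leaves the likelihood unchanged.
"""

from __future__ import annotations

import json
import logging
import os
import string
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp
from scipy.stats import norm

from .data_io import CurveObservations, LongitudinalDataset
from .errors import FitFailureError
from .spline_basis import SplineBasis

logger = logging.getLogger("curveclust")

__all__ = [
    "FCMParameters",
    "FCMFit",
    "CurveEstimate",
    "loglik",
    "fit_fcm",
    "cluster_mean_curves",
    "predict_curve",
    "save_fit",
    "load_fit",
]

_LOG2PI = float(np.log(2.0 * np.pi))


# --------------------------------------------------------------------------
# parameter container
# --------------------------------------------------------------------------

@dataclass
class FCMParameters:
    """All free parameters of the mixture: dimensions (G, p, h), the mean
    structure (lambda0, Lambda, alpha), the random-effect covariance Gamma,
    the noise variance sigma2 and the mixing weights pi."""

    G: int
    p: int
    h: int
    lambda0: np.ndarray          # (p,)
    Lambda: np.ndarray           # (p, h)
    alpha: np.ndarray            # (G, h)
    Gamma: np.ndarray            # (p, p)
    sigma2: float
    pi: np.ndarray               # (G,)

    def __post_init__(self):
        self.lambda0 = np.asarray(self.lambda0, float).reshape(self.p)
        self.Lambda = np.asarray(self.Lambda, float).reshape(self.p, self.h)
        self.alpha = np.asarray(self.alpha, float).reshape(self.G, self.h)
        self.Gamma = np.asarray(self.Gamma, float).reshape(self.p, self.p)
        self.pi = np.asarray(self.pi, float).reshape(self.G)

    def validate(self, atol: float = 1e-8, allow_zero_noise: bool = False) -> None:
        if self.G < 1:
            raise ValueError("G must be >= 1")
        hmax = min(self.p, self.G - 1)
        if not 0 <= self.h <= hmax:
            raise ValueError(f"h={self.h} violates 0 <= h <= min(p, G-1) = {hmax}")
        if allow_zero_noise and self.sigma2 == 0:
            pass  # noise-free limit is meaningful for simulation only
        elif self.sigma2 <= 0:
            raise ValueError("sigma2 must be > 0")
        if np.any(self.pi <= 0) or abs(self.pi.sum() - 1.0) > atol:
            raise ValueError("mixing weights must be positive and sum to 1")
        if not np.allclose(self.Gamma, self.Gamma.T, atol=atol):
            raise ValueError("Gamma must be symmetric")
        w = np.linalg.eigvalsh(0.5 * (self.Gamma + self.Gamma.T))
        if w.min() < -atol * max(1.0, w.max()):
            raise ValueError("Gamma must be positive semidefinite")

    def means(self) -> np.ndarray:
        """Cluster mean coefficient vectors mu_k = lambda0 + Lambda alpha_k, (G, p)."""
        return self.lambda0[None, :] + self.alpha @ self.Lambda.T

    def copy(self) -> "FCMParameters":
        return FCMParameters(self.G, self.p, self.h, self.lambda0.copy(),
                             self.Lambda.copy(), self.alpha.copy(),
                             self.Gamma.copy(), float(self.sigma2), self.pi.copy())


@dataclass
class FCMFit:
    """A fitted model: parameters, per-curve posterior memberships, hard
    assignments, per-curve posterior-mean spline coefficients and the EM
    log-likelihood trace."""

    params: FCMParameters
    basis: SplineBasis
    curve_ids: list[str]
    posteriors: np.ndarray       # (n, G)
    assignments: np.ndarray      # (n,) int, argmax posterior
    coef_hat: np.ndarray         # (n, p) posterior-mean coefficients | assigned cluster
    loglik_trace: np.ndarray
    converged: bool
    seed: int
    cluster_labels: list[str] = field(default_factory=list)
    n_failed_starts: int = 0

    def __post_init__(self):
        if not self.cluster_labels:
            self.cluster_labels = [_letter_label(k) for k in range(self.params.G)]

    @property
    def loglik(self) -> float:
        return float(self.loglik_trace[-1])

    @property
    def cluster_sizes(self) -> np.ndarray:
        return np.bincount(self.assignments, minlength=self.params.G)

    def assignment_labels(self) -> list[str]:
        return [self.cluster_labels[k] for k in self.assignments]


@dataclass
class CurveEstimate:
    """Dense reconstruction of one curve with a pointwise confidence band."""

    curve_id: str
    eval_times: np.ndarray
    mean: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    cluster: str


def _letter_label(k: int) -> str:
    letters = string.ascii_uppercase
    return letters[k] if k < 26 else f"K{k + 1}"


# --------------------------------------------------------------------------
# batched curve pack: curves grouped by n_i so the EM sweeps are vectorized
# --------------------------------------------------------------------------

class _CurvePack:
    def __init__(self, ds: LongitudinalDataset, basis: SplineBasis):
        self.curve_ids = ds.curve_ids
        self.n_curves = ds.n_curves
        self.p = basis.p
        by_len: dict[int, list[int]] = {}
        for i, c in enumerate(ds.curves):
            by_len.setdefault(c.n_obs, []).append(i)
        self.groups = []
        for n_obs in sorted(by_len):
            idx = np.asarray(by_len[n_obs], int)
            Y = np.stack([ds.curves[i].values for i in idx])
            S = np.stack([basis.design(ds.curves[i].times) for i in idx])
            self.groups.append((idx, Y, S))
        self.total_obs = sum(c.n_obs for c in ds.curves)
        # per-curve coefficient estimates used at initialization: in the
        # cardinal basis a coefficient is the curve's value at a knot, so
        # piecewise-linear interpolation of the raw observations onto the
        # knots gives a bounded, well-conditioned estimate even for curves
        # with fewer observations than basis functions, where an unpenalized
        # or lightly ridged regression fit degenerates.  Knots outside a
        # curve's observed range are filled by linear extrapolation of the
        # edge segments (clamping instead badly biases boundary-knot values
        # for steep curves), mirroring the natural spline's linear tails.
        knots = basis.knots
        span_min = 0.25 * (knots[-1] - knots[0])
        self.init_coef = np.stack([
            _interp_extrap(knots, c.times, c.values, span_min) for c in ds.curves
        ])



def _interp_extrap(x, xp, yp, span_min: float) -> np.ndarray:
    """np.interp with damped linear extrapolation beyond the observed range.

    Edge slopes are taken between the edge observation and the nearest
    observation at least ``span_min`` away (falling back to the farthest),
    so that two nearby noisy edge points cannot produce an exploding slope.
    """
    out = np.interp(x, xp, yp)
    if len(xp) < 2:
        return out
    lo = x < xp[0]
    hi = x > xp[-1]
    if lo.any():
        j = next((j for j in range(1, len(xp)) if xp[j] - xp[0] >= span_min),
                 len(xp) - 1)
        slope = (yp[j] - yp[0]) / (xp[j] - xp[0])
        out[lo] = yp[0] + slope * (x[lo] - xp[0])
    if hi.any():
        j = next((j for j in range(len(xp) - 2, -1, -1)
                  if xp[-1] - xp[j] >= span_min), 0)
        slope = (yp[-1] - yp[j]) / (xp[-1] - xp[j])
        out[hi] = yp[-1] + slope * (x[hi] - xp[-1])
    return out


class _StartFailed(Exception):
    """One EM start hit a degeneracy (empty cluster / singular covariance)."""


def _estep(pack: _CurvePack, params: FCMParameters, moments: bool = True):
    """Responsibilities, observed-data log-likelihood and (optionally) the
    per-curve posterior moments of the spline coefficients.

    Returns (loglik, log_resp (n, G), m (n, G, p), V (n, p, p)); the posterior
    covariance V does not depend on the cluster because Gamma is shared.
    """
    G, p = params.G, params.p
    mu = params.means()
    logpi = np.log(params.pi)
    n = pack.n_curves
    log_resp = np.empty((n, G))
    ll = 0.0
    m = np.empty((n, G, p)) if moments else None
    V = np.empty((n, p, p)) if moments else None
    for idx, Y, S in pack.groups:
        B, n_obs, _ = S.shape
        SG = S @ params.Gamma
        Sig = SG @ np.swapaxes(S, 1, 2) + params.sigma2 * np.eye(n_obs)
        sign, logdet = np.linalg.slogdet(Sig)
        if np.any(sign <= 0):
            raise _StartFailed("marginal covariance not positive definite")
        R = Y[:, None, :] - np.einsum("bnp,gp->bgn", S, mu)      # (B, G, n)
        rhs = np.concatenate([np.swapaxes(R, 1, 2), SG], axis=2)  # (B, n, G+p)
        try:
            X = np.linalg.solve(Sig, rhs)
        except np.linalg.LinAlgError as exc:
            raise _StartFailed(f"singular marginal covariance: {exc}") from exc
        U, W = X[:, :, :G], X[:, :, G:]
        quad = np.einsum("bgn,bng->bg", R, U)
        lw = logpi[None, :] - 0.5 * (n_obs * _LOG2PI + quad) - 0.5 * logdet[:, None]
        ll_i = logsumexp(lw, axis=1)
        ll += float(ll_i.sum())
        log_resp[idx] = lw - ll_i[:, None]
        if moments:
            m[idx] = mu[None, :, :] + np.einsum("bnp,bng->bgp", SG, U)
            V[idx] = params.Gamma - np.einsum("bnp,bnq->bpq", SG, W)
    return ll, log_resp, m, V


def _psd_sqrt_pair(Gamma: np.ndarray):
    """(Gamma^{1/2}, Gamma^{-1/2}) via eigendecomposition with an eigenvalue
    floor, so a PSD-singular Gamma still yields a usable working metric."""
    Gs = 0.5 * (Gamma + Gamma.T)
    w, Q = np.linalg.eigh(Gs)
    floor = max(w.max(), 0.0) * 1e-12 + 1e-300
    w = np.maximum(w, floor)
    return (Q * np.sqrt(w)) @ Q.T, (Q / np.sqrt(w)) @ Q.T


def _reduced_rank_means(mbar: np.ndarray, nk: np.ndarray, Gamma: np.ndarray, h: int):
    """Weighted rank-h affine fit of the cluster coefficient means in the
    Gamma^-1 metric: returns (lambda0, Lambda, alpha)."""
    G, p = mbar.shape
    lambda0 = nk @ mbar / nk.sum()
    C = mbar - lambda0
    if h == 0:
        return lambda0, np.zeros((p, 0)), np.zeros((G, 0))
    Gsq, Gih = _psd_sqrt_pair(Gamma)
    D = C @ Gih                      # cluster offsets, whitened
    Xw = np.sqrt(nk)[:, None] * D
    _, _, Vt = np.linalg.svd(Xw, full_matrices=False)
    Vh = Vt[:h].T                    # (p, h)
    return lambda0, Gsq @ Vh, D @ Vh


def _normalize_identifiability(params: FCMParameters, M0: np.ndarray) -> None:
    """In place: pi-weighted mean of alpha_k zeroed (folded into lambda0) and
    Lambda columns orthonormalized in the M0 metric (folded into alpha), with
    a deterministic sign convention.  Leaves every mu_k unchanged."""
    if params.h == 0:
        return
    abar = params.pi @ params.alpha
    params.lambda0 = params.lambda0 + params.Lambda @ abar
    params.alpha = params.alpha - abar
    B = params.Lambda.T @ M0 @ params.Lambda
    w, Q = np.linalg.eigh(0.5 * (B + B.T))
    w = np.maximum(w, w.max() * 1e-14 + 1e-300)
    A = (Q / np.sqrt(w)) @ Q.T       # B^{-1/2}
    Ainv = (Q * np.sqrt(w)) @ Q.T
    params.Lambda = params.Lambda @ A
    params.alpha = params.alpha @ Ainv
    # sign convention: largest-magnitude entry of each column positive
    for j in range(params.h):
        col = params.Lambda[:, j]
        if col[np.argmax(np.abs(col))] < 0:
            params.Lambda[:, j] = -col
            params.alpha[:, j] = -params.alpha[:, j]


def _mstep(pack: _CurvePack, params: FCMParameters, log_resp, m, V, M0,
           min_cluster_mass: float) -> FCMParameters:
    G, p = params.G, params.p
    n = pack.n_curves
    r = np.exp(log_resp)
    nk = r.sum(axis=0)
    if np.any(nk < min_cluster_mass):
        raise _StartFailed(
            f"cluster responsibility mass dropped below {min_cluster_mass} "
            f"curves (masses {np.round(nk, 3)})"
        )
    pi = np.maximum(nk / n, 1.0 / (10.0 * n))
    pi = pi / pi.sum()

    mbar = np.einsum("ig,igp->gp", r, m) / nk[:, None]
    lambda0, Lambda, alpha = _reduced_rank_means(mbar, nk, params.Gamma, params.h)
    mu = lambda0[None, :] + alpha @ Lambda.T

    dev = m - mu[None, :, :]                                   # (n, G, p)
    Gamma = (V.sum(axis=0) + np.einsum("ig,igp,igq->pq", r, dev, dev)) / n
    Gamma = 0.5 * (Gamma + Gamma.T)
    try:
        np.linalg.cholesky(Gamma + 0.0)
    except np.linalg.LinAlgError:
        Gamma = Gamma + (1e-8 * np.trace(Gamma) / p) * np.eye(p)
        try:
            np.linalg.cholesky(Gamma)
        except np.linalg.LinAlgError as exc:
            raise _StartFailed(f"random-effect covariance collapsed: {exc}") from exc

    sse = 0.0
    for idx, Y, S in pack.groups:
        fitted = np.einsum("bnp,bgp->bgn", S, m[idx])
        resid2 = ((Y[:, None, :] - fitted) ** 2).sum(axis=2)    # (B, G)
        sse += float((r[idx] * resid2).sum())
        sse += float(np.einsum("bnp,bpq,bnq->", S, V[idx], S))
    sigma2 = max(sse / pack.total_obs, 1e-300)

    out = FCMParameters(G, p, params.h, lambda0, Lambda, alpha, Gamma, sigma2, pi)
    _normalize_identifiability(out, M0)
    return out


def _init_params(pack: _CurvePack, basis: SplineBasis, G: int, h: int,
                 seed: int, M0: np.ndarray,
                 strategy: str = "largest_cluster") -> FCMParameters:
    """Data-driven start: per-curve coefficient estimates from knot
    interpolation, bisecting k-means on the coefficient vectors, then moment
    estimates from the hard partition.

    Bisecting k-means is used rather than plain k-means because on
    well-separated data plain k-means at G above the natural cluster number
    tends to carve off a few stray curves, a start the E-step immediately
    starves; bisecting splits are balanced and give over-clustered starts a
    fighting chance.  The two bisecting strategies favor different data
    shapes (``largest_cluster`` is robust to clusters of very unequal
    spread, ``biggest_inertia`` finds variance-dominated substructure), so
    multi-start fits alternate between them and keep the best final
    log-likelihood."""
    p = basis.p
    n = pack.n_curves
    eta = pack.init_coef
    if G == 1:
        labels = np.zeros(n, int)
    else:
        from sklearn.cluster import BisectingKMeans

        labels = BisectingKMeans(
            n_clusters=G, random_state=int(seed) % (2**31),
            bisecting_strategy=strategy,
        ).fit_predict(eta)
    counts = np.bincount(labels, minlength=G).astype(float)
    if np.any(counts < 1):
        raise _StartFailed("k-means initialization produced an empty cluster")
    mbar = np.stack([eta[labels == k].mean(axis=0) for k in range(G)])
    dev = eta - mbar[labels]
    yvar = float(np.var(np.concatenate([Y.ravel() for _, Y, _ in pack.groups])))
    Gamma = dev.T @ dev / n + (1e-6 * yvar + 1e-10) * np.eye(p)
    sse = 0.0
    for idx, Y, S in pack.groups:
        sse += float(((Y - np.einsum("bnp,bp->bn", S, eta[idx])) ** 2).sum())
    sigma2 = max(sse / pack.total_obs, 1e-6 * yvar, 1e-12)
    pi = np.maximum(counts / n, 1.0 / (10.0 * n))
    pi = pi / pi.sum()
    lambda0, Lambda, alpha = _reduced_rank_means(mbar, counts, Gamma, h)
    params = FCMParameters(G, p, h, lambda0, Lambda, alpha, Gamma, sigma2, pi)
    _normalize_identifiability(params, M0)
    return params


def _em_single(pack: _CurvePack, basis: SplineBasis, G: int, h: int, seed: int,
               tol: float, max_iter: int, min_cluster_mass: float, M0: np.ndarray,
               strategy: str = "largest_cluster"):
    params = _init_params(pack, basis, G, h, seed, M0, strategy)
    trace = []
    converged = False
    prev = -np.inf
    log_resp = m = V = None
    for _ in range(max_iter):
        ll, log_resp, m, V = _estep(pack, params)
        trace.append(ll)
        if np.isfinite(prev) and abs(ll - prev) <= tol * (abs(prev) + 1e-10):
            converged = True
            break
        prev = ll
        params = _mstep(pack, params, log_resp, m, V, M0, min_cluster_mass)
    return params, np.exp(log_resp), m, np.asarray(trace), converged


# --------------------------------------------------------------------------
# public operations
# --------------------------------------------------------------------------

def loglik(params: FCMParameters, ds: LongitudinalDataset, basis: SplineBasis) -> float:
    """Observed-data log-likelihood sum_i log sum_k pi_k phi(Y_i; S_i mu_k,
    S_i Gamma S_i^T + sigma2 I)."""
    params.validate()
    pack = ds if isinstance(ds, _CurvePack) else _CurvePack(ds, basis)
    try:
        ll, _, _, _ = _estep(pack, params, moments=False)
    except _StartFailed as exc:
        raise np.linalg.LinAlgError(str(exc)) from exc
    return ll


def fit_fcm(
    ds: LongitudinalDataset,
    basis: SplineBasis,
    G: int,
    h: int | None = None,
    n_starts: int = 5,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 500,
    min_cluster_mass: float = 2.0,
) -> FCMFit:
    """Fit the mixture by EM from ``n_starts`` k-means initializations and
    return the best run by final observed-data log-likelihood.

    ``h`` defaults to min(p, G-1).  Clusters in the returned fit are relabeled
    by decreasing size (ties broken by first member) and lettered A, B, C, ...
    A start fails if a cluster's responsibility mass drops below
    ``min_cluster_mass`` curves or a covariance turns singular; if every start
    fails a :class:`FitFailureError` carrying the per-start diagnostics is
    raised (this failure signal is what automatic h selection consumes).
    """
    if G < 1:
        raise ValueError("G must be >= 1")
    hmax = min(basis.p, G - 1)
    if h is None:
        h = hmax
    if not 0 <= h <= hmax:
        raise ValueError(f"h={h} violates 0 <= h <= min(p, G-1) = {hmax}")
    pack = _CurvePack(ds, basis)
    if G > pack.n_curves:
        raise ValueError(f"G={G} exceeds the number of curves ({pack.n_curves})")
    M0 = basis.gram(0)
    start_seeds = (np.random.SeedSequence(seed).generate_state(max(n_starts, 1))
                   % (2**31)).astype(int)
    best = None
    diagnostics = []
    strategies = ("largest_cluster", "biggest_inertia")
    for i, s in enumerate(start_seeds):
        strategy = strategies[i % 2]
        try:
            result = _em_single(pack, basis, G, h, int(s), tol, max_iter,
                                min_cluster_mass, M0, strategy)
        except (_StartFailed, np.linalg.LinAlgError) as exc:
            diagnostics.append({"start_seed": int(s), "strategy": strategy,
                                "error": str(exc)})
            continue
        if best is None or result[3][-1] > best[3][-1]:
            best = result
    if best is None:
        raise FitFailureError(
            f"all {len(start_seeds)} EM starts failed for G={G}, h={h}", diagnostics
        )
    params, posteriors, m, trace, converged = best

    # deterministic relabeling: decreasing responsibility mass, ties by the
    # index of the first hard-assigned curve
    hard = posteriors.argmax(axis=1)
    mass = posteriors.sum(axis=0)
    first = np.full(params.G, pack.n_curves)
    for i, k in enumerate(hard):
        first[k] = min(first[k], i)
    order = sorted(range(params.G), key=lambda k: (-mass[k], first[k]))
    params = FCMParameters(params.G, params.p, params.h, params.lambda0,
                           params.Lambda, params.alpha[order], params.Gamma,
                           params.sigma2, params.pi[order])
    M0b = basis.gram(0)
    _normalize_identifiability(params, M0b)
    posteriors = posteriors[:, order]
    m = m[:, order, :]
    assignments = posteriors.argmax(axis=1)
    coef_hat = m[np.arange(pack.n_curves), assignments]
    return FCMFit(
        params=params,
        basis=basis,
        curve_ids=list(pack.curve_ids),
        posteriors=posteriors,
        assignments=assignments,
        coef_hat=coef_hat,
        loglik_trace=trace,
        converged=converged,
        seed=int(seed),
        n_failed_starts=len(diagnostics),
    )


def cluster_mean_curves(fit: FCMFit, eval_times) -> np.ndarray:
    """Cluster mean curves g_k(t) = s(t)^T (lambda0 + Lambda alpha_k), (G, T)."""
    S = fit.basis.design(eval_times)
    return fit.params.means() @ S.T


def _posterior_for_curve(fit: FCMFit, curve: CurveObservations):
    """Responsibilities, per-cluster posterior coefficient means and the
    (cluster-independent) posterior covariance for one curve."""
    params = fit.params
    S = fit.basis.design(curve.times)
    mu = params.means()
    SG = S @ params.Gamma
    Sig = SG @ S.T + params.sigma2 * np.eye(curve.n_obs)
    R = curve.values[None, :] - mu @ S.T                       # (G, n)
    X = np.linalg.solve(Sig, np.concatenate([R.T, SG], axis=1))
    U, W = X[:, : params.G], X[:, params.G:]
    quad = np.einsum("gn,ng->g", R, U)
    _, logdet = np.linalg.slogdet(Sig)
    lw = np.log(params.pi) - 0.5 * (curve.n_obs * _LOG2PI + quad) - 0.5 * logdet
    w = np.exp(lw - logsumexp(lw))
    m = mu + (SG.T @ U).T                                      # (G, p)
    V = params.Gamma - SG.T @ W
    return w, m, 0.5 * (V + V.T)


def predict_curve(
    fit: FCMFit,
    curve: CurveObservations,
    eval_times,
    alpha_level: float = 0.05,
    map_threshold: float = 0.99,
) -> CurveEstimate:
    """Reconstruct one curve on a dense grid with a pointwise 1 - alpha band.

    Per cluster k the coefficients have the conjugate Gaussian posterior
    N(m_k, V) from prior N(mu_k, Gamma) and likelihood Y ~ N(S eta, sigma2 I).
    When the top membership probability exceeds ``map_threshold`` the band
    conditions on that cluster; otherwise mean and variance mix over the
    memberships, so uncertain curves get honestly wider (possibly multimodal
    in origin) bands.
    """
    eval_times = np.atleast_1d(np.asarray(eval_times, float))
    w, m, V = _posterior_for_curve(fit, curve)
    St = fit.basis.design(eval_times)
    var_coef = np.einsum("tp,pq,tq->t", St, V, St)
    k_map = int(np.argmax(w))
    if w[k_map] >= map_threshold:
        mean = St @ m[k_map]
        var = var_coef
    else:
        means_k = St @ m.T                                     # (T, G)
        mean = means_k @ w
        var = var_coef + (means_k**2) @ w - mean**2
    z = norm.ppf(1.0 - alpha_level / 2.0)
    half = z * np.sqrt(np.maximum(var, 0.0))
    return CurveEstimate(
        curve_id=curve.curve_id,
        eval_times=eval_times,
        mean=mean,
        lower=mean - half,
        upper=mean + half,
        cluster=fit.cluster_labels[k_map],
    )


# --------------------------------------------------------------------------
# fit archive: plain-text matrices + a JSON metadata file, re-importable
# bit-exactly
# --------------------------------------------------------------------------

def _savetxt(path, arr):
    np.savetxt(path, np.atleast_2d(np.asarray(arr, float)), fmt="%.17g", delimiter="\t")


def save_fit(fit: FCMFit, path) -> None:
    """Write the fit to a directory of plain-text matrices plus meta.json."""
    os.makedirs(path, exist_ok=True)
    params = fit.params
    meta = {
        "G": params.G, "p": params.p, "h": params.h,
        "sigma2": params.sigma2,
        "pi": params.pi.tolist(),
        "boundary": list(fit.basis.boundary),
        "interior_knots": fit.basis.interior_knots.tolist(),
        "seed": fit.seed,
        "converged": bool(fit.converged),
        "cluster_labels": fit.cluster_labels,
        "curve_ids": fit.curve_ids,
        "assignments": fit.assignments.tolist(),
        "loglik_trace": fit.loglik_trace.tolist(),
        "n_failed_starts": fit.n_failed_starts,
    }
    with open(os.path.join(path, "meta.json"), "w") as fh:
        json.dump(meta, fh, indent=1)
    _savetxt(os.path.join(path, "lambda0.tsv"), params.lambda0)
    _savetxt(os.path.join(path, "Gamma.tsv"), params.Gamma)
    _savetxt(os.path.join(path, "posteriors.tsv"), fit.posteriors)
    _savetxt(os.path.join(path, "coef_hat.tsv"), fit.coef_hat)
    if params.h > 0:
        _savetxt(os.path.join(path, "Lambda.tsv"), params.Lambda)
        _savetxt(os.path.join(path, "alpha.tsv"), params.alpha)


def load_fit(path) -> FCMFit:
    """Re-import a fit archive written by :func:`save_fit`."""
    with open(os.path.join(path, "meta.json")) as fh:
        meta = json.load(fh)
    G, p, h = meta["G"], meta["p"], meta["h"]
    basis = SplineBasis(p=p, interior_knots=np.asarray(meta["interior_knots"]),
                        boundary=tuple(meta["boundary"]))
    load = lambda name: np.loadtxt(os.path.join(path, name), delimiter="\t", ndmin=2)
    lambda0 = load("lambda0.tsv").reshape(p)
    Gamma = load("Gamma.tsv")
    if h > 0:
        Lambda = load("Lambda.tsv").reshape(p, h)
        alpha = load("alpha.tsv").reshape(G, h)
    else:
        Lambda, alpha = np.zeros((p, 0)), np.zeros((G, 0))
    params = FCMParameters(G, p, h, lambda0, Lambda, alpha, Gamma,
                           meta["sigma2"], np.asarray(meta["pi"]))
    return FCMFit(
        params=params,
        basis=basis,
        curve_ids=list(meta["curve_ids"]),
        posteriors=load("posteriors.tsv").reshape(len(meta["curve_ids"]), G),
        assignments=np.asarray(meta["assignments"], int),
        coef_hat=load("coef_hat.tsv").reshape(len(meta["curve_ids"]), p),
        loglik_trace=np.asarray(meta["loglik_trace"], float),
        converged=meta["converged"],
        seed=meta["seed"],
        cluster_labels=list(meta["cluster_labels"]),
        n_failed_starts=meta["n_failed_starts"],
    )
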