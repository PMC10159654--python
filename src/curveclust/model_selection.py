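"""Free-parameter selection toolkit: curve semi-metrics, total tightness,
the functional Davies-Bouldin index, cross-validated likelihood over the
basis dimension, run-to-run stability matrices and automatic selection of
the mean-space dimension h.

Semi-metric
-----------
D_q(f, g) = integral over the window of |f^(q)(s) - g^(q)(s)|^2 ds for
q in {0, 1, 2}; q = 0 is the squared L2 distance.  For spline-represented
curves this is the exact quadratic form (f - g)^T M_q (f - g) in the basis
Gram matrix of the q-th derivatives — no numerical differentiation enters.

Total tightness sums, over curves, the D_0 distance between each estimated
curve and its assigned cluster's mean curve; it decreases with the number of
clusters and reaches zero when every curve is its own cluster and estimated
curves coincide with their cluster means.  The fDB index averages, over
clusters, the worst (S_k' + S_k) / M_k'k ratio, where S_k is the root-mean
dispersion sqrt(mean_i D_q(g_i, gbar_k)) and M_k'k = sqrt(D_q(gbar_k',
gbar_k)) the centroid distance; both are taken on the root (curve-unit)
scale so that for constant curves the index reduces to the classical
Davies-Bouldin index on the scalar levels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import KFold

from .data_io import LongitudinalDataset, summarize_grid
from .errors import DegenerateClusteringError, FitFailureError, InfeasibleBasisError
from .fclust_model import FCMFit, fit_fcm, loglik
from .spline_basis import SplineBasis, build_basis

logger = logging.getLogger("curveclust")

__all__ = [
    "SemiMetricSpec",
    "SelectionReport",
    "distance_Dq",
    "total_tightness",
    "fdb_index",
    "cross_validate_basis",
    "stability_runs",
    "select_h",
]


@dataclass(frozen=True)
class SemiMetricSpec:
    """Choice of derivative order for the curve semi-metric."""

    q: int = 0

    def __post_init__(self):
        if self.q not in (0, 1, 2):
            raise ValueError(f"q must be 0, 1 or 2, got {self.q}")


@dataclass
class SelectionReport:
    """Everything the model-selection phase produces: the CV log-likelihood
    profile over p, knot positions per p, per-G tightness/fDB distributions
    over repeated runs, stability matrices, and the chosen (p, G, h) with
    provenance ('user' or 'rule')."""

    cv_loglik: dict = field(default_factory=dict)      # p -> (folds,) array
    knot_report: dict = field(default_factory=dict)    # p -> interior knots
    tightness: dict = field(default_factory=dict)      # G -> (runs,) array
    fdb: dict = field(default_factory=dict)            # (G, q) -> (runs,) array
    stability: dict = field(default_factory=dict)      # G -> (n, n) matrix
    per_run: list = field(default_factory=list)        # raw per-run records
    chosen: dict = field(default_factory=dict)         # {"p":..,"G":..,"h":..,"provenance":..}


def distance_Dq(f_coeffs, g_coeffs, basis: SplineBasis, q: int = 0) -> float:
    """Semi-metric between two spline-represented curves:
    (f - g)^T M_q (f - g), the exact integral of the squared difference of
    q-th derivatives over the window."""
    f = np.asarray(f_coeffs, float).reshape(-1)
    g = np.asarray(g_coeffs, float).reshape(-1)
    if f.size != basis.p or g.size != basis.p:
        raise ValueError(
            f"coefficient vectors of length {f.size}/{g.size} do not match "
            f"the basis dimension p={basis.p}"
        )
    d = f - g
    return float(max(d @ basis.gram(q) @ d, 0.0))


def total_tightness(fit: FCMFit) -> float:
    """Sum over curves of D_0 between the estimated curve and its assigned
    cluster's mean curve."""
    M0 = fit.basis.gram(0)
    mu = fit.params.means()
    dev = fit.coef_hat - mu[fit.assignments]
    return float(np.einsum("ip,pq,iq->", dev, M0, dev))


def fdb_index(fit: FCMFit, q: int = 0) -> float:
    """Functional Davies-Bouldin index of the hard partition (lower = better
    separated relative to within-cluster dispersion)."""
    G = fit.params.G
    if G < 2:
        raise ValueError("fDB requires at least two clusters")
    sizes = fit.cluster_sizes
    if np.any(sizes == 0):
        raise DegenerateClusteringError("fDB undefined: some cluster is empty")
    Mq = fit.basis.gram(q)
    mu = fit.params.means()
    dev = fit.coef_hat - mu[fit.assignments]
    d2 = np.einsum("ip,pq,iq->i", dev, Mq, dev)
    S = np.sqrt(np.array([d2[fit.assignments == k].mean() for k in range(G)]))
    diff = mu[:, None, :] - mu[None, :, :]
    M = np.sqrt(np.maximum(np.einsum("klp,pq,klq->kl", diff, Mq, diff), 0.0))
    np.fill_diagonal(M, np.inf)
    if np.any(M == 0):
        raise DegenerateClusteringError("fDB undefined: two clusters share a mean curve")
    ratio = (S[:, None] + S[None, :]) / M
    return float(np.mean(ratio.max(axis=0)))


def cross_validate_basis(
    ds: LongitudinalDataset,
    p_grid,
    G_cv: int,
    folds: int = 10,
    seed: int = 0,
    h: int | None = None,
    n_starts: int = 2,
    max_iter: int = 200,
    tol: float = 1e-6,
):
    """Cross-validated log-likelihood profile over the basis dimension.

    Curves (never observations within a curve) are split into ``folds``
    roughly equal parts; for each candidate p the model is fitted on the
    training curves with ``G_cv`` clusters and the held-out curves'
    log-likelihood under the fitted parameters is recorded.  Knot positions
    (placed from the full dataset's pooled grid) are reported alongside.
    Candidate dimensions infeasible for the pooled grid are flagged and
    skipped rather than fatal.

    Returns (cv_loglik: p -> (folds,) array with NaN for failed folds,
    knot_report: p -> interior knot array or None).
    """
    if ds.n_curves < folds:
        raise ValueError(f"need at least {folds} curves for {folds}-fold CV")
    grid = summarize_grid(ds)
    ids = np.asarray(ds.curve_ids)
    splitter = KFold(n_splits=folds, shuffle=True, random_state=int(seed) % (2**31))
    fold_sets = list(splitter.split(ids))
    cv_loglik: dict[int, np.ndarray] = {}
    knot_report: dict[int, np.ndarray | None] = {}
    sub_seeds = (np.random.SeedSequence(seed).generate_state(len(list(p_grid)) * folds)
                 % (2**31)).astype(int)
    si = 0
    for p in p_grid:
        try:
            basis = build_basis(p, grid)
        except InfeasibleBasisError as exc:
            logger.warning("cross_validate_basis: p=%d infeasible (%s)", p, exc)
            cv_loglik[p] = np.full(folds, np.nan)
            knot_report[p] = None
            si += folds
            continue
        knot_report[p] = basis.interior_knots.copy()
        scores = np.full(folds, np.nan)
        for f, (train_idx, test_idx) in enumerate(fold_sets):
            train = ds.subset(ids[train_idx])
            test = ds.subset(ids[test_idx])
            try:
                fit = fit_fcm(train, basis, G=G_cv, h=h, n_starts=n_starts,
                              seed=int(sub_seeds[si]), max_iter=max_iter, tol=tol)
                scores[f] = loglik(fit.params, test, basis)
            except (FitFailureError, np.linalg.LinAlgError) as exc:
                logger.warning("cross_validate_basis: p=%d fold %d failed (%s)", p, f, exc)
            si += 1
        cv_loglik[p] = scores
    return cv_loglik, knot_report


def _canonical_partition(assignments: np.ndarray) -> tuple:
    """Relabel a partition by order of first appearance so that partitions
    equal up to label permutation compare equal."""
    mapping: dict[int, int] = {}
    out = []
    for a in assignments:
        if a not in mapping:
            mapping[a] = len(mapping)
        out.append(mapping[a])
    return tuple(out)


def stability_runs(
    ds: LongitudinalDataset,
    basis: SplineBasis,
    G: int,
    n_runs: int = 10,
    seed: int = 0,
    h: int | None = None,
    n_starts: int = 3,
    max_iter: int = 300,
    tol: float = 1e-6,
):
    """Repeated randomized fits at fixed G: the co-membership stability
    matrix, the modal partition, and per-run quality metrics.

    stability[i, j] is the fraction of successful runs in which curves i and
    j land in the same cluster.  The modal partition is the most frequent
    partition up to relabeling; ties go to the partition with the higher mean
    within-run log-likelihood.  Returns (stability, per_run, modal) where
    per_run is a list of records {run, seed, loglik, T, fdb_0, fdb_1, fdb_2,
    partition, fit}.
    """
    if n_runs < 2:
        raise ValueError("stability needs n_runs >= 2")
    sub_seeds = (np.random.SeedSequence(seed).generate_state(n_runs) % (2**31)).astype(int)
    n = ds.n_curves
    co = np.zeros((n, n))
    per_run = []
    failures = []
    for r, s in enumerate(sub_seeds):
        try:
            fit = fit_fcm(ds, basis, G=G, h=h, n_starts=n_starts, seed=int(s),
                          max_iter=max_iter, tol=tol)
        except FitFailureError as exc:
            failures.append(exc)
            continue
        same = fit.assignments[:, None] == fit.assignments[None, :]
        co += same
        rec = {"run": r, "seed": int(s), "loglik": fit.loglik,
               "T": total_tightness(fit), "partition": _canonical_partition(fit.assignments),
               "fit": fit}
        for q in (0, 1, 2):
            try:
                rec[f"fdb_{q}"] = fdb_index(fit, q) if G >= 2 else np.nan
            except DegenerateClusteringError:
                rec[f"fdb_{q}"] = np.nan
        per_run.append(rec)
    if not per_run:
        raise FitFailureError(
            f"all {n_runs} stability runs failed for G={G}",
            [str(e) for e in failures],
        )
    stability = co / len(per_run)
    counts: dict[tuple, list] = {}
    for rec in per_run:
        counts.setdefault(rec["partition"], []).append(rec["loglik"])
    modal = max(counts.items(), key=lambda kv: (len(kv[1]), float(np.mean(kv[1]))))[0]
    return stability, per_run, np.asarray(modal, int)


def select_h(
    ds: LongitudinalDataset,
    basis: SplineBasis,
    G: int,
    freq_threshold: float = 0.8,
    n_runs: int = 5,
    seed: int = 0,
    max_iter: int = 300,
    tol: float = 1e-6,
) -> int:
    """Automatic mean-space dimension: the largest h <= min(p, G-1) for which
    the fraction of successful single-start EM runs reaches ``freq_threshold``.

    Falls back to h = 1 with a warning when no candidate qualifies.  Each run
    uses a single initialization so that estimation failures stay visible
    rather than being masked by restarts.
    """
    if G < 2:
        raise ValueError("h selection requires G >= 2")
    if not 0.0 < freq_threshold <= 1.0:
        raise ValueError("freq_threshold must lie in (0, 1]")
    hmax = min(basis.p, G - 1)
    sub_seeds = (np.random.SeedSequence(seed).generate_state(hmax * n_runs)
                 % (2**31)).astype(int)
    si = 0
    for h in range(hmax, 0, -1):
        ok = 0
        for _ in range(n_runs):
            try:
                fit_fcm(ds, basis, G=G, h=h, n_starts=1, seed=int(sub_seeds[si]),
                        max_iter=max_iter, tol=tol)
                ok += 1
            except FitFailureError:
                pass
            si += 1
        if ok / n_runs >= freq_threshold:
            return h
    logger.warning(
        "select_h: no h in [1, %d] reached success frequency %.2f for G=%d; "
        "returning h=1", hmax, freq_threshold, G,
    )
    return 1
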