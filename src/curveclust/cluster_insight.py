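"""Post-fit analytics: discriminant projections and functions, replicate-to-
sample aggregation with a Naive-Bayes pooling rule and Shannon entropy, and
the iterative sub-clustering workflow for very large clusters.
"""

from __future__ import annotations

import logging
import string
from dataclasses import dataclass

import numpy as np

from .data_io import LongitudinalDataset
from .fclust_model import FCMFit, fit_fcm
from .model_selection import fdb_index
from .errors import FitFailureError

logger = logging.getLogger("curveclust")

__all__ = [
    "DiscriminantView",
    "SampleAssignment",
    "SubclusterResult",
    "discriminant_projection",
    "discriminant_functions",
    "discriminant_view",
    "assign_samples",
    "subcluster",
]


@dataclass(frozen=True)
class DiscriminantView:
    """Low-dimensional view of a fitted clustering: each curve as a point in
    the h-dimensional mean space, the cluster centers alpha_k, and the h
    discriminant weight functions over a dense time grid."""

    projections: np.ndarray      # (n, h)
    cluster_points: np.ndarray   # (G, h)
    functions: np.ndarray        # (h, len(grid))
    grid: np.ndarray


@dataclass(frozen=True)
class SampleAssignment:
    """Cluster call for one parent sample, pooled over its replicate curves."""

    parent_id: str
    pooled_posterior: np.ndarray  # (G,)
    label: str
    shannon: float                # entropy (nats) of member hard assignments
    n_member_curves: int


def discriminant_projection(fit: FCMFit, ds: LongitudinalDataset):
    """Project every curve into the h-dimensional mean space.

    Curve i maps to the generalized-least-squares estimate of its position
    alpha_hat_i in the space spanned by Lambda, computed from the centered
    data (Y_i - S_i lambda0) with the marginal covariance
    S_i Gamma S_i^T + sigma2 I.  Cluster k maps to alpha_k.  A curve lying
    exactly on a cluster's mean with dense sampling projects onto that
    cluster's alpha_k.
    """
    params = fit.params
    if params.h < 1:
        raise ValueError("discriminant projection requires h >= 1")
    n = len(fit.curve_ids)
    proj = np.empty((n, params.h))
    by_id = {c.curve_id: c for c in ds.curves}
    for i, cid in enumerate(fit.curve_ids):
        curve = by_id[cid]
        S = fit.basis.design(curve.times)
        Sig = S @ params.Gamma @ S.T + params.sigma2 * np.eye(curve.n_obs)
        SL = S @ params.Lambda                       # (n_i, h)
        resid = curve.values - S @ params.lambda0
        A = SL.T @ np.linalg.solve(Sig, SL)
        b = SL.T @ np.linalg.solve(Sig, resid)
        proj[i] = np.linalg.lstsq(A, b, rcond=None)[0]
    return proj, params.alpha.copy()


def discriminant_functions(fit: FCMFit, grid) -> np.ndarray:
    """The h discriminant weight functions Lambda^T S^T Sigma^-1 over a dense
    common time grid; larger |value| at a time means that time carries more
    cluster-separating information."""
    params = fit.params
    if params.h < 1:
        raise ValueError("discriminant functions require h >= 1")
    grid = np.atleast_1d(np.asarray(grid, float))
    if grid.size < params.p:
        logger.warning(
            "discriminant_functions: grid of %d point(s) is coarser than the "
            "basis dimension p=%d", grid.size, params.p,
        )
    S = fit.basis.design(grid)
    Sigma = S @ params.Gamma @ S.T + params.sigma2 * np.eye(grid.size)
    return params.Lambda.T @ np.linalg.solve(Sigma, S).T


def discriminant_view(fit: FCMFit, ds: LongitudinalDataset,
                      n_grid: int = 100) -> DiscriminantView:
    """Bundle projections, cluster points and discriminant functions on a
    default dense grid (100 equispaced points over the window)."""
    a, b = fit.basis.boundary
    grid = np.linspace(a, b, n_grid)
    proj, points = discriminant_projection(fit, ds)
    return DiscriminantView(proj, points, discriminant_functions(fit, grid), grid)


def assign_samples(fit: FCMFit, grouping: dict) -> list[SampleAssignment]:
    """Aggregate replicate curves to their parent samples.

    The pooled membership is the Naive-Bayes product of the member curves'
    posterior membership probabilities, renormalized (probabilities floored
    at 1e-12 before taking logs); the parent's label is the argmax.  The
    Shannon index (natural log) of the member curves' hard-assignment
    frequencies measures how consistently a parent's replicates cluster:
    0 for unanimous parents, up to ln G for a uniform spread.
    """
    idx = {cid: i for i, cid in enumerate(fit.curve_ids)}
    missing = [cid for cid in grouping if cid not in idx]
    if missing:
        raise ValueError(f"grouped curve id(s) not in the fit: {missing[:5]}")
    members: dict[str, list[int]] = {}
    for cid, parent in grouping.items():
        members.setdefault(str(parent), []).append(idx[cid])
    out = []
    G = fit.params.G
    for parent in sorted(members):
        rows = members[parent]
        if not rows:
            logger.warning("assign_samples: parent %r has no member curves; skipped", parent)
            continue
        logpost = np.log(np.maximum(fit.posteriors[rows], 1e-12)).sum(axis=0)
        pooled = np.exp(logpost - logpost.max())
        pooled /= pooled.sum()
        hard = fit.assignments[rows]
        freqs = np.bincount(hard, minlength=G) / len(rows)
        nz = freqs[freqs > 0]
        shannon = float(max(-(nz * np.log(nz)).sum(), 0.0))
        out.append(SampleAssignment(
            parent_id=parent,
            pooled_posterior=pooled,
            label=fit.cluster_labels[int(np.argmax(pooled))],
            shannon=shannon,
            n_member_curves=len(rows),
        ))
    return out


@dataclass(frozen=True)
class SubclusterResult:
    """Second-pass clustering of one parent cluster's member curves."""

    parent_label: str
    child_fit: FCMFit
    child_labels: list[str]      # namespaced, e.g. parent "A" -> "Aa", "Ab", ...
    member_ids: list[str]

    def assignment_labels(self) -> dict[str, str]:
        return {cid: self.child_labels[k]
                for cid, k in zip(self.member_ids, self.child_fit.assignments)}


def subcluster(
    ds: LongitudinalDataset,
    fit: FCMFit,
    target_cluster: str,
    min_size: int = 200,
    G_child: int | None = None,
    G_grid=(2, 3, 4, 5),
    n_runs: int = 3,
    n_starts: int = 3,
    seed: int = 0,
    max_iter: int = 300,
) -> SubclusterResult:
    """Re-cluster the member curves of one large cluster as an independent
    dataset, namespacing the child labels under the parent label.

    When ``G_child`` is not given, the child cluster number is chosen from
    ``G_grid`` by the lowest median fDB_0 over ``n_runs`` repeated fits
    (candidates where all runs fail are skipped).  Refuses clusters smaller
    than ``min_size``.
    """
    if target_cluster not in fit.cluster_labels:
        raise ValueError(f"unknown cluster label {target_cluster!r}")
    k = fit.cluster_labels.index(target_cluster)
    member_ids = [cid for cid, a in zip(fit.curve_ids, fit.assignments) if a == k]
    if len(member_ids) < min_size:
        raise ValueError(
            f"cluster {target_cluster!r} has {len(member_ids)} curves, below "
            f"the sub-clustering threshold min_size={min_size}"
        )
    child_ds = ds.subset(member_ids)
    sub_seeds = (np.random.SeedSequence(seed).generate_state(len(G_grid) * n_runs + 1)
                 % (2**31)).astype(int)
    if G_child is None:
        scores = {}
        si = 0
        for G in G_grid:
            vals = []
            for _ in range(n_runs):
                try:
                    f = fit_fcm(child_ds, fit.basis, G=G, n_starts=n_starts,
                                seed=int(sub_seeds[si]), max_iter=max_iter)
                    vals.append(fdb_index(f, 0))
                except FitFailureError:
                    pass
                si += 1
            if vals:
                scores[G] = float(np.median(vals))
        if not scores:
            raise FitFailureError(
                f"sub-clustering of {target_cluster!r}: every candidate G failed"
            )
        G_child = min(scores, key=lambda g: (scores[g], g))
    child_fit = fit_fcm(child_ds, fit.basis, G=G_child, n_starts=n_starts,
                        seed=int(sub_seeds[-1]), max_iter=max_iter)
    letters = string.ascii_lowercase
    child_labels = [f"{target_cluster}{letters[j]}" if j < 26 else
                    f"{target_cluster}k{j + 1}" for j in range(G_child)]
    return SubclusterResult(
        parent_label=target_cluster,
        child_fit=child_fit,
        child_labels=child_labels,
        member_ids=list(child_fit.curve_ids),
    )
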