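# Methods

## The model

`curveclust` clusters sparse, irregularly sampled longitudinal curves — the
motivating case is weekly caliper measurements of engrafted tumor volumes
over a treatment window, where each animal contributes 4–10 noisy
observations on its own time grid.  Curve *i* is modeled as a natural cubic
spline observed with noise:

    Y_i = S_i (λ0 + Λ α_{z_i} + γ_i) + ε_i,
    γ_i ~ N(0, Γ),   ε_i ~ N(0, σ² I),   z_i ~ Categorical(π)

where `S_i` is the n_i × p spline design matrix of curve *i*'s own
observation times, `z_i` is a latent cluster label, and the cluster mean
coefficient vectors are constrained to an affine subspace of dimension
h ≤ min(p, G−1): μ_k = λ0 + Λ α_k.  A single random-effect covariance Γ is
shared by all clusters and the noise is i.i.d.; with 4–10 points per curve a
richer covariance structure is not estimable.  Marginally

    Y_i | z_i = k  ~  N(S_i μ_k, S_i Γ S_i^T + σ² I),

which is what the observed-data log-likelihood, the E-step responsibilities
and the held-out likelihood all evaluate.

Mixing weights π_k are free parameters (floored at 1/(10n) and renormalized
each M-step).  The parameterization is normalized after every M-step —
Σ_k π_k α_k = 0 folded into λ0, and Λ^T M0 Λ = I_h (orthonormal columns in
the L2 Gram metric) folded into the α_k, with a deterministic sign
convention — a pure reparameterization that leaves the likelihood unchanged
and makes independent runs comparable.

## Spline basis

The basis is the p-dimensional *cardinal* natural cubic spline basis:
boundary knots at the window edges, p−2 interior knots at the j/(p−1)
empirical quantiles of the pooled **distinct** observation times (so heavily
sampled times cannot collapse several knots onto one point), and basis
function l interpolating the l-th unit vector at the knots.  Consequences
used throughout:

* a spline's coefficient vector equals its values at the knots (this is how
  simulation scenarios specify mean curves, and how closed-form test cases
  represent constants and linear functions);
* beyond the boundary knots the spline continues linearly (second
  derivative zero), taming extrapolation in prediction plots;
* derivatives up to order 2 are evaluated analytically from the
  piecewise-cubic representation, never by finite differences.

Gram matrices M_q = ∫ s^(q) s^(q)ᵀ dt over the window are computed exactly
by per-interval 4-node Gauss–Legendre quadrature (exact for the degree ≤ 6
integrands).  The curve semi-metric is then the quadratic form
D_q(f, g) = (f−g)ᵀ M_q (f−g), the exact integral of the squared difference
of q-th derivatives; q is capped at 2 because a cubic spline's third
derivative is piecewise constant and discontinuous.

## EM estimation

E-step: responsibilities from the marginal mixture, plus the conjugate
Gaussian posterior of each curve's coefficient vector given its data and
cluster (posterior covariance V_i is cluster-independent because Γ is
shared).  Computation is vectorized by grouping curves with equal n_i and
using batched linear algebra; a fit on 150 curves takes well under a second.

M-step (expectation–conditional-maximization, each step in closed form):

1. mean structure — λ0 is the weighted centroid of the per-cluster posterior
   coefficient means, and (Λ, α) the exact weighted rank-h fit of the
   centered cluster means in the Γ⁻¹ metric, obtained by SVD after
   whitening;
2. Γ and σ² from expected complete-data sufficient statistics;
3. π_k as mean responsibility, floored.

This ordering makes the observed-data log-likelihood non-decreasing up to
the π floor (monitored in tests at tolerance 1e-8).  Convergence is a
relative log-likelihood change below `tol` (default 1e-6) or `max_iter`
(default 500).

Degeneracy guards: Γ is ridge-jittered by 1e-8·tr(Γ)/p when its Cholesky
fails; a cluster whose responsibility mass drops below `min_cluster_mass`
(default 2 curves) marks the start as failed.  Failure frequency is exactly
the signal consumed by automatic h selection (`select_h` returns the largest
h whose single-start success frequency reaches the user threshold, default
0.8).

### Initialization

Per-curve coefficient estimates are the observed values linearly
interpolated at the knots — in the cardinal basis these *are* coefficient
estimates — with damped linear extrapolation beyond a curve's observed range
(edge slope taken against the nearest observation at least a quarter-window
away).  Interpolation is preferred over per-curve regression because with
n_i < p a near-unpenalized regression fit is wildly ill-determined, and
plain clamping at the edges badly biases boundary-knot values for steep
curves.  Cluster starts come from bisecting k-means on these vectors;
multi-start fits alternate the bisecting strategy (`largest_cluster`,
robust to clusters of very unequal spread, and `biggest_inertia`, which
finds variance-dominated substructure) and keep the best final
log-likelihood.  Responsibilities are initialized hard; a single integer
seed drives every random choice, and all outputs record it.

Clusters of the returned fit are relabeled by decreasing responsibility mass
(ties by first member index) and lettered A, B, C, … so that independent
runs are comparable.

## Estimated curves and prediction

A curve's estimate is the posterior mean of s(t)ᵀη_i.  For the dispersion
and validity indices below, the coefficient estimate conditions on the
assigned (MAP) cluster.  For prediction bands, when the top membership
probability is at least 0.99 the band conditions on that cluster; otherwise
mean and variance mix over memberships, so ambiguous curves get honestly
wider bands.  Bands are pointwise normal quantiles of the posterior variance
of s(t)ᵀη_i at level 1−α (default 0.05).

## Model selection

* **Basis dimension p** — 10-fold cross-validated log-likelihood: folds
  split *curves* (never observations within a curve); for each candidate p
  the model is fitted on 9 folds at a working G (`G_cv`, defaulting to the
  user's working G) and the held-out curves' log-likelihood is recorded.
  Knot positions per candidate p are reported alongside, since placement
  depends on p.  Candidates infeasible for the pooled grid (p above the
  number of distinct times) are flagged, not fatal; a fold whose fit fails
  contributes NaN and is excluded from that p's mean.
* **Cluster number G** — two complementary views over repeated randomized
  runs: *total tightness* T = Σ_i D_0(ĝ_i, ḡ_{k(i)}), summed member-wise so
  that it reaches exactly zero when every curve is its own cluster (and
  generally decreases with G; the elbow is a visual guide, deliberately not
  automated), and the *functional Davies–Bouldin index*
  fDB_q = (1/G) Σ_k max_{k'≠k} (S_k' + S_k) / M_k'k with
  S_k = sqrt(mean_{i∈k} D_q(ĝ_i, ḡ_k)) and M_k'k = sqrt(D_q(ḡ_k', ḡ_k)).
  Both S and M are taken on the root (curve-unit) scale, which makes the
  index dimensionless and reduces it exactly to the classical
  Davies–Bouldin index for constant curves — the defining sanity check.
  Runs where a fDB term is undefined (an empty cluster) contribute NaN.
* **Stability matrix** — co-membership frequency across runs; the modal
  partition is the most frequent partition up to relabeling, ties broken by
  higher mean within-run log-likelihood (deterministic and quality-aware).
* **Mean-space dimension h** — chosen automatically by `select_h` as
  described above, scanning h from min(p, G−1) downward.

## Replicate aggregation and two-stage clustering

Replicate curves sharing a parental sample are aggregated by a naive-Bayes
product of their posterior membership vectors (floored at 1e-12 before
logs, renormalized); an equal-prior correction is deliberately omitted since
per-curve posteriors already embed π once — a documented approximation.  The
Shannon index (natural log) of the member curves' hard-assignment
frequencies quantifies the consistency of each parent's replicates: 0 when
unanimous, ln G when uniformly spread.  Clusters larger than `min_size`
(default 200 curves) can be re-clustered as independent datasets; child
labels are namespaced under the parent label (A → Aa, Ab, …).

## Synthetic data

The generator samples exactly from the model.  Scenario defaults emulate a
three-week xenograft study: window [0, 21] days, knots {7, 14}, baseline
volume ≈ 100 mm³, 4–10 observations per curve at uniform (or
jittered-weekly) times, optional replicate curves per parental sample
(cluster drawn at the parent level).  Shipped scenarios:

| scenario | n | G | purpose |
|---|---|---|---|
| `well-separated-3` | 150 | 3 | recovery benchmark (pairwise mean separation ≥ 8 noise units, in fact ≫) |
| `equidistant-3` | 90 | 3 | G-selection study: means pairwise equidistant at exactly 8·sqrt(σ²·\|window\|), within-cluster coefficient sd 14 vs noise sd 5 |
| `sparse-irregular` | 200 | 3 | realistic regime, 4 replicates per parent |
| `hierarchical-6` | 120 | 6 | 3 super-groups ± a fixed sub-offset, for the two-stage workflow |
| `single-cluster` | 60 | 1 | null case |

The equidistant configuration matters: a Davies–Bouldin-type index
*correctly* prefers merging a tight pair of clusters that sit much closer to
each other than to a third, so a single stated separation is only a
meaningful G-recovery premise when it applies to every pair.

What the generator does **not** emulate: value-dependent (multiplicative)
measurement noise, missing-not-at-random dropout of large tumors, recording
errors, or treatment-schedule covariates.  Passing recovery tests therefore
demonstrate correctness of the estimation machinery under the model's own
assumptions, not robustness to these real-data features.

## Numerical choices and problem sizes

* All reported times are in input units; knots and windows are never
  rescaled behind the user's back.
* Duplicate (id, time) rows: exact duplicates collapsed, conflicting values
  averaged with a logged warning (replicate caliper measurements are common;
  silent failure would be worse).
* Curves with fewer than `min_obs` (default 2) in-window points are dropped
  and counted: one point cannot constrain even a random-effect deviation.
* Fit archives store matrices as text at 17 significant digits, which
  round-trips IEEE doubles bit-exactly.
* The test battery and the acceptance script use deliberately modest problem
  sizes chosen to exercise every behavior at desk scale: recovery at n=150,
  the cross-validation study at n=60 per replicate (10 replicates), the
  G-scan at n=90 with 20 runs per G, hierarchical two-stage at n=120.  At
  these sizes the whole battery completes in a few minutes.
* In the G-scan, a G whose every run fails (all EM starts collapse — the
  model refusing an overambitious cluster number) simply contributes no
  median; it cannot displace the minimum.

## Known limitations

* The EM M-step for the reduced-rank mean structure assumes Γ is invertible
  enough to whiten; near-singular Γ is handled by an eigenvalue floor, which
  slightly biases the mean-space fit in fully degenerate cases.
* The naive-Bayes pooling treats replicate curves as conditionally
  independent given the parent's class, which understates uncertainty for
  highly correlated replicates.
* fDB and tightness are computed from MAP-conditioned curve estimates; with
  heavily overlapping clusters a fully posterior-weighted version would
  differ.
* Cross-validation places knots from the full dataset's pooled grid (knot
  placement is treated as pre-processing); the selection of p is therefore
  marginally optimistic, identically for all candidates.
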