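# curveclust

Model-based clustering of sparse, irregularly sampled longitudinal curves.

Many longitudinal studies — the motivating case is tumor growth kinetics in
patient-derived xenografts, where each animal's volume is calipered weekly
for a few weeks — produce hundreds of short, noisy curves observed at
different times, often with several replicate curves per parental sample.
`curveclust` groups such curves into classes of shared dynamics without any
supervision, and ships the complete model-selection and post-fit toolkit
needed to use the clustering responsibly.

## The model

Each curve is a natural cubic spline observed with noise, its coefficient
vector drawn from a Gaussian mixture with reduced-rank means:

```
Y_i = S_i (λ0 + Λ α_{z_i} + γ_i) + ε_i
γ_i ~ N(0, Γ),   ε_i ~ N(0, σ²I),   z_i ~ Categorical(π),
μ_k = λ0 + Λ α_k,   h ≤ min(p, G − 1)
```

so marginally `Y_i | z_i=k ~ N(S_i μ_k, S_i Γ S_iᵀ + σ²I)`.  The model is
fitted by EM with closed-form conditional M-steps; because every curve
carries its own design matrix `S_i`, irregular and unbalanced sampling is
handled natively — no alignment, no imputation.

Around the fit:

* **basis dimension p** — 10-fold cross-validated log-likelihood (folds
  split curves) plus a knot-position report;
* **cluster number G** — total tightness `T = Σ_i D₀(ĝ_i, ḡ_{k(i)})`, the
  functional Davies–Bouldin index
  `fDB = (1/G) Σ_k max_{k'≠k} (S_k' + S_k)/M_k'k`, and co-membership
  stability matrices over repeated randomized runs, where
  `D_q(f,g) = ∫ |f⁽q⁾ − g⁽q⁾|² dt` is computed exactly from spline algebra;
* **mean-space dimension h** — chosen automatically as the largest value at
  which estimation succeeds with a user-set frequency;
* **post-fit analytics** — discriminant projections and time-resolved
  discriminant functions `ΛᵀSᵀΣ⁻¹`, per-curve estimated curves with
  pointwise confidence bands, naive-Bayes aggregation of replicate curves to
  parental samples with a Shannon consistency index, and iterative
  sub-clustering of very large classes (labels A → Aa, Ab, …).

See `docs/methods.md` for the full statistical account.

## Worked example

Simulate a realistic study (200 curves, 4–10 irregular observations each,
4 replicate curves per parental sample, three growth regimes), choose the
basis from the pooled time grid, fit, and aggregate to parents:

```python
import numpy as np
import curveclust as cc

spec = cc.get_scenario("sparse-irregular")
ds, truth = cc.simulate_dataset(spec, seed=7)
basis = cc.build_basis(4, cc.summarize_grid(ds))
fit = cc.fit_fcm(ds, basis, G=3, h=2, n_starts=3, seed=0)

print(f"log-likelihood: {fit.loglik:.1f}")
print(f"cluster sizes: {dict(zip(fit.cluster_labels, fit.cluster_sizes.tolist()))}")
print(f"total tightness T = {cc.total_tightness(fit):.3g}")
print(f"fDB_0 = {cc.fdb_index(fit, 0):.3f}")
print(f"sigma^2 = {fit.params.sigma2:.1f}")

assignments = cc.assign_samples(fit, ds.grouping)
print(f"parents: {len(assignments)}, "
      f"mean Shannon = {np.mean([s.shannon for s in assignments]):.3f}")

est = cc.predict_curve(fit, ds.curves[0], np.linspace(0, 21, 5))
print("curve", ds.curves[0].curve_id, "->", est.cluster)
for t, m, lo, hi in zip(est.eval_times, est.mean, est.lower, est.upper):
    print(f"  t={t:5.2f}  fit={m:7.1f}  95% band [{lo:7.1f}, {hi:7.1f}]")
```

Output:

```
log-likelihood: -5976.9
cluster sizes: {'A': 72, 'B': 68, 'C': 60}
total tightness T = 3.85e+05
fDB_0 = 0.135
sigma^2 = 216.6
parents: 50, mean Shannon = 0.000
curve c001 -> B
  t= 0.00  fit=  114.2  95% band [   89.0,   139.4]
  t= 5.25  fit=  132.3  95% band [  115.1,   149.6]
  t=10.50  fit=  156.7  95% band [  143.4,   170.1]
  t=15.75  fit=  189.2  95% band [  177.1,   201.4]
  t=21.00  fit=  227.2  95% band [  205.6,   248.8]
```

Reading it: the three planted growth regimes are recovered as classes A–C of
roughly the planted proportions; the noise variance estimate (216.6) is close
to the generating σ² = 225; a Shannon index of 0 means every parent's four
replicate curves were assigned unanimously; and the band around curve
`c001`'s reconstruction is tightest in the interior of its observation range,
widening toward the window edges.  With low `fDB_0`, clusters are far apart
relative to their internal spread.

## Command line

The same pipeline is scriptable from a shell; every run writes a resolved
config and a log, and a single `--seed` makes all outputs byte-reproducible:

```
curveclust simulate   --scenario sparse-irregular --seed 7 --out run/sim
curveclust preprocess --input run/sim/data.csv --out run/pre
curveclust select     --input run/sim/data.csv --p-grid 2,3,4,5,6 \
                      --g-grid 2,3,4,5 --seed 7 --out run/sel
curveclust fit        --input run/sim/data.csv --grouping run/sim/grouping.csv \
                      --p 4 --g 3 --seed 7 --out run/fit
```

`select` writes the CV profile, knot report, per-run tightness/fDB tables
(violin-plot data), stability matrices and the chosen h per G; `fit` writes
the re-importable fit archive, memberships, cluster mean curves, estimated
curves with bands, discriminant tables and sample assignments.  `report`
regenerates the exports from a saved archive; `--subcluster` triggers the
two-stage workflow on clusters above `--min-size`.

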