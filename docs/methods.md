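# Methods

This note documents the statistical procedures implemented in
`clustvalid`, the defaults they use, and the choices made where the
design was genuinely open. Nothing here reports an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Normalization and imputation

k-means and every distance-based diagnostic operate on z-scores:
each variable has its mean subtracted and is divided by its sample SD
(ddof = 1), so all variables carry equal weight in the Euclidean
metric. The means/SDs are stored, making the transform exactly
invertible.

Missing biomarker values are completed by a **single stochastic
chained-equation imputation** on the clinical scale, before
normalization (normalization statistics are then well defined on the
completed data). Missing cells are initialised by random draws from
each variable's observed values; then for 10 sweeps (default) each
incomplete variable is regressed on all the others over its observed
rows, and its missing cells are replaced by X β* + ε with
σ*² ~ σ̂²·df/χ²_df, β* ~ N(β̂, σ*²(XᵀX)⁻¹) and ε ~ N(0, σ*²). The
parameter draw plus residual noise keeps the completed variable's
dispersion realistic (the suite checks completed SD ≥ 0.8 × observed
SD) — conditional-mean imputation would shrink it toward the
regression surface. Variables are visited most-missing last. All nine
panel variables are continuous, so a normal linear conditional model is
used throughout; predictive mean matching is not implemented. Every
incomplete variable must retain ≥ 10% observed entries and at least one
variable must be fully observed.

## k-means protocol

Lloyd's algorithm with k-means++ (D²) seeding, best of `n_restarts`
(default 20) independent starts. Determinism choices: nearest-center
ties break toward the lowest center index (`argmin` semantics); an
emptied cluster is re-seeded with the point currently farthest from its
assigned center; all seeding flows through `numpy` `SeedSequence`
streams. Iteration stops when assignments stop changing, the relative
WSS drop falls below `tol` (1e-6) or `max_iter` (300) is reached; a
final polish loop runs plain Lloyd steps until label stability so that
returned fits are true fixed points — centers are exact centroids of
the labels (hence TSS = WSS + BSS to machine precision) and every point
sits with its nearest center. Clusters are relabeled canonically after
fitting: by descending size by default, or by the descending center
value of a designated variable (the pipeline uses HbA1c, which puts the
high-HbA1c subgroup first, matching the conventional ordering of the
diabetes subgroup literature).

The elbow curve reports the best-of-restarts WSS for k = 1..k_max.
Restarted k-means is not guaranteed monotone in k, so if
WSS(k) > WSS(k−1) the k run is repeated once, warm-started by splitting
the highest-WSS cluster of the k−1 solution (adding its farthest point
as a new center), and the better result kept; a numerical clamp
guarantees the non-increasing invariant.

**Covariance-matched one-cluster null.** The sample covariance of the
z-scored data (whose diagonal is exactly 1 with ddof = 1 on both sides)
parameterizes a zero-mean multivariate normal; a same-size draw from it
has the observed correlation structure but one Gaussian cluster by
construction. The null dataset is clustered with byte-identical code
and protocol (same k range, restarts, seeds policy), which is why the
k-means machinery is implemented in-package rather than delegated to a
generic library — the real/null comparison is only meaningful if the
two curves come from the same algorithm. The null size defaults to the
observed n and is exposed as a parameter (`n_null`, with WSS rescaled
by n/n_null when they differ), since the appropriate null size is a
user decision.

**Knee score.** The elbow heuristic is a visual judgment; to quantify
it, for each interior k we take the ratio (WSS drop entering k)/(WSS
drop leaving k). A geometric, self-similar decay gives equal ratios at
every k (no distinguished elbow); a genuine elbow at the true k gives a
dominant ratio there. Zero drops are stabilized with an eps of
1e-12·WSS(1) and logged. The package deliberately reports curves and
knee scores rather than declaring an "optimal k".

## Validity diagnostics

All three run on the normalized scale with Euclidean distances,
by default on a uniform random subsample (20,000 rows in the pipeline
default) because silhouette and gap are quadratic or repeated-
clustering procedures.

* **Silhouette**: a(i) = mean distance to own-cluster members,
  b(i) = smallest mean distance to another cluster,
  s(i) = (b−a)/max(a,b); singleton clusters get s(i) = 0; undefined at
  k = 1 (error). Computed blockwise without materialising the n×n
  distance matrix; block self-distances are explicitly zeroed because
  the quadratic-expansion distance formula leaves them at ~√ε. The
  implementation is checked against an all-pairs brute-force oracle to
  1e-10.
* **Gap statistic**: B (default 50) reference datasets drawn uniformly
  over each variable's observed range; gap(k) = mean log WSS_ref(k) −
  log WSS_obs(k), s_k = SD_ref(log WSS)·√(1+1/B). Both selection rules
  are reported: global max (the pipeline default) and the smallest k
  with gap(k) ≥ gap(k+1) − s_{k+1} (one-SE). A PCA-rotated-box
  reference is available (`reference="pca"`), off by default.
* **Hopkins**: m probe points (default min(n/10, 500)) drawn uniformly
  over the data's bounding box; u = probe→nearest-data distances,
  w = sampled-data→nearest-other-data distances; H = Σu/(Σu+Σw).
  Under this convention uniform data give H ≈ 0.5 and clustered data
  push H toward 1. Published analyses sometimes use the complementary
  convention (clustered ≈ 0); values from different sources should be
  compared only after fixing the convention, and this package fixes the
  one stated here. Probe draws use a keyed seed stream so they can
  never replay a user data stream seeded with the same integer.

## Survival benchmark

**Design terms.** Cluster membership enters as k−1 indicators with the
largest cluster as the reference level (stable reference hazard).
"Spline" terms are fixed-basis natural cubic splines with df columns
(default 3): boundary knots at the 5th/95th percentiles, df−1 interior
knots at evenly spaced quantiles between them; the basis is linear
beyond the boundaries and contains all linear functions. A fixed 3-df
basis inside an unpenalized Cox fit was chosen over a penalized
smoother: with the flexibility budget fixed at 3 df the two
formulations are comparably flexible, and the fixed basis is
closed-form and exactly reproducible.

**Fitting.** Newton–Raphson with step-halving on the partial
likelihood, Efron's correction for tied event times (Breslow available
by flag). Risk-set sums are cumulative sums in decreasing-time order,
fully vectorised (the tie-correction loop only touches tied groups, so
continuous follow-up costs O(np²) per iteration). Convergence: score
∞-norm < 1e-8 or relative log-likelihood change < 1e-10; a
coefficient-magnitude guard (‖β‖∞ > 50) aborts with a monotone-
likelihood/separation diagnostic; rank deficiency is detected by QR
before fitting and reported with the offending column names. The
variance matrix is the inverse observed information. Fits agree with
`lifelines` to ~1e-6 in coefficients, SEs and log-likelihood on both
continuous and heavily tied data (test suite).

**Concordance.** Comparable pairs under right censoring: the earlier
time is an event and the times differ, or the times are equal with
exactly one event (the event treated as earlier); equal-time
event/event and censored/censored pairs are not comparable. Concordant
= higher risk score on the earlier event; risk-score ties count 1/2.
Counting is a single ascending-time sweep over Fenwick trees indexed by
dense risk-score ranks (point queries for the earlier member,
range-credit trees read at snapshot time for the later member), JIT
compiled; it returns exact pair counts and the per-subject pair sums
P_i, Q_i. The standard error is the U-statistic (infinitesimal-
jackknife) estimator SE = √(Σᵢ(P_i − C·Q_i)²)/Q with a normal 95% CI;
it reproduces `survival::concordance`'s SE to six decimals on a frozen
fixture. Concordance is evaluated in-sample, matching the benchmarking
convention of the cluster-versus-features literature; users wanting
out-of-sample assessment can split before calling the benchmark.

## Synthetic cohort generator

The generator emulates what the analysis assumes about registry data:

* **Biomarkers**: Gaussian mixture, k components with per-component
  means/SDs (diagonal within-component covariance) or full
  covariances. The `t2d_registry_preset` uses four components whose
  weights are proportional to published subgroup sizes
  (12,133/27,888/41,555/32,825) and whose per-component means/SDs for
  the nine-variable panel equal published registry descriptive
  statistics; only means and SDs are published, so within-component
  covariance is diagonal by default (a full covariance can be
  supplied). Raw normal draws are kept without truncation to
  physiological ranges — truncation would distort the covariance that
  the null-elbow comparison relies on.
* **Outcomes**: Weibull baseline (shape 1.4, scale 34 years) with
  hazard h₀(t)·exp(zᵀβ), z the analytically standardized biomarkers;
  observed time = min(event, Exp(0.108) censoring, 11-year horizon).
  These defaults were calibrated once so the preset cohort shows ≈15%
  events and ≈5.2 years median follow-up, and the default coefficient
  sets (`MORTALITY_COEFFS`, age-dominated; `CVD_COEFFS`, more
  BP/lipid-weighted) put the feature-model concordances in the
  mid-to-high 0.7s with cluster models in the low-to-mid 0.6s —
  magnitudes typical of published registry benchmarks.
* **Missingness**: per-variable MAR with probability
  sigmoid(α_j + slope·z_anchor) of an always-observed anchor (age by
  default), α_j solved by root-finding so realized rates match the
  targets; slope 0 degrades to MCAR.

What the generator does **not** emulate: non-Gaussian marginals
(skewed triacylglycerol, bounded eGFR), measurement error and repeat-
visit dynamics, informative censoring, competing risks, and registry
linkage artifacts. Passing tests therefore demonstrate the methods are
implemented correctly and behave as theory predicts under the stated
generative assumptions — not that any particular real cohort does or
does not contain clusters.

## Problem sizes used by the shipped checks

The statistical acceptance tests run at: oracle equivalence on 100+100
random instances (n ≤ 300); Cox recovery on 200 replicates of
n = 5,000; null-elbow exchangeability at n = 10,000 (9 correlated
variables, 20 restarts); knee detection over 50 seeds at n = 10,000
(5 restarts); gap selection over 20 seeds at n ≈ 2,000 with B = 50;
Hopkins calibration over 50 seeds at n = 2,000; the concordance-
ordering benchmark over 50 seeds of the n = 20,000 preset (5 restarts);
imputation fidelity at n = 10,000. `scripts/acceptance.py` uses the
n = 20,000 preset with a 5,000-row validity subsample, B = 50 and 10
restarts. These sizes are the package's chosen defaults for routine
verification; all are parameters, and nothing prevents running larger.

## Known limitations

* k-means and the null comparison assume the normalized Euclidean
  metric is meaningful for every variable; no categorical variables.
* The one-cluster null is Gaussian; heavy-tailed one-cluster data can
  produce real-vs-null elbow differences without any subgroup
  structure.
* The gap reference (uniform over the per-variable range) ignores
  correlation; the PCA option mitigates but does not remove this.
* Chained-equation imputation assumes linear conditional means; a
  single completed dataset is produced (no between-imputation variance
  pooling).
* Cox models assume proportional hazards; no diagnostics, time-varying
  covariates, stratification or competing risks are provided.
* In-sample concordance mildly favors richer models (the spline model's
  edge over the linear one on linear-hazard data is optimism, bounded
  by its 3-df-per-variable budget).
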