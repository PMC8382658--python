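# clustvalid

Does a clinical biomarker cohort really contain a supportable number of
k-means clusters — and do cluster memberships predict outcomes better
than the clinical variables they were built from?

`clustvalid` is a reusable pipeline for answering both questions. It was
motivated by the debate around data-driven subgroups of type 2 diabetes
(SIDD / SIRD / MOD / MARD-style clusters built from routine biomarkers
such as age at diagnosis, BMI, HbA1c, blood pressure, lipids and eGFR):
k-means will happily carve correlated variables into clusters whether or
not any discrete structure exists, so the real questions are whether the
clusters are supported by the data, and whether they add predictive
value over the underlying continuous features. The package is aimed at
biostatisticians and epidemiologists working with registry-style cohorts
of continuous biomarkers and censored time-to-event endpoints.

## What it computes

**Cluster support.** After z-scoring each variable (mean 0, SD 1), the
within-cluster sum of squares WSS(k) = Σᵢ‖xᵢ − c(xᵢ)‖² is profiled for
k = 1..10 (best of restarted k-means++). The elbow curve is compared
against a *covariance-matched one-cluster null*: the covariance Σ̂ of the
normalized data is estimated, a same-size dataset is simulated from
N(0, Σ̂) — identical correlation structure, but a single Gaussian
cluster by construction — and the identical clustering protocol is run
on it. If the two curves look alike, the elbow carries no evidence of
discrete structure. Three further diagnostics run on a subsample:

* mean silhouette width s̄, with s(i) = (b−a)/max(a,b);
* the gap statistic gap(k) = E*[log WSSᵣₑ𝒻(k)] − log WSS(k) over B
  uniform reference datasets, with both the global-max and one-SE
  selection rules;
* the Hopkins statistic H = Σu/(Σu+Σw) (≈0.5 for spatial randomness,
  →1 for clustered data).

**Predictive value.** Cox proportional-hazards models
h(t|x) = h₀(t)·exp(η(x)) are fitted to each censored endpoint with
three kinds of linear predictor: cluster membership as a categorical
term (k−1 indicators, k = 2..7), all biomarkers as linear main effects,
and all biomarkers expanded in 3-df natural cubic spline bases. Models
are ranked by Harrell's concordance C — the proportion of
censoring-comparable pairs in which the higher modelled risk has the
earlier event — with an asymptotic (U-statistic) standard error and
95% CI. Fitting is Newton–Raphson on the Efron-corrected partial
likelihood; concordance pair counting is an O(n log n) Fenwick-tree
sweep that exactly reproduces the O(n²) definition.

**Synthetic cohorts.** A generator produces registry-like test beds:
Gaussian-mixture biomarker panels (including a four-subgroup type 2
diabetes preset parameterized from published registry descriptive
statistics), Weibull event times with log-linear proportional hazards in
the standardized biomarkers, independent censoring calibrated to ≈85%
censoring and ≈5.2 years median follow-up, and missing-at-random
masking driven by an always-observed anchor variable.

## Worked example

```python
from clustvalid import AnalysisConfig, run_full

cfg = AnalysisConfig(
    synthetic={"preset": "t2d_registry", "n_individuals": 8000},
    k_max_elbow=8, benchmark_k=[2, 3, 4], subsample_size=4000,
    gap_B=20, n_restarts=10, gap_restarts=5,
    seed=7, out_dir="out",
)
bundle = run_full(cfg)
print(bundle.concordance[["model", "endpoint", "concordance",
                          "ci_lo", "ci_hi"]].round(3).to_string(index=False))
```

prints

```
     model endpoint  concordance  ci_lo  ci_hi
 2 cluster    event        0.608  0.595  0.621
 3 cluster    event        0.607  0.592  0.622
 4 cluster    event        0.639  0.626  0.653
    PH Cox    event        0.792  0.779  0.805
Spline Cox    event        0.793  0.780  0.806
```

and the accompanying validity report shows silhouette widths of
0.11–0.15 across k, a gap one-SE choice of k = 1, and near-identical
real and null elbow knee scores (2.23 vs 2.11). Read together: even on
a cohort with four *planted* overlapping subgroups, the cluster
diagnostics give at best weak support for any particular k, and Cox
models using the nine continuous variables directly (C ≈ 0.79) clearly
out-predict every cluster-membership model (C ≈ 0.61–0.64) — coarsening
continuous risk factors into clusters discards information. The spline
model matches the linear one here because the generating hazard is
itself log-linear.

The same stages are available as a CLI
(`clustvalid simulate|impute|cluster|validity|survive|report|run`).

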