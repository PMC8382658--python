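"""Cluster-validity and clustering-tendency diagnostics.

Three diagnostics complementing the WSS elbow:

* silhouette width — how well each individual sits inside its assigned
  cluster relative to the nearest other cluster, in [-1, 1];
* gap statistic — log within-cluster dispersion of the observed data
  compared against B datasets drawn uniformly over the observed
  per-variable range (a no-structure reference);
* Hopkins statistic — nearest-neighbour comparison of the data against
  uniform probe points; about 0.5 for spatial randomness, near 1 for
  strongly clustered data under the convention used here.

Silhouette and gap need all pairwise distances (or repeated
clustering), so for large cohorts they are run on a uniform subsample
(:func:`subsample`); distances are Euclidean on the normalized scale
throughout, consistent with the k-means protocol.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .clustering import _spawn_seeds, _values, kmeans_fit
from .preprocess import NormalizedMatrix

__all__ = [
    "SilhouetteReport",
    "GapReport",
    "TendencyReport",
    "subsample",
    "silhouette_mean",
    "gap_statistic",
    "hopkins",
]


@dataclass
class SilhouetteReport:
    per_point_width: np.ndarray
    mean_width: float
    k: int
    n: int


@dataclass
class GapReport:
    """Gap curve with its bootstrap reference summary.

    ``gap[k] = mean_ref log(WSS_ref(k)) - log(WSS_obs(k))``; ``s_k`` is
    the reference spread inflated by sqrt(1 + 1/B).  ``selected_k_max``
    maximises the gap; ``selected_k_1se`` is the smallest k with
    ``gap(k) >= gap(k+1) - s_{k+1}``.
    """

    k_values: np.ndarray
    log_wss_obs: np.ndarray
    log_wss_ref_mean: np.ndarray
    gap: np.ndarray
    s_k: np.ndarray
    B: int
    selected_k_max: int
    selected_k_1se: int
    seed: int


@dataclass
class TendencyReport:
    hopkins_h: float
    m_probes: int
    bounds_lo: np.ndarray
    bounds_hi: np.ndarray
    seed: int


def subsample(normalized, n_sub: int = 20_000, seed: int = 0) -> NormalizedMatrix:
    """Uniform row sample without replacement (reproducible given seed)."""
    if isinstance(normalized, NormalizedMatrix):
        vals, means, sds, names = (
            normalized.values,
            normalized.means,
            normalized.sds,
            normalized.variable_names,
        )
    else:
        vals = np.asarray(normalized, dtype=float)
        means = np.zeros(vals.shape[1])
        sds = np.ones(vals.shape[1])
        names = [f"x{j}" for j in range(vals.shape[1])]
    n = vals.shape[0]
    if n_sub > n:
        raise ValueError(f"n_sub={n_sub} exceeds n={n}")
    rng = np.random.default_rng(seed)
    rows = rng.choice(n, size=int(n_sub), replace=False)
    return NormalizedMatrix(vals[rows].copy(), np.asarray(means), np.asarray(sds), list(names))


def silhouette_mean(normalized, labels, block_size: int = 2048) -> SilhouetteReport:
    """Mean silhouette width of a clustering.

    For each point, a(i) is the mean distance to the other members of
    its own cluster and b(i) the minimum over other clusters of the
    mean distance to that cluster; s(i) = (b - a) / max(a, b).  Points
    in singleton clusters get s(i) = 0.  Computed blockwise so the full
    n x n distance matrix is never materialised.
    """
    X = _values(normalized)
    lab = np.asarray(labels)
    n = X.shape[0]
    if lab.shape != (n,):
        raise ValueError("labels length must equal the number of rows")
    uniq, lab_idx = np.unique(lab, return_inverse=True)
    k = len(uniq)
    if k < 2:
        raise ValueError("silhouette is undefined for a single cluster")
    counts = np.bincount(lab_idx, minlength=k)
    onehot = np.zeros((n, k))
    onehot[np.arange(n), lab_idx] = 1.0
    sq = (X**2).sum(axis=1)
    s = np.empty(n)
    for start in range(0, n, block_size):
        stop = min(start + block_size, n)
        d2 = sq[start:stop, None] - 2.0 * (X[start:stop] @ X.T) + sq[None, :]
        np.maximum(d2, 0.0, out=d2)
        d = np.sqrt(d2)
        # the expansion leaves self-distances at ~sqrt(eps); zero them
        d[np.arange(stop - start), np.arange(start, stop)] = 0.0
        cluster_sums = d @ onehot                      # (block, k)
        own = lab_idx[start:stop]
        rows = np.arange(stop - start)
        own_count = counts[own]
        with np.errstate(invalid="ignore"):
            a = cluster_sums[rows, own] / np.maximum(own_count - 1, 1)
        mean_other = cluster_sums / counts[None, :]
        mean_other[rows, own] = np.inf
        b = mean_other.min(axis=1)
        sb = (b - a) / np.maximum(a, b)
        sb[own_count == 1] = 0.0
        s[start:stop] = sb
    return SilhouetteReport(per_point_width=s, mean_width=float(s.mean()), k=k, n=n)


def gap_statistic(
    normalized,
    k_max: int = 10,
    B: int = 50,
    seed: int = 0,
    n_restarts: int = 10,
    reference: str = "range",
) -> GapReport:
    """Gap statistic with a uniform bootstrap reference.

    For each k = 1..k_max the observed data and each of B reference
    datasets — drawn uniformly over the per-variable observed range
    (``reference='range'``), or over the range in the PCA-rotated frame
    (``reference='pca'``) — are clustered with the identical k-means
    protocol.  Large gaps mean the observed within-cluster dispersion
    is far below what featureless uniform data produce.
    """
    X = _values(normalized)
    n, p = X.shape
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    if B < 2:
        raise ValueError("B must be >= 2")
    if reference not in ("range", "pca"):
        raise ValueError("reference must be 'range' or 'pca'")
    if reference == "pca":
        center = X.mean(axis=0)
        _, _, vt = np.linalg.svd(X - center, full_matrices=False)
        frame = (X - center) @ vt.T
    else:
        center, vt, frame = None, None, X
    lo, hi = frame.min(axis=0), frame.max(axis=0)
    if (hi <= lo).any():
        j = int(np.flatnonzero(hi <= lo)[0])
        raise ValueError(f"degenerate (constant) range in column {j}; cannot draw a uniform reference")

    seeds = _spawn_seeds(seed, (B + 1) * k_max + B)
    log_obs = np.empty(k_max)
    for i, k in enumerate(range(1, k_max + 1)):
        log_obs[i] = np.log(kmeans_fit(X, k, n_restarts=n_restarts, seed=seeds[i]).wss)
    log_ref = np.empty((B, k_max))
    for b in range(B):
        rng = np.random.default_rng(seeds[k_max + b])
        ref = rng.uniform(lo, hi, size=(n, p))
        if reference == "pca":
            ref = ref @ vt + center
        base = k_max + B + b * k_max
        for i, k in enumerate(range(1, k_max + 1)):
            log_ref[b, i] = np.log(
                kmeans_fit(ref, k, n_restarts=n_restarts, seed=seeds[base + i]).wss
            )
    ref_mean = log_ref.mean(axis=0)
    gap = ref_mean - log_obs
    s_k = log_ref.std(axis=0, ddof=0) * np.sqrt(1.0 + 1.0 / B)
    selected_max = int(np.argmax(gap)) + 1
    selected_1se = k_max
    for i in range(k_max - 1):
        if gap[i] >= gap[i + 1] - s_k[i + 1]:
            selected_1se = i + 1
            break
    return GapReport(
        k_values=np.arange(1, k_max + 1),
        log_wss_obs=log_obs,
        log_wss_ref_mean=ref_mean,
        gap=gap,
        s_k=s_k,
        B=B,
        selected_k_max=selected_max,
        selected_k_1se=selected_1se,
        seed=seed,
    )


def hopkins(normalized, m_probes: int | None = None, seed: int = 0) -> TendencyReport:
    """Hopkins clustering-tendency statistic.

    Draws m uniform probe points over the data's bounding box and
    compares their nearest-data-point distances (u) with the
    nearest-other-point distances (w) of m sampled data points:
    H = sum(u) / (sum(u) + sum(w)).  Uniform data give H near 0.5;
    clustered data push w far below u, so H approaches 1.
    """
    X = _values(normalized)
    n, p = X.shape
    if m_probes is None:
        m_probes = max(1, min(n // 10, 500))
    m = int(m_probes)
    if m >= n:
        raise ValueError(f"m_probes={m} must be smaller than n={n}")
    # keyed seed so probe draws never replay a user stream seeded alike
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x4B1D]))
    lo, hi = X.min(axis=0), X.max(axis=0)
    tree = cKDTree(X)
    probes = rng.uniform(lo, hi, size=(m, p))
    u, _ = tree.query(probes, k=1)
    rows = rng.choice(n, size=m, replace=False)
    w, _ = tree.query(X[rows], k=2)
    w = w[:, 1]  # nearest *other* point
    h = float(u.sum() / (u.sum() + w.sum()))
    return TendencyReport(hopkins_h=h, m_probes=m, bounds_lo=lo, bounds_hi=hi, seed=seed)
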