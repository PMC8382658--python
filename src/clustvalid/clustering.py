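"""k-means clustering and elbow diagnostics.

Implements Lloyd's algorithm with k-means++ seeding and a deterministic
protocol (best of ``n_restarts`` independent starts, nearest-center
ties broken toward the lowest center index, emptied clusters re-seeded
with the farthest point), the within-cluster sum-of-squares (WSS) elbow
curve for k = 1..k_max, and the covariance-matched one-cluster null
reference elbow: the covariance of the normalized data is estimated, a
same-size single-Gaussian dataset with that covariance is simulated,
and the identical clustering protocol is run on it.  If the two curves
look alike, the data offer no evidence of discrete cluster structure.

The protocol is deliberately self-contained (rather than delegating to
a generic clustering library) so that the observed and null curves are
produced by byte-identical code paths, which is what the comparison
relies on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .preprocess import NormalizedMatrix
from .synthetic_data import estimate_covariance, simulate_null

__all__ = ["KMeansFit", "ElbowCurve", "KneeScore", "kmeans_fit", "elbow_curve",
           "null_reference_elbow", "knee_score"]

logger = logging.getLogger(__name__)


@dataclass
class KMeansFit:
    """One k-means solution on the normalized scale.

    ``labels`` are 1-based cluster indices; clusters are relabeled after
    fitting (by descending size by default, or by descending value of a
    designated center coordinate) so that label 1 is well defined.
    """

    k: int
    centers: np.ndarray
    labels: np.ndarray
    wss: float
    per_cluster_wss: np.ndarray
    n_iter: int
    converged: bool
    restarts_used: int
    seed: int

    @property
    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels - 1, minlength=self.k)


@dataclass
class ElbowCurve:
    """WSS-versus-k profile, optionally with a matched-null profile."""

    k_values: np.ndarray
    wss_per_k: np.ndarray
    null_wss_per_k: np.ndarray | None
    n: int
    p: int
    seed: int


@dataclass
class KneeScore:
    """Sharpness of the elbow at each interior k.

    ``ratios[k]`` is (WSS drop entering k) / (WSS drop leaving k); a
    curve with a genuine elbow at k shows a dominant ratio there, while
    a structureless, smoothly decaying curve has no distinguished k.
    """

    k_values: np.ndarray        # interior k: 2 .. k_max-1
    ratios: np.ndarray
    best_k: int
    score: float


def _values(normalized) -> np.ndarray:
    if isinstance(normalized, NormalizedMatrix):
        return np.asarray(normalized.values, dtype=float)
    return np.asarray(normalized, dtype=float)


def _plus_plus_init(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++ seeding (D^2 sampling)."""
    n = X.shape[0]
    centers = np.empty((k, X.shape[1]))
    centers[0] = X[rng.integers(n)]
    d2 = ((X - centers[0]) ** 2).sum(axis=1)
    for c in range(1, k):
        total = d2.sum()
        if total <= 0:
            centers[c:] = X[rng.integers(n, size=k - c)]
            break
        centers[c] = X[rng.choice(n, p=d2 / total)]
        d2 = np.minimum(d2, ((X - centers[c]) ** 2).sum(axis=1))
    return centers


def _assign(X: np.ndarray, centers: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Nearest-center assignment; ties go to the lowest center index."""
    # ||x-c||^2 = ||x||^2 - 2 x.c + ||c||^2 ; ||x||^2 constant in argmin
    d2 = (centers**2).sum(axis=1)[None, :] - 2.0 * (X @ centers.T)
    lab = np.argmin(d2, axis=1)  # argmin returns the first (lowest) index on ties
    return lab, d2


def _lloyd(
    X: np.ndarray,
    centers: np.ndarray,
    max_iter: int,
    tol: float,
) -> tuple[np.ndarray, np.ndarray, float, int, bool]:
    n, p = X.shape
    k = centers.shape[0]
    labels = np.full(n, -1)
    prev_wss = np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        new_labels, _ = _assign(X, centers)
        # recompute centroids
        counts = np.bincount(new_labels, minlength=k)
        if (counts == 0).any():
            # re-seed each emptied cluster with the point farthest from
            # its currently assigned center
            d2full = ((X - centers[new_labels]) ** 2).sum(axis=1)
            for c in np.flatnonzero(counts == 0):
                far = int(np.argmax(d2full))
                centers[c] = X[far]
                new_labels[far] = c
                d2full[far] = 0.0
            counts = np.bincount(new_labels, minlength=k)
        sums = np.zeros((k, p))
        np.add.at(sums, new_labels, X)
        centers = sums / counts[:, None]
        wss = float(((X - centers[new_labels]) ** 2).sum())
        if np.array_equal(new_labels, labels):
            labels = new_labels
            converged = True
            break
        labels = new_labels
        if prev_wss - wss <= tol * max(prev_wss, 1e-300):
            converged = True
            break
        prev_wss = wss
    # polish to a label-stable fixed point so that both invariants hold
    # at return: centers are the exact centroids of the labels (TSS =
    # WSS + BSS) and every point sits with its nearest center
    for _ in range(100):
        new_labels, _ = _assign(X, centers)
        if np.array_equal(new_labels, labels):
            break
        counts = np.bincount(new_labels, minlength=k)
        if (counts == 0).any():
            break  # keep the consistent pre-polish solution
        sums = np.zeros((k, p))
        np.add.at(sums, new_labels, X)
        centers = sums / counts[:, None]
        labels = new_labels
    wss = float(((X - centers[labels]) ** 2).sum())
    return labels, centers, wss, it, converged


def kmeans_fit(
    normalized,
    k: int,
    n_restarts: int = 20,
    max_iter: int = 300,
    tol: float = 1e-6,
    seed: int = 0,
    relabel_by: int | None = None,
    _warm_centers: np.ndarray | None = None,
) -> KMeansFit:
    """Best-of-restarts k-means with k-means++ seeding.

    Parameters
    ----------
    normalized
        z-scored matrix (``NormalizedMatrix`` or plain array).
    k
        Number of clusters, 1 <= k <= n.
    n_restarts
        Independent k-means++ starts; the lowest-WSS solution is kept.
    relabel_by
        Column index: relabel clusters by descending center value of
        that column (e.g. the HbA1c column to put the high-HbA1c
        cluster first).  ``None`` relabels by descending cluster size.
    """
    X = _values(normalized)
    if np.isnan(X).any():
        raise ValueError("missing values present; impute before clustering")
    n = X.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of rows n={n}")
    rng = np.random.default_rng(seed)
    best = None
    starts = [_plus_plus_init(X, k, rng) for _ in range(max(1, n_restarts))]
    if _warm_centers is not None:
        starts.append(np.asarray(_warm_centers, dtype=float))
    for init in starts:
        labels, centers, wss, it, conv = _lloyd(X, init.copy(), max_iter, tol)
        if best is None or wss < best[2] - 1e-12:
            best = (labels, centers, wss, it, conv)
    labels, centers, wss, it, conv = best

    # canonical relabeling
    if relabel_by is None:
        order = np.argsort(-np.bincount(labels, minlength=k), kind="stable")
    else:
        order = np.argsort(-centers[:, relabel_by], kind="stable")
    remap = np.empty(k, dtype=int)
    remap[order] = np.arange(k)
    labels = remap[labels] + 1
    centers = centers[order]
    per_cluster = np.array(
        [((X[labels == c + 1] - centers[c]) ** 2).sum() for c in range(k)]
    )
    return KMeansFit(
        k=k,
        centers=centers,
        labels=labels,
        wss=wss,
        per_cluster_wss=per_cluster,
        n_iter=it,
        converged=conv,
        restarts_used=len(starts),
        seed=seed,
    )


def _split_warm_start(X: np.ndarray, fit: KMeansFit) -> np.ndarray:
    """Warm-start centers for k+1: split the highest-WSS cluster."""
    worst = int(np.argmax(fit.per_cluster_wss)) + 1
    rows = fit.labels == worst
    d2 = ((X[rows] - fit.centers[worst - 1]) ** 2).sum(axis=1)
    far = X[rows][int(np.argmax(d2))]
    return np.vstack([fit.centers, far])


def elbow_curve(
    normalized,
    k_max: int = 10,
    n_restarts: int = 20,
    max_iter: int = 300,
    tol: float = 1e-6,
    seed: int = 0,
) -> ElbowCurve:
    """Best-of-restarts WSS profile for k = 1..k_max.

    Restarted k-means is not guaranteed monotone in k, so whenever
    WSS(k) exceeds WSS(k-1) the k run is repeated warm-started by
    splitting the highest-WSS cluster of the k-1 solution, and the
    better result is kept; the returned curve is non-increasing.
    """
    X = _values(normalized)
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    seeds = _spawn_seeds(seed, k_max)
    wss = np.empty(k_max)
    prev_fit = None
    for i, k in enumerate(range(1, k_max + 1)):
        fit = kmeans_fit(X, k, n_restarts, max_iter, tol, seed=seeds[i])
        if prev_fit is not None and fit.wss > prev_fit.wss:
            warm = _split_warm_start(X, prev_fit)
            refit = kmeans_fit(
                X, k, n_restarts=0, max_iter=max_iter, tol=tol,
                seed=seeds[i], _warm_centers=warm,
            )
            if refit.wss < fit.wss:
                fit = refit
            if fit.wss > prev_fit.wss:  # numerically safeguard the invariant
                logger.info("clamping WSS(k=%d) to WSS(k=%d)", k, k - 1)
                fit.wss = prev_fit.wss
        wss[i] = fit.wss
        prev_fit = fit
    return ElbowCurve(
        k_values=np.arange(1, k_max + 1),
        wss_per_k=wss,
        null_wss_per_k=None,
        n=X.shape[0],
        p=X.shape[1],
        seed=seed,
    )


def null_reference_elbow(
    normalized,
    k_max: int = 10,
    n_restarts: int = 20,
    seed: int = 0,
    n_null: int | None = None,
) -> ElbowCurve:
    """Elbow curve of the data plus its covariance-matched null.

    Estimates the covariance of the normalized data, simulates a
    same-size (or ``n_null``-row) one-cluster multivariate normal
    dataset with that covariance, and runs the identical elbow protocol
    on both.  Returns the observed curve with ``null_wss_per_k`` filled;
    when ``n_null`` differs from n, the null WSS is rescaled by
    ``n / n_null`` so the two curves stay comparable.
    """
    if isinstance(normalized, NormalizedMatrix):
        nm = normalized
    else:
        X = np.asarray(normalized, dtype=float)
        nm = NormalizedMatrix(X, np.zeros(X.shape[1]), np.ones(X.shape[1]))
    real = elbow_curve(nm, k_max=k_max, n_restarts=n_restarts, seed=seed)
    cov = estimate_covariance(nm)
    n = nm.values.shape[0]
    n_null = n if n_null is None else int(n_null)
    null_data = simulate_null(cov, n_null, seed=_spawn_seeds(seed, k_max + 1)[-1])
    null = elbow_curve(null_data, k_max=k_max, n_restarts=n_restarts, seed=seed)
    real.null_wss_per_k = null.wss_per_k * (n / n_null)
    return real


def knee_score(curve: ElbowCurve, use_null: bool = False) -> KneeScore:
    """Ratio-of-successive-drops elbow sharpness.

    For each interior k the score is the WSS drop entering k divided by
    the drop leaving k; an exactly geometric decay gives equal ratios at
    every k (no distinguished elbow), while a sharp elbow at the true
    cluster count gives a dominant ratio there.
    """
    wss = curve.null_wss_per_k if use_null else curve.wss_per_k
    if wss is None:
        raise ValueError("curve has no null profile")
    k_max = len(wss)
    if k_max < 3:
        raise ValueError("knee score needs k_max >= 3")
    drops = -np.diff(wss)  # drops[i] = wss[k=i+1] - wss[k=i+2] drop leaving
    eps = 1e-12 * max(float(wss[0]), 1.0)
    if (drops <= 0).any():
        logger.info("zero WSS drop encountered; ratios stabilized with eps=%g", eps)
    ratios = (drops[:-1] + eps) / (drops[1:] + eps)
    ks = np.arange(2, k_max)
    best = int(np.argmax(ratios))
    return KneeScore(k_values=ks, ratios=ratios, best_k=int(ks[best]),
                     score=float(ratios[best]))


def _spawn_seeds(seed: int, count: int) -> list[int]:
    ss = np.random.SeedSequence(int(seed))
    return [int(s) for s in ss.generate_state(count) >> 1]
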