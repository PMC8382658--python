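"""Feature normalization and chained-equation imputation.

k-means operates on Euclidean distance, so variables measured on
different clinical scales (mmHg, mmol/mol, kg/m^2 ...) must be brought
to a common scale first.  :func:`normalize` z-scores each column
(subtract the column mean, divide by the column SD) so every variable
has mean zero and SD one, and keeps the original means/SDs so the
transform can be inverted exactly.

Missing biomarker values are completed by :func:`impute_chained`, a
single stochastic imputation drawn from a chained-equation (MICE-style)
sweep: each incomplete variable is regressed on all the others over its
observed rows and its missing cells are replaced by the linear
prediction plus a residual draw, cycling until the fill-in stabilises.
A stochastic draw (rather than the conditional mean) is used so the
completed variable keeps realistic dispersion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["NormalizedMatrix", "normalize", "impute_chained"]


@dataclass
class NormalizedMatrix:
    """A z-scored feature matrix together with the scale it came from.

    ``values`` holds the z-scores; ``means``/``sds`` are the per-variable
    location and scale (clinical units) removed by the transform, so
    ``values * sds + means`` recovers the original matrix exactly.
    """

    values: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    variable_names: list[str] = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    def inverse(self) -> np.ndarray:
        """Map the z-scores back to the original clinical scale."""
        return self.values * self.sds + self.means

    def to_frame(self) -> pd.DataFrame:
        names = self.variable_names or [f"x{j}" for j in range(self.p)]
        return pd.DataFrame(self.values, columns=names)


def _as_array(features) -> tuple[np.ndarray, list[str]]:
    if isinstance(features, pd.DataFrame):
        return features.to_numpy(dtype=float), [str(c) for c in features.columns]
    if isinstance(features, NormalizedMatrix):
        return np.asarray(features.values, dtype=float), list(features.variable_names)
    arr = np.asarray(features, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    return arr, []


def normalize(features, variable_names: list[str] | None = None) -> NormalizedMatrix:
    """Column-wise z-scoring with the sample SD (ddof=1).

    Parameters
    ----------
    features
        n x p matrix (array or DataFrame) with no missing entries.
    variable_names
        Optional column names; taken from the DataFrame if given one.

    Raises
    ------
    ValueError
        If any entry is missing (impute first) or a column is constant.
    """
    arr, inferred = _as_array(features)
    names = list(variable_names) if variable_names is not None else inferred
    if not names:
        names = [f"x{j}" for j in range(arr.shape[1])]
    if np.isnan(arr).any():
        raise ValueError(
            "features contain missing values; run impute_chained before normalize"
        )
    means = arr.mean(axis=0)
    sds = arr.std(axis=0, ddof=1)
    bad = np.flatnonzero(~(sds > 0))
    if bad.size:
        raise ValueError(
            "constant column(s) cannot be normalized: "
            + ", ".join(names[j] for j in bad)
        )
    return NormalizedMatrix((arr - means) / sds, means, sds, names)


def _split_input(features, mask):
    """Return (array, mask, names, was_frame) from the accepted input forms."""
    if isinstance(features, pd.DataFrame):
        arr = features.to_numpy(dtype=float)
        names = [str(c) for c in features.columns]
        frame = True
    else:
        arr = np.array(features, dtype=float)
        names = [f"x{j}" for j in range(arr.shape[1])]
        frame = False
    if mask is None:
        m = np.isnan(arr)
    else:
        m = np.asarray(mask, dtype=bool)
        if m.shape != arr.shape:
            raise ValueError("missing mask shape does not match features")
        m = m | np.isnan(arr)
    return arr, m, names, frame


def impute_chained(
    features,
    mask: np.ndarray | None = None,
    n_cycles: int = 10,
    seed: int = 0,
    min_observed_frac: float = 0.1,
):
    """Single stochastic imputation by chained equations.

    Missing cells are initialised by random draws from each variable's
    observed values.  Then for ``n_cycles`` sweeps each incomplete
    variable is regressed (ordinary least squares with an intercept) on
    all other variables over its observed rows; its missing cells are
    replaced by a stochastic draw: coefficients are perturbed by their
    sampling distribution (sigma^2 drawn from the scaled inverse
    chi-square, beta from its normal approximation) and independent
    residual noise is added.  Variables are visited most-missing last.
    Observed cells are never altered.

    Parameters
    ----------
    features
        n x p matrix or DataFrame; missing entries as NaN.
    mask
        Optional explicit boolean missing mask (True = missing), OR-ed
        with the NaN pattern.
    n_cycles
        Number of full sweeps over the incomplete variables.
    seed
        Seed for every stochastic draw; same seed, same completion.
    min_observed_frac
        Reject variables with fewer observed entries than this fraction.

    Returns
    -------
    Completed matrix of the same type as the input (DataFrame in,
    DataFrame out).
    """
    arr, miss, names, frame = _split_input(features, mask)
    n, p = arr.shape
    if not np.issubdtype(arr.dtype, np.floating):
        raise TypeError("non-numeric input cannot be imputed")
    rng = np.random.default_rng(seed)

    n_miss = miss.sum(axis=0)
    for j in range(p):
        if n_miss[j] == n:
            raise ValueError(f"variable {names[j]!r} is 100% missing; cannot impute")
        if n - n_miss[j] < max(2, min_observed_frac * n) and n_miss[j] > 0:
            raise ValueError(
                f"variable {names[j]!r} has fewer than "
                f"{min_observed_frac:.0%} observed entries"
            )
    if not (n_miss == 0).any():
        raise ValueError("at least one fully observed variable is required")
    if not miss.any():
        return pd.DataFrame(arr, columns=names) if frame else arr

    filled = arr.copy()
    incomplete = np.flatnonzero(n_miss > 0)
    # initial fill: random draws from the observed distribution
    for j in incomplete:
        obs = arr[~miss[:, j], j]
        filled[miss[:, j], j] = rng.choice(obs, size=n_miss[j], replace=True)

    order = incomplete[np.argsort(n_miss[incomplete], kind="stable")]  # most-missing last
    for _ in range(n_cycles):
        for j in order:
            rows_obs = ~miss[:, j]
            others = np.delete(np.arange(p), j)
            X_obs = np.column_stack([np.ones(rows_obs.sum()), filled[rows_obs][:, others]])
            y_obs = arr[rows_obs, j]
            beta, _, _, _ = np.linalg.lstsq(X_obs, y_obs, rcond=None)
            resid = y_obs - X_obs @ beta
            df = max(rows_obs.sum() - X_obs.shape[1], 1)
            sigma2 = float(resid @ resid) / df
            # stochastic ("Bayesian-flavored") parameter draw
            sigma2_star = sigma2 * df / rng.chisquare(df)
            XtX = X_obs.T @ X_obs
            try:
                cov_beta = sigma2_star * np.linalg.pinv(XtX)
                beta_star = rng.multivariate_normal(beta, cov_beta, method="eigh")
            except np.linalg.LinAlgError:  # pragma: no cover - degenerate design
                beta_star = beta
            rows_mis = miss[:, j]
            X_mis = np.column_stack([np.ones(rows_mis.sum()), filled[rows_mis][:, others]])
            filled[rows_mis, j] = X_mis @ beta_star + rng.normal(
                0.0, np.sqrt(sigma2_star), size=rows_mis.sum()
            )
    return pd.DataFrame(filled, columns=names) if frame else filled
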