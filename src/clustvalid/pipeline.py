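"""End-to-end orchestration: impute -> normalize -> elbow + matched-null
elbow -> subsampled validity diagnostics -> cluster/linear/spline Cox
benchmark, with every artifact written to disk and reproducible from
(config, master seed).

Stage seeds are derived from the master seed by a fixed keyed scheme
(one ``SeedSequence([master, stage_id])`` per stage), so any stage can
be re-run in isolation with identical results.
"""

from __future__ import annotations

import hashlib
import json
import time as _time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clustering, validity
from .preprocess import impute_chained, normalize
from .survival import ModelSpec, SurvivalDataset, benchmark_models
from .synthetic_data import (
    DEFAULT_VARIABLES,
    CohortSpec,
    SyntheticCohort,
    simulate_cohort,
    t2d_registry_preset,
)

__all__ = [
    "AnalysisConfig",
    "ReportBundle",
    "run_full",
    "descriptive_table",
    "read_cohort",
    "write_cohort",
    "write_bundle",
    "stage_seed",
]

_STAGE_IDS = {
    "simulate": 1,
    "impute": 2,
    "elbow": 3,
    "subsample": 4,
    "gap": 5,
    "hopkins": 6,
    "kmeans": 7,
}


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed."""
    ss = np.random.SeedSequence([int(master_seed), _STAGE_IDS[stage]])
    return int(ss.generate_state(1)[0] >> 1)


@dataclass
class AnalysisConfig:
    """Everything needed to reproduce one full analysis run."""

    input_csv: str | None = None
    synthetic: dict | None = None          # preset name / CohortSpec fields
    variables: list[str] | None = None
    endpoints: list[tuple[str, str, str]] = field(
        default_factory=lambda: [("event", "time", "event")]
    )  # (name, time column, event column)
    k_max_elbow: int = 10
    benchmark_k: list[int] = field(default_factory=lambda: list(range(2, 8)))
    subsample_size: int = 20_000
    gap_B: int = 50
    n_restarts: int = 20
    gap_restarts: int = 10
    impute_cycles: int = 10
    spline_df: int = 3
    relabel_variable: str = "hba1c"        # puts the high-HbA1c cluster first
    seed: int = 0
    out_dir: str = "clustvalid_out"
    make_plots: bool = False

    def __post_init__(self) -> None:
        if not (1 <= self.k_max_elbow <= 10):
            raise ValueError("k_max_elbow must lie in [1, 10]")
        if any(k < 2 or k > 10 for k in self.benchmark_k):
            raise ValueError("benchmark cluster counts must lie in [2, 10]")
        self.endpoints = [tuple(e) for e in self.endpoints]
        if self.input_csv is None and self.synthetic is None:
            raise ValueError("either input_csv or a synthetic spec is required")

    @staticmethod
    def from_yaml(path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return AnalysisConfig(**data)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class ReportBundle:
    descriptives: pd.DataFrame
    elbow: pd.DataFrame
    knee: dict
    validity: dict
    concordance: pd.DataFrame
    cluster_labels: dict[int, np.ndarray]
    run_log: list[dict]
    master_seed: int
    config_hash: str


def _spec_from_config(cfg: AnalysisConfig) -> CohortSpec:
    syn = dict(cfg.synthetic or {})
    preset = syn.pop("preset", None)
    if preset in ("t2d_registry", "t2d", "registry"):
        allowed = {"n_individuals", "hazard_coefficients", "missing_rates", "seed"}
        unknown = set(syn) - allowed
        if unknown:
            raise ValueError(f"unknown preset option(s): {sorted(unknown)}")
        return t2d_registry_preset(**syn)
    if preset is not None:
        raise ValueError(f"unknown preset {preset!r}")
    return CohortSpec(**syn)


# ------------------------------------------------------------------
# cohort CSV round trip
# ------------------------------------------------------------------

def write_cohort(cohort: SyntheticCohort, path: str | Path) -> Path:
    """Write a cohort as CSV: one row per individual, empty cell = missing."""
    path = Path(path)
    df = pd.DataFrame(cohort.features_with_missing(), columns=cohort.variable_names)
    df["time"] = cohort.time
    df["event"] = cohort.event
    df["true_label"] = cohort.true_labels
    df.to_csv(path, index=False, float_format="%.10g")
    return path


def read_cohort(
    path: str | Path,
    variables: list[str] | None = None,
    endpoints: list[tuple[str, str, str]] | None = None,
):
    """Read a cohort CSV; returns ``(features, endpoint frame, true labels)``.

    ``features`` is a DataFrame with NaN at missing cells; the endpoint
    frame holds the referenced time/event columns after validation
    (positive times, 0/1 indicators — violations are reported with
    their 1-based data row number).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except ValueError as exc:
        raise ValueError(f"{path}: could not parse CSV: {exc}") from exc
    endpoints = endpoints or [("event", "time", "event")]
    special = {c for _, tc, ec in endpoints for c in (tc, ec)} | {"true_label"}
    if variables is None:
        variables = [c for c in df.columns if c not in special]
    missing_cols = [v for v in variables if v not in df.columns]
    if missing_cols:
        raise ValueError(f"{path}: unknown feature column(s): {missing_cols}")
    feats = df[variables].apply(pd.to_numeric, errors="coerce")
    bad = feats.isna() & df[variables].notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"{path}: non-numeric value in column {variables[c]!r}, data row {r + 1}"
        )
    ep_cols = {}
    for _, tcol, ecol in endpoints:
        for col in (tcol, ecol):
            if col not in df.columns:
                raise ValueError(f"{path}: endpoint column {col!r} not found")
        t = pd.to_numeric(df[tcol], errors="raise").to_numpy(dtype=float)
        nonpos = np.flatnonzero(~(t > 0))
        if nonpos.size:
            raise ValueError(
                f"{path}: non-positive time in column {tcol!r}, data row {nonpos[0] + 1}"
            )
        e = pd.to_numeric(df[ecol], errors="raise").to_numpy()
        if not np.isin(e, (0, 1)).all():
            row = int(np.flatnonzero(~np.isin(e, (0, 1)))[0])
            raise ValueError(
                f"{path}: event indicator not 0/1 in column {ecol!r}, data row {row + 1}"
            )
        ep_cols[tcol] = t
        ep_cols[ecol] = e.astype(int)
    labels = df["true_label"].to_numpy(dtype=int) if "true_label" in df.columns else None
    return feats, pd.DataFrame(ep_cols), labels


def descriptive_table(features, labels, variable_names: list[str] | None = None) -> pd.DataFrame:
    """Per-cluster and total mean/SD/size table.

    Tidy layout: one row per (group, variable) with the group sizes and
    proportions repeated per row; ``group`` is ``"total"`` or the
    1-based cluster label.  Every individual is counted in exactly one
    cluster.
    """
    if isinstance(features, pd.DataFrame):
        names = list(features.columns)
        arr = features.to_numpy(dtype=float)
    else:
        arr = np.asarray(features, dtype=float)
        names = variable_names or [f"x{j}" for j in range(arr.shape[1])]
    lab = np.asarray(labels)
    if lab.shape[0] != arr.shape[0]:
        raise ValueError("labels must be defined for every row")
    n = arr.shape[0]
    groups = [("total", np.ones(n, dtype=bool))] + [
        (str(g), lab == g) for g in np.unique(lab)
    ]
    assert sum(m.sum() for _, m in groups[1:]) == n  # partition
    rows = []
    for gname, mask in groups:
        sub = arr[mask]
        for j, v in enumerate(names):
            rows.append(
                {
                    "group": gname,
                    "variable": v,
                    "mean": float(np.nanmean(sub[:, j])),
                    "sd": float(np.nanstd(sub[:, j], ddof=1)),
                    "n": int(mask.sum()),
                    "proportion": float(mask.sum() / n),
                }
            )
    return pd.DataFrame(rows)


# ------------------------------------------------------------------
# full pipeline
# ------------------------------------------------------------------

def run_full(cfg: AnalysisConfig, write: bool = True) -> ReportBundle:
    """Execute the complete analysis described by ``cfg``.

    Stages: load/simulate -> impute -> normalize -> elbow + matched
    one-cluster null elbow -> subsample -> silhouette / gap / Hopkins ->
    k-means fits for the benchmark k values -> cluster, main-effects
    and spline Cox per endpoint -> concordance table.  Any stage error
    is re-raised annotated with the stage name.
    """
    log: list[dict] = []
    seed = int(cfg.seed)

    def _run(stage, fn):
        t0 = _time.perf_counter()
        try:
            out = fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
        log.append({"stage": stage, "seconds": round(_time.perf_counter() - t0, 3),
                    "seed": stage_seed(seed, stage) if stage in _STAGE_IDS else None})
        return out

    # --- load or simulate -----------------------------------------
    def _load():
        if cfg.input_csv is not None:
            return read_cohort(cfg.input_csv, cfg.variables, cfg.endpoints)
        spec = _spec_from_config(cfg)
        cohort = simulate_cohort(spec, seed=stage_seed(seed, "simulate"))
        feats = pd.DataFrame(cohort.features_with_missing(), columns=cohort.variable_names)
        eps = {}
        for _, tcol, ecol in cfg.endpoints:
            eps[tcol] = cohort.time
            eps[ecol] = cohort.event
        return feats, pd.DataFrame(eps), cohort.true_labels

    feats, endpoint_frame, _true = _run("load", _load)
    variables = list(feats.columns)

    # --- impute + normalize ---------------------------------------
    completed = _run(
        "impute",
        lambda: impute_chained(feats, n_cycles=cfg.impute_cycles,
                               seed=stage_seed(seed, "impute"))
        if feats.isna().to_numpy().any() else feats,
    )
    norm = _run("normalize", lambda: normalize(completed))

    # --- elbow + covariance-matched null --------------------------
    curve = _run(
        "elbow",
        lambda: clustering.null_reference_elbow(
            norm, k_max=cfg.k_max_elbow, n_restarts=cfg.n_restarts,
            seed=stage_seed(seed, "elbow"),
        ),
    )
    knee: dict = {}
    if cfg.k_max_elbow >= 3:
        ks_real = clustering.knee_score(curve)
        ks_null = clustering.knee_score(curve, use_null=True)
        knee = {
            "real": {"best_k": ks_real.best_k, "score": ks_real.score},
            "null": {"best_k": ks_null.best_k, "score": ks_null.score},
        }

    # --- subsampled validity diagnostics --------------------------
    n_sub = min(cfg.subsample_size, norm.n)
    sub = _run("subsample",
               lambda: validity.subsample(norm, n_sub, seed=stage_seed(seed, "subsample")))
    relabel = variables.index(cfg.relabel_variable) if cfg.relabel_variable in variables else None

    def _silhouettes():
        out = {}
        for k in range(2, cfg.k_max_elbow + 1):
            fit = clustering.kmeans_fit(
                sub, k, n_restarts=cfg.n_restarts,
                seed=stage_seed(seed, "kmeans") + k, relabel_by=relabel,
            )
            out[k] = validity.silhouette_mean(sub, fit.labels).mean_width
        return out

    sil = _run("silhouette", _silhouettes) if cfg.k_max_elbow >= 2 else {}
    gap = _run(
        "gap",
        lambda: validity.gap_statistic(
            sub, k_max=cfg.k_max_elbow, B=cfg.gap_B,
            seed=stage_seed(seed, "gap"), n_restarts=cfg.gap_restarts,
        ),
    )
    hop = _run("hopkins",
               lambda: validity.hopkins(sub, seed=stage_seed(seed, "hopkins")))
    validity_report = {
        "silhouette_mean_by_k": {int(k): float(v) for k, v in sil.items()},
        "gap": {
            "k": curveify(gap.k_values),
            "gap": curveify(gap.gap),
            "s_k": curveify(gap.s_k),
            "B": gap.B,
            "selected_k_max": gap.selected_k_max,
            "selected_k_1se": gap.selected_k_1se,
        },
        "hopkins": {"h": hop.hopkins_h, "m_probes": hop.m_probes},
        "n_subsample": n_sub,
    }

    # --- benchmark cluster fits + Cox models ----------------------
    def _fits():
        out = {}
        for k in cfg.benchmark_k:
            fit = clustering.kmeans_fit(
                norm, k, n_restarts=cfg.n_restarts,
                seed=stage_seed(seed, "kmeans") + 1000 + k, relabel_by=relabel,
            )
            out[k] = fit.labels
        return out

    labels_by_k = _run("cluster_fits", _fits)

    def _benchmark():
        datasets = {}
        for name, tcol, ecol in cfg.endpoints:
            datasets[name] = SurvivalDataset(
                endpoint_frame[tcol].to_numpy(),
                endpoint_frame[ecol].to_numpy(),
                completed,
            )
        specs = [
            ModelSpec.all_linear(variables, name="PH Cox"),
            ModelSpec.all_spline(variables, df=cfg.spline_df, name="Spline Cox"),
        ]
        return benchmark_models(datasets, labels_by_k, specs)

    concordance = _run("benchmark", _benchmark)

    # --- descriptives (four-cluster fit if available) -------------
    desc_k = 4 if 4 in labels_by_k else (cfg.benchmark_k[0] if labels_by_k else None)
    if desc_k is not None:
        desc = descriptive_table(completed, labels_by_k[desc_k])
    else:
        desc = descriptive_table(completed, np.ones(len(completed), dtype=int))

    elbow_df = pd.DataFrame(
        {"k": curve.k_values, "wss": curve.wss_per_k, "null_wss": curve.null_wss_per_k}
    )
    bundle = ReportBundle(
        descriptives=desc,
        elbow=elbow_df,
        knee=knee,
        validity=validity_report,
        concordance=concordance,
        cluster_labels=labels_by_k,
        run_log=log,
        master_seed=seed,
        config_hash=cfg.config_hash(),
    )
    if write:
        write_bundle(bundle, cfg.out_dir, make_plots=cfg.make_plots)
    return bundle


def curveify(arr) -> list[float]:
    return [float(v) for v in np.asarray(arr).ravel()]


def write_bundle(bundle: ReportBundle, out_dir: str | Path, make_plots: bool = False) -> Path:
    """Serialize a ReportBundle: CSVs are the canonical outputs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = {"master_seed": bundle.master_seed, "config_hash": bundle.config_hash}
    bundle.descriptives.to_csv(out / "descriptives.csv", index=False, float_format="%.6g")
    bundle.elbow.to_csv(out / "elbow.csv", index=False, float_format="%.10g")
    bundle.concordance.to_csv(out / "concordance.csv", index=False, float_format="%.6g")
    labels_df = pd.DataFrame({f"cluster_k{k}": v for k, v in bundle.cluster_labels.items()})
    labels_df.to_csv(out / "cluster_labels.csv", index=False)
    with open(out / "validity.json", "w") as fh:
        json.dump({**stamp, "knee": bundle.knee, **bundle.validity}, fh, indent=2)
    with open(out / "run_log.jsonl", "w") as fh:
        for rec in [stamp] + bundle.run_log:
            fh.write(json.dumps(rec) + "\n")
    if make_plots:
        _render_plots(bundle, out)
    return out


def _render_plots(bundle: ReportBundle, out: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(bundle.elbow["k"], bundle.elbow["wss"], "o-", label="observed")
    if bundle.elbow["null_wss"].notna().any():
        ax.plot(bundle.elbow["k"], bundle.elbow["null_wss"], "s--",
                label="one-cluster null")
    ax.set_xlabel("k"), ax.set_ylabel("within-cluster SS"), ax.legend()
    fig.tight_layout(), fig.savefig(out / "elbow.png", dpi=120), plt.close(fig)

    sil = bundle.validity.get("silhouette_mean_by_k", {})
    if sil:
        fig, ax = plt.subplots(figsize=(5, 4))
        ax.plot(list(sil.keys()), list(sil.values()), "o-")
        ax.set_xlabel("k"), ax.set_ylabel("mean silhouette width")
        fig.tight_layout(), fig.savefig(out / "silhouette.png", dpi=120), plt.close(fig)

    gap = bundle.validity.get("gap", {})
    if gap:
        fig, ax = plt.subplots(figsize=(5, 4))
        ax.errorbar(gap["k"], gap["gap"], yerr=gap["s_k"], fmt="o-")
        ax.set_xlabel("k"), ax.set_ylabel("gap statistic")
        fig.tight_layout(), fig.savefig(out / "gap.png", dpi=120), plt.close(fig)
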