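"""Monte Carlo study orchestration.

Runs the full design — generate benchmark instances per condition, run each
detection method, score MP / ARI / modularity ratio — and provides the
downstream analyses: across-run stability of the non-deterministic methods,
condition regressions with dummy-coded predictors, the ARI–MR coherence
(Pearson correlation between the adjusted Rand index and the modularity
ratio), and tidy summary tables with pairwise Cohen's d contrasts.

Every record carries full provenance (condition, replicate, matrix type,
method, run index, derived seed); re-running with the same master seed
reproduces the records exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from ._exceptions import CommbenchError, UndefinedMetricError
from ._seeds import STREAM_DETECT, derive_seed
from .conditions import ConditionRegistry, load_registry
from .detect import METHOD_NAMES, METHODS, run_method
from .metrics import ari_ha, majority_placement, weighted_modularity
from .types import BenchmarkInstance, MatrixType, SimilarityMatrix

__all__ = [
    "StudyConfig",
    "RegressionSummary",
    "PRESETS",
    "run_study",
    "evaluate_instance",
    "stability_analysis",
    "fit_condition_regression",
    "mr_coherence",
    "summarize",
]

_MATRIX_CODE = {MatrixType.COUNT: 0, MatrixType.CORRELATION: 1, MatrixType.REFLECTED_EUCD: 2}

RECORD_COLUMNS = [
    "family",
    "condition_id",
    "matrix_type",
    "method",
    "replicate",
    "run_index",
    "seed",
    "mp",
    "ari",
    "q_recovered",
    "q_true",
    "mr",
    "n_communities_found",
    "n_communities_true",
    "error",
]


@dataclass(frozen=True)
class StudyConfig:
    """Which slice of the study to run, at what replication, from which seed."""

    corr_ids: tuple[int, ...] = ()
    lfr_ids: tuple[int, ...] = ()
    reps_per_condition: int = 100
    runs_per_dataset: int = 1
    methods: tuple[str, ...] = METHOD_NAMES
    master_seed: int = 0
    matrix_types: tuple[str, ...] = ("correlation", "reflected_eucd", "count")

    def __post_init__(self) -> None:
        if self.reps_per_condition < 1 or self.runs_per_dataset < 1:
            raise ValueError("replication counts must be >= 1")
        unknown = set(self.methods) - set(METHOD_NAMES)
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")


#: ``paper``: the published scale (100 replicates per condition).
#: ``desk``: the same pipeline at 3 replicates for desk-scale reruns.
PRESETS: dict[str, dict] = {
    "paper": {"reps_per_condition": 100},
    "desk": {"reps_per_condition": 3},
}


def _clipped(matrix: SimilarityMatrix) -> np.ndarray:
    return np.clip(matrix.values, 0.0, None)


def evaluate_instance(
    instance: BenchmarkInstance,
    methods: Sequence[str] = METHOD_NAMES,
    runs_per_dataset: int = 1,
    master_seed: int = 0,
    family: str = "corr",
) -> list[dict]:
    """Score each method on one instance; returns tidy record dicts.

    Modularity (and hence MR) is always computed on the clipped nonnegative
    matrix so the ratio is comparable across methods; MR is missing (NaN)
    when the planted partition's modularity is zero.  Per-run failures are
    recorded with an error message, never dropped.
    """
    w = _clipped(instance.matrix)
    try:
        q_true = weighted_modularity(w, instance.truth)
    except UndefinedMetricError:
        q_true = np.nan
    rows = []
    mcode = _MATRIX_CODE[instance.matrix_type]
    for m_idx, name in enumerate(methods):
        for run in range(runs_per_dataset):
            seed = derive_seed(
                master_seed,
                STREAM_DETECT,
                mcode,
                instance.condition_id,
                instance.replicate,
                m_idx,
                run,
            )
            row = {
                "family": family,
                "condition_id": instance.condition_id,
                "matrix_type": instance.matrix_type.value,
                "method": name,
                "replicate": instance.replicate,
                "run_index": run,
                "seed": seed,
                "mp": np.nan,
                "ari": np.nan,
                "q_recovered": np.nan,
                "q_true": q_true,
                "mr": np.nan,
                "n_communities_found": -1,
                "n_communities_true": instance.truth.n_communities,
                "error": "",
            }
            try:
                res = run_method(name, instance.matrix, seed=seed, run_index=run)
                row["mp"] = majority_placement(instance.truth, res.partition)
                row["ari"] = ari_ha(instance.truth, res.partition)
                row["q_recovered"] = weighted_modularity(w, res.partition)
                row["n_communities_found"] = res.n_communities
                if q_true == q_true and q_true != 0.0:
                    row["mr"] = row["q_recovered"] / q_true
            except Exception as err:  # logged and recorded, never dropped
                row["error"] = f"{type(err).__name__}: {err}"
            rows.append(row)
    return rows


def run_study(
    config: StudyConfig,
    registry: Optional[ConditionRegistry] = None,
    out_csv: Optional[str] = None,
    progress: bool = False,
) -> pd.DataFrame:
    """Run the Monte Carlo sweep described by ``config``.

    For each selected correlation condition x replicate, the correlation and
    reflected-EucD instances share one time-series realization; count
    conditions yield one instance each.  Every (instance, method, run) cell
    becomes one record.
    """
    from .synth_corr import generate_corr_instance
    from .synth_lfr import generate_lfr_instance

    registry = registry or load_registry()
    rows: list[dict] = []

    def eval_rows(instance, family):
        return evaluate_instance(
            instance,
            methods=config.methods,
            runs_per_dataset=config.runs_per_dataset,
            master_seed=config.master_seed,
            family=family,
        )

    for cid in config.corr_ids:
        cond = registry.corr_by_id(cid)
        for rep in range(config.reps_per_condition):
            corr_inst, eucd_inst = generate_corr_instance(
                cond, rep, config.master_seed
            )
            if "correlation" in config.matrix_types:
                rows.extend(eval_rows(corr_inst, "corr"))
            if "reflected_eucd" in config.matrix_types:
                rows.extend(eval_rows(eucd_inst, "corr"))
            if progress:
                print(f"corr condition {cid} replicate {rep} done", flush=True)
    if "count" in config.matrix_types:
        for cid in config.lfr_ids:
            cond = registry.lfr_by_id(cid)
            for rep in range(config.reps_per_condition):
                inst = generate_lfr_instance(cond, rep, config.master_seed)
                rows.extend(eval_rows(inst, "lfr"))
                if progress:
                    print(f"lfr condition {cid} replicate {rep} done", flush=True)

    records = pd.DataFrame(rows, columns=RECORD_COLUMNS)
    if out_csv is not None:
        records.to_csv(out_csv, index=False)
    return records


def stability_analysis(records: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Across-run SD of ARI per (method, condition, matrix type, replicate).

    Requires multi-run records (runs_per_dataset > 1).  Also returns, per
    method, the Pearson correlation across conditions between the mean ARI
    and the mean across-run SD — does instability signal inaccuracy?
    """
    if records["run_index"].max() < 1:
        raise ValueError("stability analysis needs runs_per_dataset > 1 records")
    keys = ["method", "matrix_type", "condition_id", "replicate"]
    per_dataset = (
        records.groupby(keys)["ari"].agg(ari_mean="mean", ari_sd="std").reset_index()
    )
    per_condition = (
        per_dataset.groupby(["method", "matrix_type", "condition_id"])
        .agg(ari_mean=("ari_mean", "mean"), ari_sd=("ari_sd", "mean"))
        .reset_index()
    )
    corrs = {}
    for method, grp in per_condition.groupby("method"):
        if grp["ari_sd"].std() == 0 or grp["ari_mean"].std() == 0 or len(grp) < 3:
            corrs[method] = np.nan
        else:
            corrs[method] = float(np.corrcoef(grp["ari_mean"], grp["ari_sd"])[0, 1])
    return per_dataset, pd.Series(corrs, name="mean_sd_correlation")


@dataclass
class RegressionSummary:
    """Standardized betas of ARI on dummy-coded condition indicators."""

    method: str
    matrix_type: str
    betas: dict[str, float]
    reference_category: str
    n_records: int
    dropped: tuple[str, ...] = field(default_factory=tuple)


def _corr_condition_features(registry: ConditionRegistry) -> pd.DataFrame:
    from .synth_corr import assign_community_sizes

    rows = []
    for c in registry.corr:
        share = min(
            s / c.n_nodes
            for s in assign_community_sizes(c.n_nodes, c.n_communities, c.size_scheme)
        )
        rows.append(
            {
                "condition_id": c.id,
                "n_nodes": c.n_nodes,
                "weight_range": f"{c.loading_range[0]}-{c.loading_range[1]}",
                "overlap": c.overlap,
                "unequal": c.size_scheme.value != "equal",
                "level_diff": c.level_diff,
                "comm_share": "ge25" if share >= 0.25 else ("10to25" if share >= 0.1 else "lt10"),
            }
        )
    return pd.DataFrame(rows)


def _lfr_condition_features(registry: ConditionRegistry) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "condition_id": [c.id for c in registry.lfr],
            "n_nodes": [c.n_nodes for c in registry.lfr],
            "avg_degree": [c.avg_degree for c in registry.lfr],
            "prop_out": [c.prop_out for c in registry.lfr],
            "size_hetero": [c.size_hetero for c in registry.lfr],
        }
    )
    # in-degree level is relative to the graph size (low/med/high rank)
    df["degree_level"] = (
        df.groupby("n_nodes")["avg_degree"].rank(method="dense").astype(int)
    )
    return df


_REFERENCES = {
    "corr": "N=25, equal sizes, low overlap, community share >= 25%, "
    "loadings 0.25-0.95, no level difference",
    "lfr": "N=25, low in-degree, low proportion out, low size heterogeneity",
}


def fit_condition_regression(
    records: pd.DataFrame,
    method: str,
    matrix_type: str,
    registry: Optional[ConditionRegistry] = None,
) -> RegressionSummary:
    """OLS of ARI on dummy-coded condition indicators, both sides z-scored.

    Reference categories are the smallest graph size and the "typical"
    setting of each factor; constant or collinear dummies are dropped with a
    warning.
    """
    registry = registry or load_registry()
    sub = records[
        (records["method"] == method) & (records["matrix_type"] == matrix_type)
    ].dropna(subset=["ari"])
    if sub["condition_id"].nunique() < 2:
        raise ValueError("need records from at least two distinct conditions")

    family = "lfr" if matrix_type == "count" else "corr"
    if family == "corr":
        feats = _corr_condition_features(registry)
        dummies = pd.get_dummies(
            feats.set_index("condition_id").astype(
                {"n_nodes": "str", "overlap": "str", "level_diff": "str"}
            ),
            columns=["n_nodes", "weight_range", "overlap", "comm_share", "level_diff"],
            dtype=float,
        )
        # reference levels excluded from the predictor set
        refs = [
            "n_nodes_25",
            "weight_range_0.25-0.95",
            "overlap_0.1",
            "comm_share_ge25",
            "level_diff_0",
        ]
        dummies = dummies.drop(columns=refs, errors="ignore")
        dummies["unequal"] = dummies["unequal"].astype(float)
    else:
        feats = _lfr_condition_features(registry)
        dummies = pd.get_dummies(
            feats.set_index("condition_id").astype({"n_nodes": "str"}),
            columns=["n_nodes", "degree_level"],
            dtype=float,
        )
        dummies["high_prop_out"] = (feats.set_index("condition_id")["prop_out"] > 0.2).astype(float)
        dummies["high_size_hetero"] = (
            feats.set_index("condition_id")["size_hetero"] == 2
        ).astype(float)
        dummies = dummies.drop(
            columns=["n_nodes_25", "degree_level_1", "avg_degree", "prop_out", "size_hetero"],
            errors="ignore",
        )

    design = sub.join(dummies, on="condition_id")
    y = design["ari"].to_numpy(float)
    x = design[dummies.columns].to_numpy(float)

    keep, dropped = [], []
    for j, col in enumerate(dummies.columns):
        if np.std(x[:, j]) == 0:
            dropped.append(col)
        else:
            keep.append(j)
    if dropped:
        warnings.warn(
            f"dropping constant predictors: {dropped}", stacklevel=2
        )
    x = x[:, keep]
    cols = [dummies.columns[j] for j in keep]
    if np.all(y == y[0]):
        betas = {c: 0.0 for c in cols}
    else:
        yz = (y - y.mean()) / y.std()
        xz = (x - x.mean(axis=0)) / x.std(axis=0)
        fit = sm.OLS(yz, xz).fit()
        betas = dict(zip(cols, (float(b) for b in fit.params)))
    return RegressionSummary(
        method=method,
        matrix_type=matrix_type,
        betas=betas,
        reference_category=_REFERENCES[family],
        n_records=len(sub),
        dropped=tuple(dropped),
    )


def mr_coherence(
    records: pd.DataFrame,
    method: Optional[str] = None,
    matrix_type: Optional[str] = None,
) -> float:
    """Pearson correlation between per-record ARI and modularity ratio.

    Records with missing MR (zero planted modularity) are excluded pairwise.
    """
    sub = records
    if method is not None:
        sub = sub[sub["method"] == method]
    if matrix_type is not None:
        sub = sub[sub["matrix_type"] == matrix_type]
    sub = sub.dropna(subset=["ari", "mr"])
    if len(sub) < 3:
        raise ValueError("need at least 3 records with non-missing MR")
    if sub["ari"].std() == 0 or sub["mr"].std() == 0:
        raise UndefinedMetricError("zero variance in ARI or MR")
    return float(np.corrcoef(sub["ari"], sub["mr"])[0, 1])


def summarize(records: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-(condition, matrix type, method) means/SDs and pairwise Cohen's d.

    The effect-size table contrasts each method pair within (condition,
    matrix type) on ARI, using the pooled-SD Cohen's d.
    """
    if records.empty:
        raise ValueError("no records to summarize")
    keys = ["family", "matrix_type", "condition_id", "method"]
    summary = (
        records.groupby(keys)
        .agg(
            n=("ari", "size"),
            mp_mean=("mp", "mean"),
            mp_sd=("mp", "std"),
            ari_mean=("ari", "mean"),
            ari_sd=("ari", "std"),
            mr_mean=("mr", "mean"),
            mr_sd=("mr", "std"),
        )
        .reset_index()
    )
    drows = []
    for (fam, mt, cid), grp in records.groupby(
        ["family", "matrix_type", "condition_id"]
    ):
        methods = sorted(grp["method"].unique())
        for i, mi in enumerate(methods):
            for mj in methods[i + 1 :]:
                xi = grp.loc[grp["method"] == mi, "ari"].dropna()
                xj = grp.loc[grp["method"] == mj, "ari"].dropna()
                if len(xi) < 2 or len(xj) < 2:
                    d = np.nan
                else:
                    from .metrics import cohens_d

                    try:
                        d = cohens_d(xi, xj)
                    except UndefinedMetricError:
                        d = 0.0 if xi.mean() == xj.mean() else np.nan
                drows.append(
                    {
                        "family": fam,
                        "matrix_type": mt,
                        "condition_id": cid,
                        "method_i": mi,
                        "method_j": mj,
                        "cohens_d": d,
                    }
                )
    return summary, pd.DataFrame(drows)
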