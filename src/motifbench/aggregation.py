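"""Hierarchical geometric-mean rank aggregation and metric harmonization.

Raw benchmark metrics are not comparable across benchmarks, datasets and
platforms.  Two complementary devices make them comparable:

* **Hierarchical rank aggregation** — within each test dataset, motifs are
  ranked per metric; ranks are combined by geometric mean followed by
  re-ranking, climbing the hierarchy metric -> variant -> benchmark ->
  replicate (dataset) -> experiment type -> global.  The winner is the
  motif with the best aggregated rank.
* **Harmonization** — per (TF, dataset, benchmark, metric) scope, metric
  values are min-max rescaled to [0, 1]; the mean of scaled values over a
  platform's metrics and datasets is the motif's overall performance there.

Ties get fractional (average) ranks; the final ordering breaks remaining
ties by motif_id for reproducibility.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .benchmarks import validate_benchmark_table

__all__ = [
    "DEFAULT_HIERARCHY",
    "rank_level",
    "aggregate_ranks",
    "harmonize",
    "overall_performance",
    "select_best",
]

logger = logging.getLogger(__name__)

#: Aggregation levels from leaf to root: at each step, ranks of the listed
#: column's children are combined by geometric mean and re-ranked within
#: the remaining grouping keys.
DEFAULT_HIERARCHY = ["metric_name", "variant", "benchmark_id", "dataset_id",
                     "experiment_type"]


def rank_level(values_by_motif: dict, higher_is_better: bool = True) -> dict:
    """Fractional (average-tie) ranks with rank 1 = best."""
    if not values_by_motif:
        raise ValueError("need at least one motif")
    motifs = list(values_by_motif)
    values = np.array([values_by_motif[m] for m in motifs], dtype=float)
    ranks = rankdata(-values if higher_is_better else values)
    return dict(zip(motifs, ranks.tolist()))


def _gmean_and_rerank(df: pd.DataFrame, group_cols: list[str]) -> pd.DataFrame:
    """Geometric mean of ranks over children, then re-rank within groups."""
    keys = group_cols + ["motif_id"]
    gm = (
        df.assign(log_rank=np.log(df["rank"]))
        .groupby(keys, sort=True)["log_rank"]
        .mean()
        .pipe(np.exp)
        .rename("gmean_rank")
        .reset_index()
    )
    if group_cols:
        gm["rank"] = gm.groupby(group_cols, sort=False)["gmean_rank"].transform(
            lambda s: rankdata(s)
        )
    else:
        gm["rank"] = rankdata(gm["gmean_rank"])
    return gm.drop(columns="gmean_rank")


def aggregate_ranks(
    table: pd.DataFrame, hierarchy: list[str] | None = None
) -> dict[str, pd.DataFrame]:
    """Hierarchical geometric-mean rank aggregation of a benchmark table.

    Returns ``{"per_type": ..., "global": ...}`` orderings (per TF).  Motifs
    missing any leaf covered by the table within a TF are excluded from
    that TF's aggregation with a logged reason.
    """
    table = validate_benchmark_table(table)
    hierarchy = list(hierarchy or DEFAULT_HIERARCHY)
    per_type_frames = []
    global_frames = []
    for tf, sub in table.groupby("tf", sort=True):
        leaf_cols = ["tf"] + hierarchy[::-1]  # broad -> narrow grouping keys
        # leaf ranking: within every full leaf scope, rank motifs by value
        leaves = sub.copy()
        scope = [c for c in leaf_cols if c != "metric_name"] + ["metric_name"]
        scope = [c for c in scope if c in leaves.columns]
        leaf_scope = [c for c in scope if c != "motif_id"]
        n_leaves = leaves.groupby(leaf_scope, sort=False).ngroups
        counts = leaves.groupby("motif_id", sort=False).size()
        complete = counts[counts == n_leaves].index
        incomplete = sorted(set(counts.index) - set(complete))
        if incomplete:
            logger.info(
                "tf=%s: excluding motifs missing leaves: %s", tf, incomplete
            )
            leaves = leaves[leaves["motif_id"].isin(complete)]
        if leaves.empty:
            continue
        leaves = leaves.copy()
        leaves["rank"] = leaves.groupby(leaf_scope, sort=False)["value"].transform(
            lambda s: rankdata(-s)
        )
        df = leaves[leaf_scope + ["motif_id", "rank"]]
        # climb the hierarchy: drop one level at a time, gmean + re-rank
        remaining = list(leaf_scope)
        per_type = None
        for level in hierarchy:
            if level not in remaining:
                continue
            remaining.remove(level)
            df = _gmean_and_rerank(df, remaining)
            if level == "dataset_id":  # per-experiment-type ordering ready
                per_type = df.copy()
        if per_type is None:
            per_type = df.copy()
        per_type_frames.append(per_type)
        global_frames.append(df)
    if not global_frames:
        raise ValueError("no motif covers a complete set of leaves")
    per_type = pd.concat(per_type_frames, ignore_index=True)
    global_df = pd.concat(global_frames, ignore_index=True)
    # deterministic final ordering: rank, then motif_id
    per_type = per_type.sort_values(
        ["tf", "experiment_type", "rank", "motif_id"], kind="mergesort"
    ).reset_index(drop=True)
    global_df = global_df.sort_values(
        ["tf", "rank", "motif_id"], kind="mergesort"
    ).reset_index(drop=True)
    return {"per_type": per_type, "global": global_df}


HARMONIZE_SCOPE = ["tf", "dataset_id", "benchmark_id", "metric_name"]


def harmonize(table: pd.DataFrame) -> pd.DataFrame:
    """Min-max rescale metric values to [0, 1] per (TF, dataset, benchmark,
    metric) scope; degenerate scopes (all values equal) map to 0.5."""
    table = validate_benchmark_table(table).copy()

    def _scale(s: pd.Series) -> pd.Series:
        lo, hi = s.min(), s.max()
        if hi == lo:
            return pd.Series(0.5, index=s.index)
        return (s - lo) / (hi - lo)

    table["scaled_value"] = table.groupby(HARMONIZE_SCOPE, sort=False)[
        "value"
    ].transform(_scale)
    return table


def overall_performance(harmonized: pd.DataFrame, platform: str) -> pd.Series:
    """Mean harmonized value per motif over all metrics and datasets of a
    platform (experiment type)."""
    sub = harmonized[harmonized["experiment_type"] == platform]
    if sub.empty:
        raise ValueError(f"no rows for experiment type {platform!r}")
    return sub.groupby("motif_id")["scaled_value"].mean().sort_values(
        ascending=False
    )


def select_best(
    table: pd.DataFrame,
    mode: str = "global",
    tool: str | None = None,
    tools_by_motif: dict | None = None,
) -> dict:
    """Best motif ids per scope.

    ``per_type``/``global`` use aggregated ranks; ``representative_per_tool``
    uses harmonized overall performance restricted to one tool's motifs
    (``tools_by_motif`` maps motif_id -> tool).
    """
    if mode in ("per_type", "global"):
        agg = aggregate_ranks(table)
        if mode == "global":
            best = (
                agg["global"]
                .sort_values(["tf", "rank", "motif_id"], kind="mergesort")
                .groupby("tf", sort=True)
                .first()["motif_id"]
            )
            return best.to_dict()
        best = (
            agg["per_type"]
            .sort_values(
                ["tf", "experiment_type", "rank", "motif_id"], kind="mergesort"
            )
            .groupby(["tf", "experiment_type"], sort=True)
            .first()["motif_id"]
        )
        return best.to_dict()
    if mode == "representative_per_tool":
        if tool is None or tools_by_motif is None:
            raise ValueError("representative_per_tool needs tool and tools_by_motif")
        harm = harmonize(table)
        harm = harm[harm["motif_id"].map(tools_by_motif) == tool]
        if harm.empty:
            raise ValueError(f"no motifs from tool {tool!r}")
        out = {}
        for tf, sub in harm.groupby("tf", sort=True):
            perf = sub.groupby("motif_id")["scaled_value"].mean()
            out[tf] = perf.sort_values(ascending=False).index[0]
        return out
    raise ValueError(f"unknown mode {mode!r}")
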