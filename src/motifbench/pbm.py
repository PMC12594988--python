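"""Protein-binding microarray probe-intensity normalization.

Three strategies correct systematic biases of the array scans:

* **QNZS** — log-transform, quantile-normalize across replicate arrays so
  every array shares one value distribution, then Z-score each probe using
  its own mean/sd across arrays.
* **SD** — spatial detrending: divide each probe by the ratio of its 11x11
  neighborhood median to the global median, removing smooth spatial
  intensity gradients (multiplicative model).
* **SDQN** — spatial detrending followed by quantile normalization, giving
  a uniform normalized scale across datasets.

Arrays are probe tables with grid coordinates; flagged probes are excluded
from neighborhood statistics and keep their flag through every transform.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "PbmArray",
    "qnzs",
    "spatial_detrend",
    "sdqn",
    "pbm_positive_set",
    "quantile_normalize",
    "MIN_POSITIVE_PROBES",
]

MIN_POSITIVE_PROBES = 50
DETREND_WINDOW = 11

PBM_COLUMNS = ["probe_id", "row", "col", "sequence", "intensity"]


class PbmArray:
    """A single PBM: probe records on a (row, col) grid.

    ``probes`` requires columns probe_id, row, col, sequence, intensity and
    optionally a boolean ``flagged`` column.  Intensities must be positive
    (they are log-transformed by QNZS).
    """

    def __init__(self, probes: pd.DataFrame, design_id: str = "", array_id: str = ""):
        df = probes.reset_index(drop=True).copy()
        missing = set(PBM_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"PbmArray missing columns: {sorted(missing)}")
        if "flagged" not in df.columns:
            df["flagged"] = False
        if df.duplicated(subset=["row", "col"]).any():
            raise ValueError("duplicate (row, col) grid positions")
        if (df["intensity"] <= 0).any():
            raise ValueError("intensities must be positive")
        self.probes = df
        self.design_id = design_id
        self.array_id = array_id

    def __len__(self) -> int:
        return len(self.probes)


def _check_shared_design(arrays: list[PbmArray]) -> None:
    if len(arrays) < 2:
        raise ValueError("need at least two arrays sharing the probe design")
    ref = arrays[0].probes["probe_id"]
    for arr in arrays[1:]:
        if arr.design_id != arrays[0].design_id or not arr.probes[
            "probe_id"
        ].equals(ref):
            raise ValueError("arrays must share the same probe design")


def quantile_normalize(values: np.ndarray) -> np.ndarray:
    """Quantile-normalize columns of an (n_probes, n_arrays) matrix.

    After the transform every column holds the identical sorted value
    vector (the per-rank mean across arrays); ties within a column receive
    the average of their tied quantile values.
    """
    values = np.asarray(values, dtype=float)
    order = np.argsort(values, axis=0, kind="mergesort")
    reference = np.take_along_axis(values, order, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        col = values[:, j]
        ranks = np.empty(len(col), dtype=int)
        ranks[order[:, j]] = np.arange(len(col))
        mapped = reference[ranks]
        # average reference values over ties
        df = pd.Series(mapped).groupby(pd.Series(col)).transform("mean")
        out[:, j] = df.to_numpy()
    return out


def qnzs(arrays: list[PbmArray]) -> list[pd.DataFrame]:
    """Quantile normalization + per-probe Z-scoring across replicate arrays.

    Returns one table per array with a ``value`` column holding the probe's
    Z-score.  Probes with zero variance across arrays get NaN and are
    flagged rather than silently ranked.
    """
    _check_shared_design(arrays)
    logged = np.column_stack(
        [np.log2(arr.probes["intensity"].to_numpy(dtype=float)) for arr in arrays]
    )
    qn = quantile_normalize(logged)
    mean = qn.mean(axis=1, keepdims=True)
    sd = qn.std(axis=1, ddof=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 0, (qn - mean) / sd, np.nan)
    out = []
    for j, arr in enumerate(arrays):
        df = arr.probes.copy()
        df["normalized"] = qn[:, j]
        df["value"] = z[:, j]
        df.loc[~np.isfinite(z[:, j]), "flagged"] = True
        out.append(df)
    return out


def spatial_detrend(array: PbmArray, window: int = DETREND_WINDOW) -> pd.DataFrame:
    """Remove smooth spatial trends by local-median ratio.

    Each probe's intensity is divided by (median of unflagged intensities
    in its ``window x window`` neighborhood / global median of unflagged
    intensities).  Windows truncate at grid edges; probes whose whole
    neighborhood is flagged become flagged themselves.
    """
    df = array.probes.copy()
    rows = df["row"].to_numpy(dtype=int)
    cols = df["col"].to_numpy(dtype=int)
    vals = df["intensity"].to_numpy(dtype=float)
    flagged = df["flagged"].to_numpy(dtype=bool)
    r0, c0 = rows.min(), cols.min()
    grid = np.full((rows.max() - r0 + 1, cols.max() - c0 + 1), np.nan)
    grid[rows - r0, cols - c0] = np.where(flagged, np.nan, vals)
    global_median = np.nanmedian(grid)
    half = window // 2
    out = np.empty(len(df))
    newly_flagged = np.zeros(len(df), dtype=bool)
    for i in range(len(df)):
        r, c = rows[i] - r0, cols[i] - c0
        block = grid[
            max(0, r - half) : r + half + 1, max(0, c - half) : c + half + 1
        ]
        local = np.nanmedian(block) if np.any(np.isfinite(block)) else np.nan
        if not np.isfinite(local) or local <= 0:
            out[i] = vals[i]
            newly_flagged[i] = True
        else:
            out[i] = vals[i] / (local / global_median)
    df["value"] = out
    df.loc[newly_flagged, "flagged"] = True
    return df


def sdqn(arrays: list[PbmArray], window: int = DETREND_WINDOW) -> list[pd.DataFrame]:
    """Spatial detrending followed by quantile normalization across arrays."""
    _check_shared_design(arrays)
    detrended = [spatial_detrend(arr, window) for arr in arrays]
    mat = np.column_stack([df["value"].to_numpy(dtype=float) for df in detrended])
    qn = quantile_normalize(np.log2(mat))
    for j, df in enumerate(detrended):
        df["value"] = qn[:, j]
    return detrended


def pbm_positive_set(
    values,
    rule: str = "mean_plus_4sd",
    min_positives: int = MIN_POSITIVE_PROBES,
) -> np.ndarray:
    """Boolean positive-probe labels for the PBM benchmark.

    ``mean_plus_4sd`` selects probes above mean + 4 sd of the values;
    ``zscore_gt_4`` selects values strictly above 4.  If fewer than
    ``min_positives`` pass, the top ``min_positives`` values are taken
    instead.
    """
    values = np.asarray(values, dtype=float)
    if values.size < min_positives:
        raise ValueError(f"need at least {min_positives} probes, got {values.size}")
    if rule == "mean_plus_4sd":
        finite = values[np.isfinite(values)]
        labels = values > finite.mean() + 4 * finite.std(ddof=0)
    elif rule == "zscore_gt_4":
        labels = values > 4
    else:
        raise ValueError(f"unknown rule {rule!r}")
    labels &= np.isfinite(values)
    if labels.sum() < min_positives:
        filled = np.where(np.isfinite(values), values, -np.inf)
        top = np.argsort(-filled, kind="mergesort")[:min_positives]
        labels = np.zeros(values.size, dtype=bool)
        labels[top] = True
    return labels
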