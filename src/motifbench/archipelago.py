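"""Archipelago: a random forest over PWM best-hit scores for genomic TFBS
prediction.

Many TFs bind several distinct site subtypes that no single fixed-width PWM
captures.  Archipelago builds, per TF, a feature matrix of log-odds best-hit
scores of the top-performing PWMs over 301-bp peak-summit-centered regions,
and trains a random forest classifier (max_depth=6, max_samples=0.8,
n_estimators=100) on standardized features against GC-matched random
genomic negatives.  Evaluation uses three negative sets — random regions
(1:100), "alien" peaks of other TFs (1:100) and "shades" flanking the true
summits (up to 1:2) — and reports auROC/auPRC per set plus their mean, the
gain over the best single PWM, and a feature-importance motif ranking.

PWMs discovered from the test experiment platform are excluded from the
features (leakage guard), as are test-chromosome sequences from training.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.preprocessing import StandardScaler
from sklearn.utils.validation import check_is_fitted

from .benchmarks import PeakSet, classification_metrics
from .motifs import MotifRecord
from .scanning import best_hit_scores_batch

__all__ = [
    "NegativeSetSpec",
    "ArchipelagoDataset",
    "ArchipelagoClassifier",
    "merge_peaks",
    "build_positive_set",
    "sample_negatives",
    "build_feature_matrix",
    "train_archipelago",
    "evaluate_archipelago",
    "delta_vs_best_pwm",
    "importance_ranking",
    "POSITIVE_HALF",
    "SHADE_OFFSET_RANGE",
]

POSITIVE_HALF = 150  # positives are [summit-150, summit+151), 301 bp
SHADE_OFFSET_RANGE = (450, 750)  # |shade summit - true summit| interval
RF_PARAMS = {"max_depth": 6, "max_samples": 0.8, "n_estimators": 100}
GC_BIN_WIDTH = 0.02


@dataclass(frozen=True)
class NegativeSetSpec:
    """How to build a negative set.

    kind 'random': GC-matched random genomic regions, ratio 100 per
    positive; 'alien': peaks of other TFs, GC-matched, ratio 100 (all taken
    unmatched if unachievable); 'shades': flanking regions with summits
    drawn uniformly from +-[450, 750] bp, up to 2 per positive.
    """

    kind: str
    ratio: float = 100.0
    gc_matched: bool = True

    def __post_init__(self):
        if self.kind not in ("random", "alien", "shades"):
            raise ValueError(f"unknown negative kind {self.kind!r}")
        if self.kind == "shades" and self.ratio > 2:
            raise ValueError("shades ratio is at most 2 per positive")


@dataclass
class ArchipelagoDataset:
    """Labelled sequences with their per-PWM best-hit feature matrix."""

    sequences: list[str]
    labels: np.ndarray
    features: np.ndarray  # (n_sequences, n_pwms)
    pwm_ids: list[str]
    provenance: pd.DataFrame | None = None

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        self.features = np.asarray(self.features, dtype=float)
        if self.features.shape != (len(self.sequences), len(self.pwm_ids)):
            raise ValueError("feature matrix shape mismatch")
        if np.isnan(self.features).any():
            raise ValueError("feature matrix must have no missing values")


# ---------------------------------------------------------------------------
# positives


def merge_peaks(peaksets: list[PeakSet]) -> PeakSet:
    """Union overlapping peaks across peak sets; merged summit = floor of
    the mean of member summits; merged signal = max of member signals."""
    frames = [ps.records for ps in peaksets if len(ps)]
    if not frames:
        return PeakSet(
            pd.DataFrame(columns=["chrom", "start", "end", "signal", "summit_offset"])
        )
    df = pd.concat(frames, ignore_index=True).sort_values(
        ["chrom", "start", "end"], kind="mergesort"
    )
    out = []
    for chrom, sub in df.groupby("chrom", sort=True):
        cur = None
        for rec in sub.itertuples(index=False):
            summit = rec.start + rec.summit_offset
            if cur is None or rec.start >= cur["end"]:
                if cur is not None:
                    out.append(cur)
                cur = {
                    "chrom": chrom,
                    "start": int(rec.start),
                    "end": int(rec.end),
                    "signal": float(rec.signal),
                    "summits": [summit],
                }
            else:
                cur["end"] = max(cur["end"], int(rec.end))
                cur["signal"] = max(cur["signal"], float(rec.signal))
                cur["summits"].append(summit)
        if cur is not None:
            out.append(cur)
    rows = []
    for rec in out:
        summit = int(np.floor(np.mean(rec["summits"])))
        rows.append(
            {
                "chrom": rec["chrom"],
                "start": rec["start"],
                "end": rec["end"],
                "signal": rec["signal"],
                "summit_offset": summit - rec["start"],
            }
        )
    return PeakSet(pd.DataFrame(rows))


def build_positive_set(peaks: PeakSet, genome: dict) -> pd.DataFrame:
    """301-bp regions centered at merged peak summits.

    Returns a table (chrom, start, end, sequence); summit windows that run
    off the contig or contain N are dropped.
    """
    rows = []
    for rec in peaks.records.itertuples(index=False):
        summit = int(rec.start + rec.summit_offset)
        start, end = summit - POSITIVE_HALF, summit + POSITIVE_HALF + 1
        seq = genome.get(rec.chrom)
        if seq is None or start < 0 or end > len(seq):
            continue
        window = seq[start:end]
        if "N" in window:
            continue
        rows.append(
            {"chrom": rec.chrom, "start": start, "end": end, "sequence": window}
        )
    if not rows:
        raise ValueError("no peak yields a valid 301-bp positive window")
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# negatives


def _gc(seq: str) -> float:
    return (seq.count("G") + seq.count("C")) / len(seq)


def _overlaps(intervals: dict, chrom: str, start: int, end: int) -> bool:
    arr = intervals.get(chrom)
    if arr is None or not len(arr):
        return False
    starts, ends = arr
    i = np.searchsorted(starts, end)
    return bool(np.any(ends[:i] > start))


def _interval_index(df: pd.DataFrame) -> dict:
    out = {}
    for chrom, sub in df.groupby("chrom"):
        sub = sub.sort_values("start")
        out[chrom] = (sub["start"].to_numpy(), sub["end"].to_numpy())
    return out


def _gc_matched_sample(
    candidates: list[dict],
    target_gcs: np.ndarray,
    n_needed: int,
    rng: np.random.Generator,
) -> list[dict]:
    """Sample candidates so their 2%-binned GC histogram matches the target."""
    bins = np.floor(np.array([c["gc"] for c in candidates]) / GC_BIN_WIDTH).astype(int)
    by_bin: dict[int, list[int]] = {}
    for i, b in enumerate(bins):
        by_bin.setdefault(b, []).append(i)
    target_bins = np.floor(target_gcs / GC_BIN_WIDTH).astype(int)
    draw_bins = rng.choice(target_bins, size=n_needed, replace=True)
    chosen = []
    all_bins = sorted(by_bin)
    for b in draw_bins:
        pool = by_bin.get(b)
        if not pool:
            # nearest non-empty bin
            nearest = min(all_bins, key=lambda x: abs(x - b))
            pool = by_bin[nearest]
        chosen.append(candidates[pool[rng.integers(len(pool))]])
    return chosen


def sample_negatives(
    spec: NegativeSetSpec,
    positives: pd.DataFrame,
    genome: dict,
    exclusion: pd.DataFrame | None = None,
    pool: PeakSet | None = None,
    seed: int = 0,
    peaks: PeakSet | None = None,
) -> pd.DataFrame:
    """Build a negative-region table per the spec.

    All negatives are 301 bp, avoid the positives' whole peaks, optional
    blacklist regions and N-containing windows, and are deterministic for a
    given seed.  ``peaks`` (the merged positive peaks) defines the excluded
    peak intervals; ``pool`` supplies alien peaks.
    """
    rng = np.random.default_rng(seed)
    excl_frames = []
    if peaks is not None and len(peaks):
        excl_frames.append(peaks.records[["chrom", "start", "end"]])
    else:
        excl_frames.append(positives[["chrom", "start", "end"]])
    if exclusion is not None and len(exclusion):
        excl_frames.append(exclusion[["chrom", "start", "end"]])
    excl = _interval_index(pd.concat(excl_frames, ignore_index=True))
    width = 2 * POSITIVE_HALF + 1

    def window_ok(chrom: str, start: int) -> str | None:
        seq = genome.get(chrom)
        end = start + width
        if seq is None or start < 0 or end > len(seq):
            return None
        if _overlaps(excl, chrom, start, end):
            return None
        win = seq[start:end]
        if "N" in win:
            return None
        return win

    target_gcs = positives["sequence"].map(_gc).to_numpy()
    n_pos = len(positives)
    rows: list[dict] = []

    if spec.kind == "shades":
        lo, hi = SHADE_OFFSET_RANGE
        for rec in positives.itertuples(index=False):
            summit = rec.start + POSITIVE_HALF
            for sign in (-1, 1):
                for _ in range(10):  # retries against exclusions
                    off = sign * int(rng.integers(lo, hi + 1))
                    start = summit + off - POSITIVE_HALF
                    win = window_ok(rec.chrom, start)
                    if win is not None:
                        rows.append(
                            {
                                "chrom": rec.chrom,
                                "start": start,
                                "end": start + width,
                                "sequence": win,
                                "offset": off,
                            }
                        )
                        break
        if not rows:
            raise ValueError("no eligible shade windows")
        return pd.DataFrame(rows)

    n_needed = int(round(spec.ratio * n_pos))
    if spec.kind == "random":
        chroms = list(genome)
        lengths = np.array([len(genome[c]) for c in chroms], dtype=float)
        probs = lengths / lengths.sum()
        candidates: list[dict] = []
        attempts = 0
        # oversample so GC matching has material to draw from
        while len(candidates) < max(4 * n_needed, 200) and attempts < 200 * n_needed:
            attempts += 1
            ci = rng.choice(len(chroms), p=probs)
            chrom = chroms[ci]
            if len(genome[chrom]) <= width:
                continue
            start = int(rng.integers(0, len(genome[chrom]) - width))
            win = window_ok(chrom, start)
            if win is not None:
                candidates.append(
                    {
                        "chrom": chrom,
                        "start": start,
                        "end": start + width,
                        "sequence": win,
                        "gc": _gc(win),
                    }
                )
        if not candidates:
            raise ValueError("no eligible random windows in the genome")
        chosen = (
            _gc_matched_sample(candidates, target_gcs, n_needed, rng)
            if spec.gc_matched
            else [candidates[i] for i in rng.integers(len(candidates), size=n_needed)]
        )
        return pd.DataFrame(chosen).drop(columns="gc")

    # alien: windows at other TFs' peak summits
    if pool is None or not len(pool):
        raise ValueError("alien negatives need a pool of other TFs' peaks")
    candidates = []
    for rec in pool.records.itertuples(index=False):
        summit = int(rec.start + rec.summit_offset)
        start = summit - POSITIVE_HALF
        win = window_ok(rec.chrom, start)
        if win is not None:
            candidates.append(
                {
                    "chrom": rec.chrom,
                    "start": start,
                    "end": start + width,
                    "sequence": win,
                    "gc": _gc(win),
                }
            )
    if not candidates:
        raise ValueError("no eligible alien windows")
    if len(candidates) <= n_needed or not spec.gc_matched:
        # unachievable ratio: take all available without GC matching
        chosen = candidates
        if len(candidates) > n_needed:
            idx = rng.choice(len(candidates), size=n_needed, replace=False)
            chosen = [candidates[i] for i in np.sort(idx)]
        return pd.DataFrame(chosen).drop(columns="gc")
    chosen = _gc_matched_sample(candidates, target_gcs, n_needed, rng)
    return pd.DataFrame(chosen).drop(columns="gc")


# ---------------------------------------------------------------------------
# features


def build_feature_matrix(
    sequences: list[str],
    labels,
    pwms: list[MotifRecord],
    exclusion_platform: str | None = None,
    provenance: pd.DataFrame | None = None,
) -> ArchipelagoDataset:
    """Per-sequence best-hit log-odds score for every PWM.

    PWMs originating from ``exclusion_platform`` raise a hard error (they
    would leak test-platform information into the features).  Sequences
    without a valid window take the matrix minimum score minus 1, below any
    achievable score.
    """
    if not pwms:
        raise ValueError("need at least one PWM")
    seen = set()
    unique_pwms = []
    for rec in pwms:
        if exclusion_platform is not None and rec.platform == exclusion_platform:
            raise ValueError(
                f"PWM {rec.motif_id!r} originates from excluded platform "
                f"{exclusion_platform!r}"
            )
        if rec.motif_id not in seen:
            seen.add(rec.motif_id)
            unique_pwms.append(rec)
    features = np.column_stack(
        [best_hit_scores_batch(rec.weights(), sequences) for rec in unique_pwms]
    )
    return ArchipelagoDataset(
        sequences=list(sequences),
        labels=labels,
        features=features,
        pwm_ids=[rec.motif_id for rec in unique_pwms],
        provenance=provenance,
    )


# ---------------------------------------------------------------------------
# model


class ArchipelagoClassifier(BaseEstimator, ClassifierMixin):
    """Random forest over standardized PWM best-hit features.

    sklearn-compatible: ``fit(X, y)`` / ``predict_proba`` / ``predict``;
    the scaler is fit on training data only.  ``model="logreg"`` swaps in
    the logistic-regression comparator behind the same interface.
    """

    def __init__(
        self,
        max_depth: int = 6,
        max_samples: float = 0.8,
        n_estimators: int = 100,
        random_state: int = 0,
        model: str = "random_forest",
    ):
        self.max_depth = max_depth
        self.max_samples = max_samples
        self.n_estimators = n_estimators
        self.random_state = random_state
        self.model = model

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if len(np.unique(y)) < 2:
            raise ValueError("training data must contain both classes")
        self.scaler_ = StandardScaler().fit(X)
        Xs = self.scaler_.transform(X)
        if self.model == "random_forest":
            self.estimator_ = RandomForestClassifier(
                max_depth=self.max_depth,
                max_samples=self.max_samples,
                n_estimators=self.n_estimators,
                random_state=self.random_state,
            )
        elif self.model == "logreg":
            self.estimator_ = LogisticRegression(
                max_iter=1000, random_state=self.random_state
            )
        else:
            raise ValueError(f"unknown model {self.model!r}")
        self.estimator_.fit(Xs, y)
        self.classes_ = self.estimator_.classes_
        self.n_features_in_ = X.shape[1]
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "estimator_")
        return self.estimator_.predict_proba(self.scaler_.transform(X))

    def predict(self, X):
        check_is_fitted(self, "estimator_")
        return self.estimator_.predict(self.scaler_.transform(X))

    def decision_scores(self, X) -> np.ndarray:
        """P(class 1), the score used for auROC/auPRC."""
        proba = self.predict_proba(X)
        return proba[:, list(self.classes_).index(1)]

    @property
    def feature_importances_(self):
        check_is_fitted(self, "estimator_")
        if self.model != "random_forest":
            raise AttributeError("importances require the random forest model")
        return self.estimator_.feature_importances_


def train_archipelago(
    dataset: ArchipelagoDataset, seed: int = 0, model: str = "random_forest"
) -> ArchipelagoClassifier:
    """Fit the Archipelago classifier on a (random-negative) dataset."""
    clf = ArchipelagoClassifier(random_state=seed, model=model)
    return clf.fit(dataset.features, dataset.labels)


def evaluate_archipelago(
    model: ArchipelagoClassifier, test_sets: dict[str, ArchipelagoDataset]
) -> dict:
    """auROC/auPRC per negative set plus their means.

    ``test_sets`` maps negative-set kind -> test dataset (positives and
    that kind's negatives).
    """
    per_set = {}
    for kind, ds in test_sets.items():
        scores = model.decision_scores(ds.features)
        per_set[kind] = classification_metrics(
            scores[ds.labels == 1], scores[ds.labels == 0]
        )
    mean = {
        metric: float(np.mean([m[metric] for m in per_set.values()]))
        for metric in ("auroc", "auprc")
    }
    return {"per_set": per_set, "mean": mean}


def best_pwm_metrics(test_sets: dict[str, ArchipelagoDataset]) -> dict:
    """Per negative set, the best single-PWM auROC and auPRC (features are
    the PWM scores themselves); baselines may be different PWMs."""
    out = {}
    for kind, ds in test_sets.items():
        pos, neg = ds.labels == 1, ds.labels == 0
        per_pwm = [
            classification_metrics(ds.features[pos, j], ds.features[neg, j])
            for j in range(ds.features.shape[1])
        ]
        aurocs = [m["auroc"] for m in per_pwm]
        auprcs = [m["auprc"] for m in per_pwm]
        out[kind] = {
            "auroc": max(aurocs),
            "auprc": max(auprcs),
            "best_auroc_pwm": ds.pwm_ids[int(np.argmax(aurocs))],
            "best_auprc_pwm": ds.pwm_ids[int(np.argmax(auprcs))],
        }
    return out


def delta_vs_best_pwm(model_metrics: dict, pwm_metrics: dict) -> dict:
    """Gain of the model over the per-metric best single PWM.

    ``delta_auroc`` compares against the auROC-best PWM, ``delta_auprc``
    against the auPRC-best PWM (possibly different motifs);
    ``average_gain`` is their mean.  Computed per negative set, then
    averaged.
    """
    per_set = {}
    for kind in model_metrics["per_set"]:
        m = model_metrics["per_set"][kind]
        b = pwm_metrics[kind]
        d_roc = m["auroc"] - b["auroc"]
        d_prc = m["auprc"] - b["auprc"]
        per_set[kind] = {
            "delta_auroc": d_roc,
            "delta_auprc": d_prc,
            "average_gain": (d_roc + d_prc) / 2,
        }
    return {
        "per_set": per_set,
        "delta_auroc": float(np.mean([v["delta_auroc"] for v in per_set.values()])),
        "delta_auprc": float(np.mean([v["delta_auprc"] for v in per_set.values()])),
        "average_gain": float(
            np.mean([v["average_gain"] for v in per_set.values()])
        ),
    }


def importance_ranking(
    model: ArchipelagoClassifier, pwm_ids: list[str], top: int | None = None
) -> list[tuple[str, float]]:
    """PWMs ordered by random-forest feature importance (descending)."""
    imp = model.feature_importances_
    order = np.argsort(-imp, kind="mergesort")
    ranked = [(pwm_ids[i], float(imp[i])) for i in order]
    return ranked[:top] if top else ranked
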