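"""Train/test splitting and the classification benchmark families.

Three benchmark families score a motif's ability to separate bound from
unbound sequences:

* **PBM** — bound probes (by an intensity/Z-score threshold with a 50-probe
  fallback) against the remaining probes.
* **peaks** (ChIP-Seq / genomic HT-SELEX) — 250-bp windows around the top
  peak summits against flanking "shade" windows shifted 300 bp away.
* **reads** (HT-SELEX / SMiLE-Seq) — the top-scoring fraction of reads
  against dinucleotide-shuffled copies of the read pool.

All families report auROC and auPRC; results accumulate in a long-form
benchmark table consumed by the rank-aggregation module.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .motifs import FrequencyMatrix, MotifRecord
from .scanning import ScanConfig, sum_occupancy_score, PBM_LINKER_PREFIX
from .pbm import pbm_positive_set

__all__ = [
    "PeakSet",
    "BENCHMARK_TABLE_COLUMNS",
    "make_benchmark_rows",
    "validate_benchmark_table",
    "split_peaks",
    "split_reads",
    "classification_metrics",
    "pbm_benchmark",
    "peaks_benchmark",
    "reads_benchmark",
    "reads_benchmark_all",
    "peak_benchmark_windows",
    "dedup_and_sample_reads",
    "dinucleotide_shuffle",
    "MIN_PEAKS",
    "MAX_BENCHMARK_PEAKS",
    "MAX_UNIQUE_READS",
    "READ_FRACTIONS",
]

MIN_PEAKS = 50  # minimum test (benchmarking) / train (discovery) peaks
MAX_BENCHMARK_PEAKS = 1000
MAX_UNIQUE_READS = 500_000
READ_FRACTIONS = (0.10, 0.25, 0.50)

POSITIVE_HALF_UP = 124  # positive window: [summit-124, summit+126), 250 bp
POSITIVE_HALF_DOWN = 126
SHADE_SHIFT = 300


@dataclass
class PeakSet:
    """narrowPeak records (0-based half-open) with summit offsets."""

    records: pd.DataFrame  # columns: chrom, start, end, signal, summit_offset
    dataset_id: str = ""
    replicate_id: str = ""

    def __post_init__(self):
        df = self.records.reset_index(drop=True)
        required = {"chrom", "start", "end", "signal", "summit_offset"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"PeakSet missing columns: {sorted(missing)}")
        if len(df):
            if not (df["start"] < df["end"]).all():
                raise ValueError("peak start must be < end")
            off = df["summit_offset"]
            if not ((off >= 0) & (off < df["end"] - df["start"])).all():
                raise ValueError("summit_offset must lie within the peak")
        self.records = df

    def __len__(self) -> int:
        return len(self.records)

    @property
    def summits(self) -> pd.Series:
        return self.records["start"] + self.records["summit_offset"]

    def subset(self, mask) -> "PeakSet":
        return PeakSet(
            self.records[mask].reset_index(drop=True),
            dataset_id=self.dataset_id,
            replicate_id=self.replicate_id,
        )

    def sort_by_coordinate(self) -> "PeakSet":
        df = self.records.sort_values(["chrom", "start", "end"], kind="mergesort")
        return PeakSet(df, self.dataset_id, self.replicate_id)


BENCHMARK_TABLE_COLUMNS = [
    "motif_id",
    "tf",
    "dataset_id",
    "experiment_type",
    "benchmark_id",
    "variant",
    "metric_name",
    "value",
]


def make_benchmark_rows(
    metrics: dict,
    motif_id: str,
    tf: str,
    dataset_id: str,
    experiment_type: str,
    benchmark_id: str,
    variant: str = "default",
) -> pd.DataFrame:
    rows = [
        dict(
            motif_id=motif_id,
            tf=tf,
            dataset_id=dataset_id,
            experiment_type=experiment_type,
            benchmark_id=benchmark_id,
            variant=variant,
            metric_name=name,
            value=float(value),
        )
        for name, value in metrics.items()
    ]
    return pd.DataFrame(rows, columns=BENCHMARK_TABLE_COLUMNS)


def validate_benchmark_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = set(BENCHMARK_TABLE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"benchmark table missing columns: {sorted(missing)}")
    key = ["motif_id", "dataset_id", "benchmark_id", "variant", "metric_name"]
    if table.duplicated(subset=key).any():
        raise ValueError("duplicate (motif, dataset, benchmark, variant, metric) rows")
    return table


# ---------------------------------------------------------------------------
# splits


def _autosome_number(chrom: str) -> int | None:
    if isinstance(chrom, str) and chrom.startswith("chr"):
        tail = chrom[3:]
        if tail.isdigit() and 1 <= int(tail) <= 22:
            return int(tail)
    return None


def split_peaks(peaks: PeakSet) -> dict:
    """Chromosome-holdout split: odd autosomes train, even autosomes test.

    Non-autosomal contigs are dropped with a warning.  Eligibility flags
    require at least 50 test peaks for benchmarking and 50 training peaks
    for motif discovery.
    """
    numbers = peaks.records["chrom"].map(_autosome_number)
    dropped = numbers.isna()
    if dropped.any():
        names = sorted(peaks.records.loc[dropped, "chrom"].unique())
        warnings.warn(f"dropping non-autosomal contigs: {names}", stacklevel=2)
    train = peaks.subset(numbers.notna() & (numbers % 2 == 1))
    test = peaks.subset(numbers.notna() & (numbers % 2 == 0))
    return {
        "train": train,
        "test": test,
        "eligible": {
            "benchmarking": len(test) >= MIN_PEAKS,
            "discovery": len(train) >= MIN_PEAKS,
        },
    }


def split_reads(reads, seed: int) -> dict:
    """Deterministic 2:1 train/test split of reads, performed per cycle.

    ``reads`` is either a flat list (one cycle) or a {cycle: list} dict.
    ``|train| = round(2n/3)`` per cycle; cycles are pooled in the output.
    """
    if isinstance(reads, dict):
        cycles = reads
    else:
        cycles = {0: list(reads)}
    rng = np.random.default_rng(seed)
    train: list = []
    test: list = []
    for cycle in sorted(cycles):
        pool = list(cycles[cycle])
        n = len(pool)
        n_train = round(2 * n / 3)
        perm = rng.permutation(n)
        train.extend(pool[i] for i in perm[:n_train])
        test.extend(pool[i] for i in perm[n_train:])
    return {"train": train, "test": test}


# ---------------------------------------------------------------------------
# metrics


def classification_metrics(pos_scores, neg_scores) -> dict:
    """auROC (Mann-Whitney form, ties at half weight) and auPRC
    (precision step-interpolation over recall)."""
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if pos.size == 0:
        raise ValueError("positive score list is empty")
    if neg.size == 0:
        raise ValueError("negative score list is empty")
    ranks = rankdata(np.concatenate([pos, neg]))
    auroc = (ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2) / (
        pos.size * neg.size
    )
    return {"auroc": float(auroc), "auprc": _average_precision(pos, neg)}


def _average_precision(pos: np.ndarray, neg: np.ndarray) -> float:
    """AP = sum over distinct thresholds of precision * delta-recall."""
    scores = np.concatenate([pos, neg])
    labels = np.concatenate([np.ones(pos.size), np.zeros(neg.size)])
    order = np.argsort(-scores, kind="mergesort")
    scores, labels = scores[order], labels[order]
    distinct = np.nonzero(np.diff(scores))[0]
    cut = np.r_[distinct, scores.size - 1]
    tp = np.cumsum(labels)[cut]
    n_pred = cut + 1.0
    precision = tp / n_pred
    recall = tp / pos.size
    delta_recall = np.diff(np.r_[0.0, recall])
    return float((precision * delta_recall).sum())


def dedup_and_sample_reads(
    reads: list[str], rng: np.random.Generator, cap: int = MAX_UNIQUE_READS
) -> list[str]:
    """Order-preserving dedup followed by seeded sampling of at most ``cap``
    unique reads (without replacement)."""
    unique = list(dict.fromkeys(reads))
    if len(unique) > cap:
        idx = rng.choice(len(unique), size=cap, replace=False)
        unique = [unique[i] for i in np.sort(idx)]
    return unique


# ---------------------------------------------------------------------------
# shuffling


def dinucleotide_shuffle(sequence: str, rng: np.random.Generator) -> str:
    """Shuffle a sequence preserving its exact dinucleotide counts
    (random Eulerian path on the dinucleotide multigraph)."""
    if len(sequence) < 3:
        return sequence
    seq = sequence.upper()
    edges: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        edges.setdefault(a, []).append(b)
    last = seq[-1]
    vertices = list(edges)
    # pick a random last-edge per non-terminal vertex forming a tree into `last`
    for _ in range(1000):
        last_edge = {
            v: edges[v][rng.integers(len(edges[v]))] for v in vertices if v != last
        }
        ok = True
        for v in last_edge:
            cur, seen = v, {v}
            while cur != last:
                cur = last_edge.get(cur)
                if cur is None or cur in seen:
                    ok = False
                    break
                seen.add(cur)
            if not ok:
                break
        if ok:
            break
    else:  # pragma: no cover - astronomically unlikely for DNA
        raise RuntimeError("failed to sample an Eulerian last-edge tree")
    ordered: dict[str, list[str]] = {}
    for v in vertices:
        rest = list(edges[v])
        if v != last:
            rest.remove(last_edge[v])
        rng.shuffle(rest)
        if v != last:
            rest.append(last_edge[v])
        ordered[v] = rest
    out = [seq[0]]
    counters = {v: 0 for v in vertices}
    cur = seq[0]
    for _ in range(len(seq) - 1):
        nxt = ordered[cur][counters[cur]]
        counters[cur] += 1
        out.append(nxt)
        cur = nxt
    return "".join(out)


# ---------------------------------------------------------------------------
# benchmark families


def _motif_frequencies(motif) -> FrequencyMatrix:
    if isinstance(motif, MotifRecord):
        return motif.frequencies()
    if isinstance(motif, FrequencyMatrix):
        return motif
    raise TypeError("motif must be a MotifRecord or FrequencyMatrix")


def pbm_benchmark(
    motif,
    probes: pd.DataFrame,
    normalization: str = "SD",
    linker_prefix: str = PBM_LINKER_PREFIX,
    config: ScanConfig = ScanConfig(),
) -> dict:
    """PBM classification benchmark: bound probes vs the rest.

    ``probes`` must carry ``sequence`` and ``value`` (normalized intensity
    or Z-score) columns.  Positives follow the normalization-specific rule
    (SD: mean + 4 sd; QNZS: Z > 4) with the top-50 fallback; scores are
    sum-occupancy over the probe with the first 6 linker bases prepended.
    """
    if normalization not in ("SD", "QNZS"):
        raise ValueError("normalization must be 'SD' or 'QNZS'")
    freqs = _motif_frequencies(motif)
    values = probes["value"].to_numpy(dtype=float)
    rule = "mean_plus_4sd" if normalization == "SD" else "zscore_gt_4"
    labels = pbm_positive_set(values, rule=rule)
    scores = np.array(
        [
            sum_occupancy_score(freqs, linker_prefix[:6] + seq, config)
            for seq in probes["sequence"]
        ]
    )
    return classification_metrics(scores[labels], scores[~labels])


def _extract_window(genome: dict, chrom: str, start: int, end: int) -> str | None:
    seq = genome.get(chrom)
    if seq is None or start < 0 or end > len(seq):
        return None
    return seq[start:end]


def peak_benchmark_windows(
    test_peaks: PeakSet, genome: dict
) -> tuple[list[str], list[str], pd.DataFrame]:
    """Positive/negative window construction of the peak benchmark.

    Up to the top 1000 test peaks by signal yield 250-bp positive windows
    ``[summit-124, summit+126)``; each positive contributes two negative
    windows shifted 300 bp up- and downstream.  Windows extending past
    contig edges are dropped.  Returns (positives, negatives, coordinates).
    """
    df = test_peaks.records.sort_values(
        ["signal", "chrom", "start"], ascending=[False, True, True], kind="mergesort"
    ).head(MAX_BENCHMARK_PEAKS)
    summits = df["start"] + df["summit_offset"]
    pos_seqs, neg_seqs, coords = [], [], []
    for chrom, summit in zip(df["chrom"], summits):
        start, end = summit - POSITIVE_HALF_UP, summit + POSITIVE_HALF_DOWN
        pos = _extract_window(genome, chrom, start, end)
        if pos is None:
            continue
        pos_seqs.append(pos)
        coords.append({"chrom": chrom, "start": start, "end": end, "role": "pos"})
        for shift in (-SHADE_SHIFT, SHADE_SHIFT):
            neg = _extract_window(genome, chrom, start + shift, end + shift)
            if neg is not None:
                neg_seqs.append(neg)
                coords.append(
                    {
                        "chrom": chrom,
                        "start": start + shift,
                        "end": end + shift,
                        "role": "neg",
                    }
                )
    return pos_seqs, neg_seqs, pd.DataFrame(coords)


def peaks_benchmark(
    motif,
    test_peaks: PeakSet,
    genome: dict,
    config: ScanConfig = ScanConfig(),
) -> dict:
    """Peak classification benchmark (positives vs flanking shades).

    Windows come from :func:`peak_benchmark_windows`; scoring is
    sum-occupancy; metrics are auROC and auPRC.
    """
    freqs = _motif_frequencies(motif)
    pos_seqs, neg_seqs, _ = peak_benchmark_windows(test_peaks, genome)
    if not pos_seqs:
        raise ValueError("no valid positive windows within the genome")
    if not neg_seqs:
        raise ValueError("no valid negative windows within the genome")
    pos_scores = [sum_occupancy_score(freqs, s, config) for s in pos_seqs]
    neg_scores = [sum_occupancy_score(freqs, s, config) for s in neg_seqs]
    return classification_metrics(pos_scores, neg_scores)


def reads_benchmark(
    motif,
    reads: list[str],
    fraction: float,
    seed: int,
    flank5: str = "",
    flank3: str = "",
    config: ScanConfig = ScanConfig(),
) -> dict:
    """Read-set benchmark: top-scoring reads vs dinucleotide-shuffled reads.

    Reads are deduplicated, at most 500,000 are sampled, and the top
    ``ceil(fraction * n)`` by sum-occupancy score (with constant flanks
    attached) become positives; negatives are seeded dinucleotide shuffles
    of every sampled read, scored within the same flanks.
    """
    return reads_benchmark_all(
        motif, reads, (fraction,), seed, flank5, flank3, config
    )[fraction]


def reads_benchmark_all(
    motif,
    reads: list[str],
    fractions=READ_FRACTIONS,
    seed: int = 0,
    flank5: str = "",
    flank3: str = "",
    config: ScanConfig = ScanConfig(),
) -> dict:
    """Reads benchmark for several positive fractions sharing one scan.

    Returns {fraction: metrics}; sampling and shuffling are seeded once, so
    the single-fraction form is a slice of this result.
    """
    for fraction in fractions:
        if not any(math.isclose(fraction, f) for f in READ_FRACTIONS):
            raise ValueError(
                f"fraction must be one of {READ_FRACTIONS}, got {fraction}"
            )
    freqs = _motif_frequencies(motif)
    rng = np.random.default_rng(seed)
    unique = dedup_and_sample_reads(reads, rng)
    scores = np.array(
        [sum_occupancy_score(freqs, flank5 + r + flank3, config) for r in unique]
    )
    neg_scores = np.array(
        [
            sum_occupancy_score(
                freqs, flank5 + dinucleotide_shuffle(r, rng) + flank3, config
            )
            for r in unique
        ]
    )
    order = np.argsort(-scores, kind="mergesort")
    out = {}
    for fraction in fractions:
        n_pos = math.ceil(fraction * len(unique))
        out[fraction] = classification_metrics(scores[order[:n_pos]], neg_scores)
    return out
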