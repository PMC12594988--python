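"""End-to-end synthetic experiments tying the whole stack together.

Two reference experiments, both fully seeded:

* **ranking recovery** — simulate peaks, SELEX reads and PBM arrays all
  driven by one planted motif, benchmark the planted motif against decoy
  competitors on every platform, aggregate hierarchically, and check that
  the planted motif wins the global cross-platform ranking.
* **Archipelago gain** — simulate a TF with one or two disjoint binding
  modes, build the Archipelago train/test datasets (random / alien /
  shades negatives, chromosome holdout) and measure the random forest's
  auROC gain over the best single PWM.

These are the workhorses behind the acceptance checks and double as usage
examples; problem sizes are desk-scale (kilobase chromosomes, thousands of
reads) rather than genome-scale.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import archipelago as arch
from .aggregation import aggregate_ranks
from .background import pseudo_auroc
from .benchmarks import (
    make_benchmark_rows,
    peaks_benchmark,
    reads_benchmark_all,
    pbm_benchmark,
    split_peaks,
    split_reads,
    READ_FRACTIONS,
)
from .motifs import FrequencyMatrix, MotifRecord, CountMatrix
from .pbm import qnzs, spatial_detrend
from .simulate import (
    GenomeConfig,
    PbmConfig,
    PeakConfig,
    SelexConfig,
    make_decoys,
    make_genome,
    plant_peaks,
    simulate_pbm,
    simulate_selex,
)

__all__ = [
    "planted_motif",
    "second_mode_motif",
    "run_recovery_experiment",
    "run_archipelago_experiment",
]


def _soft_onehot(consensus: str, dominant: float = 0.85) -> FrequencyMatrix:
    rest = (1 - dominant) / 3
    mat = np.full((len(consensus), 4), rest)
    for j, b in enumerate(consensus):
        mat[j, "ACGT".index(b)] = dominant
    return FrequencyMatrix(mat)


def planted_motif() -> FrequencyMatrix:
    """The reference planted motif: an AT-rich 10-mer at 90% consensus
    (~12.7 bits), the information content of a typical specific TF."""
    return _soft_onehot("ATTGCACAAT", dominant=0.9)


def second_mode_motif() -> FrequencyMatrix:
    """A dissimilar second binding mode (E-box-like GC-rich 10-mer)."""
    return _soft_onehot("GCCACGTGGC", dominant=0.9)


def _competitors(seed: int) -> list[tuple[str, FrequencyMatrix]]:
    """Planted motif plus nine seeded decoys of three kinds."""
    motif = planted_motif()
    named = [("planted", motif)]
    for kind in ("column_shuffle", "dinuc_sample", "random"):
        for i, decoy in enumerate(make_decoys(motif, 3, kind=kind, seed=seed)):
            named.append((f"decoy_{kind}_{i}", decoy))
    return named


def run_recovery_experiment(
    seed: int,
    n_peaks: int = 200,
    reads_per_cycle: int = 1000,
    genome_length: int = 120_000,
) -> dict:
    """Benchmark planted motif vs 9 decoys across three simulated platforms
    and aggregate; returns the benchmark table, rankings and the winner."""
    motif = planted_motif()
    competitors = _competitors(seed)
    rows = []

    # --- peaks platform (ChIP-Seq-like)
    genome = make_genome(GenomeConfig(n_autosomes=4, length=genome_length), seed=seed)
    peaks, genome = plant_peaks(
        genome, motif, PeakConfig(n=n_peaks, half_width=150), seed=seed + 1
    )
    test_peaks = split_peaks(peaks)["test"]
    # pseudo-auROC positives: first peaks in coordinate order, summit +-150
    coord = test_peaks.sort_by_coordinate()
    pa_positives = []
    for rec in coord.records.head(1000).itertuples(index=False):
        summit = rec.start + rec.summit_offset
        seq = genome[rec.chrom][summit - 150 : summit + 151]
        if len(seq) == 301:
            pa_positives.append(seq)
    for name, freqs in competitors:
        rows.append(
            make_benchmark_rows(
                peaks_benchmark(freqs, test_peaks, genome),
                name, "TF1", "chs_rep1", "CHS", "peak_classification",
            )
        )
        pa = pseudo_auroc(
            MotifRecord(name, freqs).weights(), pa_positives, d=20
        )
        rows.append(
            make_benchmark_rows(
                {"pseudo_auroc": pa},
                name, "TF1", "chs_rep1", "CHS", "pseudo_auroc",
            )
        )

    # --- reads platform (HT-SELEX-like)
    selex = simulate_selex(
        motif,
        SelexConfig(cycles=3, reads_per_cycle=reads_per_cycle),
        seed=seed + 2,
    )
    test_reads = split_reads(
        {c: selex.reads_by_cycle[c] for c in (1, 2, 3)}, seed=seed + 3
    )["test"]
    for name, freqs in competitors:
        per_fraction = reads_benchmark_all(
            freqs, test_reads, READ_FRACTIONS, seed=seed + 4,
            flank5=selex.flank5, flank3=selex.flank3,
        )
        for fraction, metrics in per_fraction.items():
            rows.append(
                make_benchmark_rows(
                    metrics,
                    name, "TF1", "hts_rep1", "HTS", "read_classification",
                    variant=f"top{int(fraction * 100)}",
                )
            )

    # --- PBM platform
    arrays = simulate_pbm(motif, PbmConfig(), seed=seed + 5)
    sd_probes = spatial_detrend(arrays[0])
    qnzs_probes = qnzs(arrays)[0]
    for name, freqs in competitors:
        for variant, probes, norm in (
            ("SD", sd_probes, "SD"),
            ("QNZS", qnzs_probes, "QNZS"),
        ):
            rows.append(
                make_benchmark_rows(
                    pbm_benchmark(freqs, probes, normalization=norm),
                    name, "TF1", "pbm_rep1", "PBM", "pbm_classification",
                    variant=variant,
                )
            )

    table = pd.concat(rows, ignore_index=True)
    ranking = aggregate_ranks(table)
    winner = ranking["global"].iloc[0]["motif_id"]
    return {"table": table, "ranking": ranking, "winner": winner}


def _freq_record(name: str, freqs: FrequencyMatrix, platform: str) -> MotifRecord:
    counts = CountMatrix(
        freqs.matrix * 100, total_count=100, source_kind="normalized_pfm_scaled"
    )
    return MotifRecord(name, counts, tf="TF1", platform=platform)


def run_archipelago_experiment(
    seed: int,
    two_mode: bool = True,
    n_peaks: int = 300,
    genome_length: int = 200_000,
    negative_ratio: float = 25.0,
) -> dict:
    """Train and evaluate Archipelago on a simulated one- or two-mode TF.

    Builds merged peaks, 301-bp positives, the three negative sets (random
    negatives train the forest), a PWM feature panel containing the planted
    mode PFMs plus decoys, and reports per-negative-set metrics, the gain
    over the best single PWM, and the importance ranking.
    """
    mode_a = planted_motif()
    modes = [mode_a, second_mode_motif()] if two_mode else [mode_a]
    genome = make_genome(GenomeConfig(n_autosomes=4, length=genome_length), seed=seed)
    peaks, genome = plant_peaks(
        genome, modes, PeakConfig(n=n_peaks, half_width=150), seed=seed + 1
    )
    # an unrelated TF provides alien peaks
    alien_motif = _soft_onehot("ATCGATAC")
    alien_peaks, genome = plant_peaks(
        genome, alien_motif, PeakConfig(n=n_peaks, half_width=150),
        seed=seed + 2, avoid=peaks,
    )

    merged = arch.merge_peaks([peaks])
    positives = arch.build_positive_set(merged, genome)

    # PWM panel: both planted modes + decoys, from non-excluded platforms
    panel = [_freq_record("pwm_mode_a", mode_a, "HTS")]
    if two_mode:
        panel.append(_freq_record("pwm_mode_b", second_mode_motif(), "HTS"))
    for i, decoy in enumerate(make_decoys(mode_a, 4, kind="random", seed=seed + 3)):
        panel.append(_freq_record(f"pwm_decoy_{i}", decoy, "SMS"))

    neg_random = arch.sample_negatives(
        arch.NegativeSetSpec("random", ratio=negative_ratio),
        positives, genome, peaks=merged, seed=seed + 4,
    )
    neg_alien = arch.sample_negatives(
        arch.NegativeSetSpec("alien", ratio=negative_ratio),
        positives, genome, pool=arch.merge_peaks([alien_peaks]),
        peaks=merged, seed=seed + 5,
    )
    neg_shades = arch.sample_negatives(
        arch.NegativeSetSpec("shades", ratio=2),
        positives, genome, peaks=merged, seed=seed + 6,
    )

    def parity(df: pd.DataFrame) -> pd.Series:
        return df["chrom"].str.removeprefix("chr").astype(int) % 2

    def build(df_pos, df_neg, mask_pos, mask_neg):
        seqs = list(df_pos.loc[mask_pos, "sequence"]) + list(
            df_neg.loc[mask_neg, "sequence"]
        )
        labels = np.r_[
            np.ones(int(mask_pos.sum())), np.zeros(int(mask_neg.sum()))
        ]
        return arch.build_feature_matrix(
            seqs, labels, panel, exclusion_platform="GHTS"
        )

    pos_par = parity(positives)
    train = build(positives, neg_random, pos_par == 1, parity(neg_random) == 1)
    test_sets = {
        "random": build(positives, neg_random, pos_par == 0, parity(neg_random) == 0),
        "alien": build(positives, neg_alien, pos_par == 0, parity(neg_alien) == 0),
        "shades": build(positives, neg_shades, pos_par == 0, parity(neg_shades) == 0),
    }

    model = arch.train_archipelago(train, seed=seed)
    metrics = arch.evaluate_archipelago(model, test_sets)
    baselines = arch.best_pwm_metrics(test_sets)
    gains = arch.delta_vs_best_pwm(metrics, baselines)
    importances = arch.importance_ranking(model, train.pwm_ids)
    return {
        "model": model,
        "metrics": metrics,
        "baselines": baselines,
        "gains": gains,
        "importances": importances,
        "pwm_ids": train.pwm_ids,
        "n_positives": len(positives),
        "datasets": {"train": train, "test": test_sets},
    }
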