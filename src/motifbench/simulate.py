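"""Seeded generators for every input the benchmarking stack consumes.

The generators emulate the statistical structure the benchmarks assume —
summit-centered planted motif sites in genomic peaks, multiplicative cycle
enrichment in SELEX reads, smooth spatial intensity trends on PBM grids,
decoy and artifact motifs — while staying at desk scale.  Everything is
bit-reproducible from (config, seed) and emits the standard formats the
corresponding readers parse.

Default HT-SELEX flank/barcode constants follow the published ligand
design (33/34-bp Illumina primers around a barcoded 40-bp random insert).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .benchmarks import PeakSet, dinucleotide_shuffle
from .motifs import FrequencyMatrix, pfm_to_pwm
from .pbm import PbmArray
from .scanning import PBM_LINKER_PREFIX, ScanConfig, sum_occupancy_score

__all__ = [
    "GenomeConfig",
    "PeakConfig",
    "SelexConfig",
    "PbmConfig",
    "SimulationConfig",
    "SelexResult",
    "make_genome",
    "plant_peaks",
    "simulate_selex",
    "simulate_pbm",
    "make_decoys",
    "random_motif",
    "HTS_FLANK5",
    "HTS_FLANK3",
]

BASES = np.array(list("ACGT"))

#: Constant 5'/3' primers of the HT-SELEX ligand design; experiment
#: barcodes sit between the primer and the 40-bp random insert.
HTS_FLANK5 = "ACACTCTTTCCCTACACGACGCTCTTCCGATCT"
HTS_FLANK3 = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCAC"


@dataclass(frozen=True)
class GenomeConfig:
    n_autosomes: int = 4
    length: int = 100_000
    gc: float = 0.5
    order: int = 0  # 1 adds a first-order correlation so dinucleotide
    # backgrounds are non-trivially exercised
    correlation: float = 0.3  # order-1 same-base excess


@dataclass(frozen=True)
class PeakConfig:
    n: int = 300
    half_width: int = 150
    summit_jitter_sd: float = 0.0
    signal_noise_sd: float = 0.1
    # peak callers report only the strongest binding events: sample
    # n * detection_oversample candidate sites, keep the top n by signal
    detection_oversample: float = 1.5
    # minimum distance between planted summits, so flanking "shade"
    # windows of one peak never cover another peak's site
    min_spacing: int = 1000


@dataclass(frozen=True)
class SelexConfig:
    cycles: int = 3
    reads_per_cycle: int = 2000
    insert_length: int = 40
    flank5: str = HTS_FLANK5
    flank3: str = HTS_FLANK3
    barcode5: str = "TGACGC"
    barcode3: str = "GCAGTA"
    selection_strength: float = 1.0


@dataclass(frozen=True)
class PbmConfig:
    n_rows: int = 50
    n_cols: int = 50
    probe_length: int = 36
    trend_amplitude: float = 0.5
    noise_sd: float = 0.1
    n_arrays: int = 2
    # arrays of *other* experiments sharing the probe design: they carry
    # the same probes and trend but no signal for this motif, and provide
    # the cross-PBM per-probe mean/sd that Z-scoring needs; enough of them
    # that a bound probe is a genuine outlier (Z is bounded by (n-1)/sqrt(n)
    # when the pool is small)
    n_background_arrays: int = 30
    site_fraction: float = 0.1
    signal_gain: float = 30.0


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    genome: GenomeConfig = field(default_factory=GenomeConfig)
    peaks: PeakConfig = field(default_factory=PeakConfig)
    selex: SelexConfig = field(default_factory=SelexConfig)
    pbm: PbmConfig = field(default_factory=PbmConfig)

    def to_manifest(self) -> dict:
        return asdict(self)


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(BASES[rng.choice(4, size=length, p=p)])


def make_genome(config: GenomeConfig = GenomeConfig(), seed: int = 0) -> dict:
    """Synthetic multi-chromosome genome as {chr1..chrN: sequence}.

    Order 0 draws iid bases at the target GC; order 1 repeats the previous
    base with probability ``correlation`` (else draws iid), producing a
    non-uniform dinucleotide composition at the same marginal GC.
    """
    rng = np.random.default_rng(seed)
    gc = config.gc
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    genome = {}
    for i in range(1, config.n_autosomes + 1):
        if config.order == 0:
            seq = BASES[rng.choice(4, size=config.length, p=p)]
        else:
            codes = rng.choice(4, size=config.length, p=p)
            repeat = rng.random(config.length) < config.correlation
            for j in range(1, config.length):
                if repeat[j]:
                    codes[j] = codes[j - 1]
            seq = BASES[codes]
        genome[f"chr{i}"] = "".join(seq)
    return genome


def _sample_site(rng: np.random.Generator, freqs: FrequencyMatrix) -> str:
    mat = freqs.matrix
    return "".join(
        BASES[rng.choice(4, p=mat[j] / mat[j].sum())] for j in range(len(freqs))
    )


def plant_peaks(
    genome: dict,
    motifs: FrequencyMatrix | list[FrequencyMatrix],
    config: PeakConfig = PeakConfig(),
    mixture_weights: list[float] | None = None,
    seed: int = 0,
    avoid: PeakSet | None = None,
) -> tuple[PeakSet, dict]:
    """Plant one motif site per peak into a genome copy.

    Peaks are placed uniformly (non-overlapping) across chromosomes; the
    site word is sampled from the motif (a mixture over modes when several
    matrices are given) and written at the summit plus a Normal(0, jitter)
    offset.  The narrowPeak signal column is the site's log-odds score plus
    noise, so signal correlates with site strength.  Returns the PeakSet
    and the modified genome.
    """
    if isinstance(motifs, FrequencyMatrix):
        motifs = [motifs]
    k = len(motifs)
    weights = np.full(k, 1 / k) if mixture_weights is None else np.asarray(
        mixture_weights, dtype=float
    )
    weights = weights / weights.sum()
    pwms = [pfm_to_pwm(m) for m in motifs]
    rng = np.random.default_rng(seed)
    chroms = list(genome)
    lengths = np.array([len(genome[c]) for c in chroms], dtype=float)
    mutable = {c: bytearray(genome[c], "ascii") for c in chroms}
    probs = lengths / lengths.sum()
    summits_taken: dict[str, list[int]] = {c: [] for c in chroms}
    if avoid is not None:
        for rec in avoid.records.itertuples(index=False):
            if rec.chrom in summits_taken:
                summits_taken[rec.chrom].append(
                    int(rec.start + rec.summit_offset)
                )
    rows = []
    margin = config.half_width + 20
    n_candidates = max(config.n, int(round(config.n * config.detection_oversample)))
    for _ in range(n_candidates):
        for _attempt in range(200):
            ci = rng.choice(len(chroms), p=probs)
            chrom = chroms[ci]
            L = len(genome[chrom])
            if L < 2 * margin + 1:
                continue
            summit = int(rng.integers(margin, L - margin))
            start, end = summit - config.half_width, summit + config.half_width + 1
            if any(
                abs(summit - s) < config.min_spacing for s in summits_taken[chrom]
            ):
                continue
            summits_taken[chrom].append(summit)
            mode = int(rng.choice(k, p=weights))
            site = _sample_site(rng, motifs[mode])
            w = len(site)
            offset = (
                int(round(rng.normal(0, config.summit_jitter_sd)))
                if config.summit_jitter_sd > 0
                else 0
            )
            site_start = summit + offset - w // 2
            mutable[chrom][site_start : site_start + w] = site.encode("ascii")
            pwm = pwms[mode].matrix
            strength = float(
                sum(pwm[j, "ACGT".index(b)] for j, b in enumerate(site))
            )
            signal = strength + rng.normal(0, config.signal_noise_sd)
            rows.append(
                {
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "signal": signal,
                    "summit_offset": summit - start,
                    "mode": mode,
                }
            )
            break
    if config.n and not rows:
        raise ValueError("could not place any peak within the genome")
    columns = ["chrom", "start", "end", "signal", "summit_offset", "mode"]
    df = pd.DataFrame(rows, columns=columns)
    if len(df) > config.n:
        # detection: weak binding events exist in the genome but do not
        # yield called peaks
        df = (
            df.sort_values("signal", ascending=False, kind="mergesort")
            .head(config.n)
            .sort_values(["chrom", "start"], kind="mergesort")
            .reset_index(drop=True)
        )
    peaks = PeakSet(df)
    modified = {c: mutable[c].decode("ascii") for c in chroms}
    return peaks, modified


@dataclass
class SelexResult:
    """Reads per cycle (variable inserts) plus the constant flank context.

    ``flank5``/``flank3`` include the experiment barcodes, i.e. they are
    exactly the constant sequence adjacent to the random insert.
    """

    reads_by_cycle: dict[int, list[str]]
    flank5: str
    flank3: str

    def full_reads(self, cycle: int) -> list[str]:
        return [self.flank5 + r + self.flank3 for r in self.reads_by_cycle[cycle]]


def simulate_selex(
    motif: FrequencyMatrix,
    config: SelexConfig = SelexConfig(),
    seed: int = 0,
) -> SelexResult:
    """Multi-cycle SELEX enrichment of a random insert pool.

    Cycle 0 is an iid random pool; cycle k+1 resamples cycle k with
    probability proportional to (sum-occupancy of the flanked read) raised
    to ``selection_strength``, then re-synthesizes sequencing noise-free
    copies.  Strength 0 reduces to uniform resampling.
    """
    if config.cycles < 1:
        raise ValueError("need at least one cycle")
    rng = np.random.default_rng(seed)
    flank5 = config.flank5 + config.barcode5
    flank3 = config.barcode3 + config.flank3
    scan = ScanConfig()
    pool = [
        _random_seq(rng, config.insert_length, 0.5)
        for _ in range(config.reads_per_cycle)
    ]
    reads = {0: pool}
    for cycle in range(1, config.cycles + 1):
        if config.selection_strength == 0:
            probs = np.full(len(pool), 1 / len(pool))
        else:
            occ = np.array(
                [
                    sum_occupancy_score(motif, flank5 + r + flank3, scan)
                    for r in pool
                ]
            )
            weightsq = occ ** config.selection_strength
            total = weightsq.sum()
            probs = (
                weightsq / total
                if total > 0
                else np.full(len(pool), 1 / len(pool))
            )
        idx = rng.choice(len(pool), size=config.reads_per_cycle, p=probs)
        pool = [pool[i] for i in idx]
        reads[cycle] = pool
    return SelexResult(reads_by_cycle=reads, flank5=flank5, flank3=flank3)


def simulate_pbm(
    motif: FrequencyMatrix,
    config: PbmConfig = PbmConfig(),
    seed: int = 0,
) -> list[PbmArray]:
    """Replicate PBM arrays with planted sites and a spatial trend.

    A fixed fraction of probes carries a sampled motif site; probe
    intensity is baseline x trend(row, col) x (1 + gain x occupancy) x
    lognormal noise.  The smooth multiplicative trend (a diagonal gradient
    of the configured amplitude) is shared across replicates; noise is not.

    The first ``n_arrays`` returned arrays are replicates of the
    experiment; a further ``n_background_arrays`` (array ids ``bg_*``)
    share the probe design but carry no signal for this motif, standing in
    for the other experiments on the same design that per-probe Z-scoring
    normalizes against.
    """
    if config.n_rows < 50 or config.n_cols < 50:
        raise ValueError("PBM grid must be at least 50x50")
    rng = np.random.default_rng(seed)
    n = config.n_rows * config.n_cols
    scan = ScanConfig()
    sequences, occupancies = [], []
    w = len(motif)
    for i in range(n):
        seq = _random_seq(rng, config.probe_length, 0.5)
        if rng.random() < config.site_fraction:
            site = _sample_site(rng, motif)
            pos = int(rng.integers(0, config.probe_length - w + 1))
            seq = seq[:pos] + site + seq[pos + w :]
        sequences.append(seq)
        occupancies.append(
            sum_occupancy_score(motif, PBM_LINKER_PREFIX + seq, scan)
        )
    occupancies = np.array(occupancies)
    rows, cols = np.divmod(np.arange(n), config.n_cols)
    trend = 1.0 + config.trend_amplitude * (
        rows / max(config.n_rows - 1, 1) + cols / max(config.n_cols - 1, 1)
    ) / 2.0
    baseline = 100.0
    arrays = []
    probe_ids = [f"probe_{i:05d}" for i in range(n)]

    def build(array_id: str, with_signal: bool) -> PbmArray:
        noise = rng.lognormal(mean=0.0, sigma=config.noise_sd, size=n)
        signal = 1 + config.signal_gain * occupancies if with_signal else 1.0
        df = pd.DataFrame(
            {
                "probe_id": probe_ids,
                "row": rows,
                "col": cols,
                "sequence": sequences,
                "intensity": baseline * trend * signal * noise,
            }
        )
        return PbmArray(df, design_id="synthetic", array_id=array_id)

    for a in range(config.n_arrays):
        arrays.append(build(f"array_{a}", True))
    for a in range(config.n_background_arrays):
        arrays.append(build(f"bg_{a}", False))
    return arrays


def random_motif(
    length: int, rng: np.random.Generator, concentration: float = 0.5
) -> FrequencyMatrix:
    """Random motif with Dirichlet-distributed columns."""
    return FrequencyMatrix(rng.dirichlet(np.full(4, concentration), size=length))


def make_decoys(
    motif: FrequencyMatrix,
    n: int,
    kind: str = "column_shuffle",
    seed: int = 0,
) -> list[FrequencyMatrix]:
    """Decoy competitor motifs preserving the original's length.

    ``column_shuffle`` permutes the positions (exact column multiset,
    identical length/IC); ``dinuc_sample`` builds a near-one-hot motif from
    a shuffled consensus word; ``random`` draws fresh Dirichlet columns.
    """
    if n < 1:
        raise ValueError("need n >= 1 decoys")
    rng = np.random.default_rng(seed)
    w = len(motif)
    out = []
    for _ in range(n):
        if kind == "column_shuffle":
            for _attempt in range(100):
                perm = rng.permutation(w)
                decoy = FrequencyMatrix(motif.matrix[perm])
                if decoy != motif or w == 1:
                    break
            out.append(decoy)
        elif kind == "dinuc_sample":
            consensus = "".join("ACGT"[b] for b in motif.matrix.argmax(axis=1))
            # short words admit few Eulerian paths; retry so the decoy is
            # not the consensus itself
            for _attempt in range(100):
                word = dinucleotide_shuffle(consensus, rng)
                if word != consensus:
                    break
            mat = np.full((w, 4), 0.1)
            for j, b in enumerate(word):
                mat[j, "ACGT".index(b)] = 0.7
            out.append(FrequencyMatrix(mat))
        elif kind == "random":
            out.append(random_motif(w, rng))
        else:
            raise ValueError(f"unknown decoy kind {kind!r}")
    return out
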