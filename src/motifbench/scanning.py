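"""Score DNA sequences with motif matrices.

Two scoring modes are provided, matching the two matrix kinds:

* **sum-occupancy** — frequencies multiply within a window; window products
  are summed over all valid windows on both strands.  A soft multi-hit
  affinity proxy.
* **best hit** — log-odds weights add within a window; the maximal window
  score over both strands is reported with its position and strand.

Windows overlapping non-ACGT characters are skipped.  Coordinates are
0-based half-open; a reverse-strand hit at position ``i`` occupies forward
coordinates ``[i, i+w)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .motifs import FrequencyMatrix, WeightMatrix

__all__ = [
    "ScanConfig",
    "BestHit",
    "NO_HIT",
    "encode_sequence",
    "sum_occupancy_score",
    "best_hit",
    "best_hit_scores_batch",
    "scan_with_flanks",
]

_CODES = np.full(128, 4, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _CODES[ord(_b)] = _i
    _CODES[ord(_b.lower())] = _i


def encode_sequence(sequence: str) -> np.ndarray:
    """Encode A,C,G,T (case-insensitive) as 0..3; anything else as 4."""
    raw = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    return _CODES[raw]


@dataclass(frozen=True)
class ScanConfig:
    """Scanning options.

    ``epsilon`` regularizes zero frequencies for occupancy scoring as
    ``(f + eps) / (1 + 4 eps)`` — the uniform column is a fixed point, so
    uniform motifs score identically for any epsilon.
    """

    epsilon: float = 1e-4
    skip_invalid_windows: bool = True
    strands: str = "both"  # or "forward"

    def __post_init__(self):
        if not (0 <= self.epsilon < 0.25):
            raise ValueError("epsilon must lie in [0, 0.25)")
        if self.strands not in ("both", "forward"):
            raise ValueError("strands must be 'both' or 'forward'")


@dataclass(frozen=True)
class BestHit:
    score: float
    position: int
    strand: str  # '+' or '-'


#: Sentinel returned when a sequence has no valid (N-free) window.
NO_HIT = BestHit(score=float("-inf"), position=-1, strand=".")

DEFAULT_CONFIG = ScanConfig()


def _window_scores(mat: np.ndarray, codes: np.ndarray, multiply: bool) -> np.ndarray:
    """Scores of all windows on the forward strand; NaN where a window has N."""
    w = mat.shape[0]
    L = codes.size
    if L < w:
        return np.empty(0)
    wins = np.lib.stride_tricks.sliding_window_view(codes, w)  # (L-w+1, w)
    valid = ~np.any(wins == 4, axis=1)
    safe = np.where(wins == 4, 0, wins)
    vals = mat[np.arange(w), safe]  # (n_windows, w)
    scores = vals.prod(axis=1) if multiply else vals.sum(axis=1)
    scores = np.where(valid, scores, np.nan)
    return scores


def sum_occupancy_score(
    freqs: FrequencyMatrix, sequence: str, config: ScanConfig = DEFAULT_CONFIG
) -> float:
    """Sum over all valid windows (both strands) of the window frequency product.

    Sequences shorter than the motif score 0; windows containing N are
    skipped.
    """
    eps = config.epsilon
    mat = (freqs.matrix + eps) / (1.0 + 4.0 * eps)
    codes = encode_sequence(sequence)
    total = np.nansum(_window_scores(mat, codes, multiply=True))
    if config.strands == "both":
        rc = mat[::-1, ::-1]
        total += np.nansum(_window_scores(rc, codes, multiply=True))
    return float(total)


def best_hit(
    weights: WeightMatrix, sequence: str, config: ScanConfig = DEFAULT_CONFIG
) -> BestHit:
    """Maximal additive window score over both strands.

    Ties are broken by smallest position, then '+' strand.  Returns the
    :data:`NO_HIT` sentinel when no N-free window exists.
    """
    codes = encode_sequence(sequence)
    fwd = _window_scores(weights.matrix, codes, multiply=False)
    candidates = []
    if fwd.size and not np.all(np.isnan(fwd)):
        i = int(np.nanargmax(fwd))
        candidates.append((fwd[i], i, "+"))
    if config.strands == "both":
        rc = _window_scores(weights.matrix[::-1, ::-1], codes, multiply=False)
        if rc.size and not np.all(np.isnan(rc)):
            i = int(np.nanargmax(rc))
            candidates.append((rc[i], i, "-"))
    if not candidates:
        return NO_HIT
    # max score; ties -> smallest position, then '+' (sorts before '-')
    best = max(candidates, key=lambda c: (c[0], -c[1], c[2] == "+"))
    return BestHit(score=float(best[0]), position=int(best[1]), strand=best[2])


def best_hit_scores_batch(
    weights: WeightMatrix,
    sequences: list[str],
    config: ScanConfig = DEFAULT_CONFIG,
    no_hit_value: float | None = None,
) -> np.ndarray:
    """Best-hit scores for many sequences at once.

    Equal-length sequences are scored in a single vectorized pass.
    ``no_hit_value`` replaces the score for sequences without a valid
    window (default: the matrix minimum score minus 1, a value below any
    achievable score).
    """
    if no_hit_value is None:
        no_hit_value = weights.min_score - 1.0
    mat = weights.matrix
    w = mat.shape[0]
    rc = mat[::-1, ::-1]
    out = np.empty(len(sequences))
    by_len: dict[int, list[int]] = {}
    for idx, s in enumerate(sequences):
        by_len.setdefault(len(s), []).append(idx)
    for L, idxs in by_len.items():
        if L < w:
            out[idxs] = no_hit_value
            continue
        codes = np.empty((len(idxs), L), dtype=np.int8)
        for row, idx in enumerate(idxs):
            codes[row] = encode_sequence(sequences[idx])
        wins = np.lib.stride_tricks.sliding_window_view(codes, w, axis=1)
        invalid = np.any(wins == 4, axis=2)
        safe = np.where(wins == 4, 0, wins)
        scores = mat[np.arange(w), safe].sum(axis=2)
        scores[invalid] = -np.inf
        if config.strands == "both":
            rscores = rc[np.arange(w), safe].sum(axis=2)
            rscores[invalid] = -np.inf
            scores = np.maximum(scores, rscores)
        best = scores.max(axis=1)
        best[~np.isfinite(best)] = no_hit_value
        out[idxs] = best
    return out


#: First bases of the static PBM linker adjacent to the unique probe
#: sequence; the benchmarking protocol prepends exactly 6 of them.
PBM_LINKER_PREFIX = "GTCTGT"


def scan_with_flanks(
    matrix,
    read: str,
    flank5: str = "",
    flank3: str = "",
    scorer: str = "sum_occupancy",
    config: ScanConfig = DEFAULT_CONFIG,
):
    """Score ``flank5 + read + flank3`` with the chosen scorer.

    Synthetic-ligand platforms (HT-SELEX, SMiLE-Seq, PBM) expose constant
    primer/barcode/linker sequence next to the variable region, and binding
    sites may straddle the boundary; scanning the concatenation finds them.
    """
    for name, f in (("flank5", flank5), ("flank3", flank3)):
        if any(c not in "ACGTacgt" for c in f):
            raise ValueError(f"{name} must contain only A,C,G,T")
    seq = flank5 + read + flank3
    if scorer == "sum_occupancy":
        return sum_occupancy_score(matrix, seq, config)
    if scorer == "best_hit":
        return best_hit(matrix, seq, config)
    raise ValueError(f"unknown scorer {scorer!r}")
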