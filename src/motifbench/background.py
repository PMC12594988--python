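"""PWM score distributions under mono- and dinucleotide backgrounds.

The exact probability mass function of a single motif-length window score is
computed by position-wise dynamic programming on a discretized score grid
(scores multiplied by the discretization ``d`` and floored to integer bins,
the MACRO-APE ``-d`` convention).  On top of the PMF sit threshold <->
P-value conversion, sequence-level best-hit P-values and the asymptotic
pseudo-auROC.

The pseudo-auROC treats each positive's best hit score ``s`` as a test
statistic and converts it to a sequence-level P-value
``u = 1 - (1 - p_win)^(2(L-w+1))`` where ``p_win = P(window >= s)`` under a
background of the positives' own dinucleotide composition.  Under the null
(positives drawn from the background) ``u`` is approximately Uniform(0,1),
so ``1 - mean(u)`` estimates the area under the ROC curve whose FPR axis is
the analytic null exceedance probability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .motifs import WeightMatrix
from .scanning import ScanConfig, best_hit, encode_sequence, NO_HIT

__all__ = [
    "BackgroundModel",
    "ScoreDistribution",
    "UNIFORM_BACKGROUND",
    "fit_background",
    "score_distribution",
    "pvalue_of_score",
    "score_of_pvalue",
    "quantize_weights",
    "best_hit_pvalue",
    "pseudo_auroc",
]


@dataclass(frozen=True)
class BackgroundModel:
    """Mono- (order 0) or dinucleotide (order 1) sequence null model."""

    order: int
    base_freqs: np.ndarray  # stationary / mononucleotide frequencies
    transitions: np.ndarray | None = None  # 4x4 row-stochastic, order 1 only

    def __post_init__(self):
        if self.order not in (0, 1):
            raise ValueError("order must be 0 or 1")
        bf = np.asarray(self.base_freqs, dtype=float)
        object.__setattr__(self, "base_freqs", bf)
        if bf.shape != (4,) or np.any(bf < 0) or abs(bf.sum() - 1) > 1e-9:
            raise ValueError("base_freqs must be a probability 4-vector")
        if self.order == 1:
            tr = np.asarray(self.transitions, dtype=float)
            object.__setattr__(self, "transitions", tr)
            if tr.shape != (4, 4) or np.any(tr < 0):
                raise ValueError("transitions must be a nonnegative 4x4 matrix")
            if not np.allclose(tr.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError("transition rows must sum to 1")


UNIFORM_BACKGROUND = BackgroundModel(order=0, base_freqs=np.full(4, 0.25))


def fit_background(sequences: list[str], order: int = 1) -> BackgroundModel:
    """Fit base or dinucleotide-transition frequencies from pooled sequences.

    Order 1 uses add-one smoothing on the 4x4 dinucleotide count table; the
    stationary vector is the pooled mononucleotide frequency.
    """
    if not sequences:
        raise ValueError("need at least one sequence")
    base_counts = np.zeros(4)
    dinuc = np.zeros((4, 4))
    for seq in sequences:
        codes = encode_sequence(seq)
        valid = codes < 4
        base_counts += np.bincount(codes[valid], minlength=4)[:4]
        if order == 1 and codes.size > 1:
            a, b = codes[:-1], codes[1:]
            ok = (a < 4) & (b < 4)
            np.add.at(dinuc, (a[ok], b[ok]), 1)
    if base_counts.sum() == 0:
        raise ValueError("no valid (A,C,G,T) bases in input")
    base_freqs = base_counts / base_counts.sum()
    if order == 0:
        return BackgroundModel(order=0, base_freqs=base_freqs)
    dinuc += 1.0  # add-one smoothing
    transitions = dinuc / dinuc.sum(axis=1, keepdims=True)
    return BackgroundModel(order=1, base_freqs=base_freqs, transitions=transitions)


@dataclass(frozen=True)
class ScoreDistribution:
    """Discretized window-score PMF: bin ``b`` holds P(floor(score*d) == b)."""

    d: int
    min_bin: int
    pmf: np.ndarray  # pmf[i] = P(bin == min_bin + i)

    @property
    def grid_step(self) -> float:
        return 1.0 / self.d

    @property
    def max_bin(self) -> int:
        return self.min_bin + self.pmf.size - 1

    def sf(self) -> np.ndarray:
        """Survival function: sf[i] = P(bin >= min_bin + i)."""
        return self.pmf[::-1].cumsum()[::-1]


def discretize_cells(weights: WeightMatrix, d: int) -> np.ndarray:
    """Integer score bins per matrix cell: floor(w * d), jitter-guarded."""
    return np.floor(weights.matrix * d + 1e-9).astype(np.int64)


def quantize_weights(weights: WeightMatrix, d: int) -> WeightMatrix:
    """Weights snapped to the d-grid (cells / d).

    The grid defines the score scale of :class:`ScoreDistribution`; scanning
    with quantized weights makes observed scores land exactly on that grid,
    so threshold <-> P-value lookups are self-consistent.
    """
    return WeightMatrix(discretize_cells(weights, d) / d, weights.origin_count)


def score_distribution(
    weights: WeightMatrix, bg: BackgroundModel, d: int = 10
) -> ScoreDistribution:
    """Exact PMF of the discretized one-window score under ``bg``.

    Order 0 convolves per-position base distributions; order 1 keeps the
    previous base in the DP state.  Matches exhaustive word enumeration on
    the shared grid.
    """
    if d < 1:
        raise ValueError("discretization d must be >= 1")
    cells = discretize_cells(weights, d)
    w = cells.shape[0]
    col_min = cells.min(axis=1)
    col_max = cells.max(axis=1)
    # partial-score arrays are indexed relative to the running minimum, so
    # per-step shifts (cells[j, b] - col_min[j]) are always nonnegative
    if bg.order == 0:
        cur = np.zeros(col_max[0] - col_min[0] + 1)
        for b in range(4):
            cur[cells[0, b] - col_min[0]] += bg.base_freqs[b]
        for j in range(1, w):
            nxt = np.zeros(cur.size + col_max[j] - col_min[j])
            for b in range(4):
                shift = cells[j, b] - col_min[j]
                nxt[shift : shift + cur.size] += cur * bg.base_freqs[b]
            cur = nxt
        return ScoreDistribution(d=d, min_bin=int(col_min.sum()), pmf=cur)
    # order 1: state = (previous base, partial score)
    state = np.zeros((4, col_max[0] - col_min[0] + 1))
    for b in range(4):
        state[b, cells[0, b] - col_min[0]] += bg.base_freqs[b]
    for j in range(1, w):
        nxt = np.zeros((4, state.shape[1] + col_max[j] - col_min[j]))
        for b2 in range(4):
            shift = cells[j, b2] - col_min[j]
            mix = bg.transitions[:, b2] @ state
            nxt[b2, shift : shift + mix.size] += mix
        state = nxt
    return ScoreDistribution(d=d, min_bin=int(col_min.sum()), pmf=state.sum(axis=0))


def _threshold_bin(dist: ScoreDistribution, s: float) -> int:
    """Grid bin of a real score threshold (same floor convention as cells)."""
    return int(np.floor(s * dist.d + 1e-9))


def pvalue_of_score(dist: ScoreDistribution, s: float) -> float:
    """P(window score >= s) on the discretized grid."""
    t = _threshold_bin(dist, s)
    if t <= dist.min_bin:
        return 1.0
    if t > dist.max_bin:
        return 0.0
    return float(dist.sf()[t - dist.min_bin])


def score_of_pvalue(dist: ScoreDistribution, p: float) -> float:
    """Smallest grid threshold whose P-value is <= ``p``."""
    if not (0 < p <= 1):
        raise ValueError(f"p must lie in (0, 1], got {p}")
    sf = dist.sf()
    idx = np.nonzero(sf <= p + 1e-15)[0]
    if idx.size == 0:
        # no achievable threshold reaches p; one bin above the support
        return (dist.max_bin + 1) / dist.d
    return (dist.min_bin + int(idx[0])) / dist.d


def threshold_bin_of_pvalue(dist: ScoreDistribution, p: float) -> int:
    """Integer-bin version of :func:`score_of_pvalue` (used by word-set ops)."""
    return int(round(score_of_pvalue(dist, p) * dist.d))


def best_hit_pvalue(
    weights: WeightMatrix,
    bg: BackgroundModel,
    L: int,
    s: float,
    d: int = 100,
    dist: ScoreDistribution | None = None,
) -> float:
    """P(a random double-stranded length-L sequence has a window >= s).

    Uses the independence approximation across the ``2(L - w + 1)``
    window/strand combinations: ``1 - (1 - p_win)^(2(L-w+1))``.
    """
    w = len(weights)
    if L < w:
        raise ValueError(f"sequence length {L} shorter than motif length {w}")
    if dist is None:
        dist = score_distribution(weights, bg, d)
    p_win = pvalue_of_score(dist, s)
    n_windows = 2 * (L - w + 1)
    return float(-np.expm1(n_windows * np.log1p(-min(p_win, 1.0 - 1e-16))))


def pseudo_auroc(
    weights: WeightMatrix,
    positives: list[str],
    bg_source: str = "fit_from_positives",
    d: int = 100,
    bg: BackgroundModel | None = None,
) -> float:
    """Asymptotic pseudo-auROC of a PWM on a positive sequence set.

    Each positive contributes its best-hit sequence-level P-value ``u_i``
    against a background of the positives' own dinucleotide composition;
    the statistic is ``1 - mean(u_i)``, the ROC area when the FPR at
    P-value threshold alpha equals alpha.
    """
    if bg_source == "fit_from_positives":
        bg = fit_background(positives, order=1)
    elif bg is None:
        raise ValueError("provide bg when bg_source != 'fit_from_positives'")
    dist = score_distribution(weights, bg, d)
    w = len(weights)
    config = ScanConfig()
    scan_weights = quantize_weights(weights, d)
    us = []
    for seq in positives:
        hit = best_hit(scan_weights, seq, config)
        if hit is NO_HIT or len(seq) < w:
            continue
        us.append(best_hit_pvalue(weights, bg, len(seq), hit.score, d=d, dist=dist))
    if not us:
        raise ValueError("no positive sequence had a valid scanning window")
    return float(1.0 - np.mean(us))
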