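"""Artifact-motif filtering.

Recurrent platform artifacts (primer-derived patterns, lysate contaminants)
show up as near-identical motifs across unrelated proteins.  Two filters
remove them:

* **catalog filter** — motif-vs-artifact similarity measured as the Jaccard
  index of *high-scoring word sets*: each matrix admits the words scoring
  above its own P-value-5e-4 threshold (uniform background, discretization
  d=10); word sets are compared over the common span of every relative
  shift and orientation, overhang columns accepting any base, and the
  maximal Jaccard is taken.  Motifs reaching >= 0.15 against any catalog
  entry are removed.
* **flank filter** — motifs whose best hit inside the constant
  primer/barcode flanks is stronger than P = 1e-4 are removed (they match
  the ligand scaffold, not the protein), except for the less noisy
  GFP-tagged IVT design.

Word counting is exact: the pair-score dynamic program prunes states that
can no longer cross (or can no longer miss) either threshold, and counts
are integers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .background import (
    UNIFORM_BACKGROUND,
    BackgroundModel,
    pvalue_of_score,
    quantize_weights,
    score_distribution,
    discretize_cells,
)
from .motifs import MotifRecord, WeightMatrix
from .scanning import ScanConfig, best_hit, NO_HIT

__all__ = [
    "SimilarityResult",
    "jaccard_similarity",
    "filter_artifact_catalog",
    "flank_filter",
    "JACCARD_PVALUE",
    "JACCARD_D",
    "JACCARD_THRESHOLD",
    "FLANK_PVALUE",
]

JACCARD_PVALUE = 5e-4
JACCARD_D = 10
JACCARD_THRESHOLD = 0.15
FLANK_PVALUE = 1e-4


@dataclass(frozen=True)
class SimilarityResult:
    jaccard: float
    best_shift: int
    best_orientation: str  # "direct" or "reverse_complement"


def _threshold_bin(weights: WeightMatrix, p: float, d: int) -> tuple[int, int]:
    """(integer score-bin threshold, count of own-length passing words).

    When no threshold achieves P <= p (short matrices: even the consensus
    of a 5-mer has P ~ 1e-3 under the uniform null), the top score bin is
    used so the word set is never empty — sim(M, M) stays 1 regardless of
    motif length.
    """
    dist = score_distribution(weights, UNIFORM_BACKGROUND, d)
    sf = dist.sf()
    w = len(weights)
    # smallest bin whose exceedance probability is <= p
    idx = np.nonzero(sf <= p + 1e-15)[0]
    if idx.size == 0:
        nonzero = np.nonzero(dist.pmf > 0)[0]
        i = int(nonzero[-1])  # top achievable bin
    else:
        i = int(idx[0])
    return dist.min_bin + i, int(round(float(sf[i]) * 4**w))


_PASS = None  # sentinel partial-score marker: all completions pass


def _pair_word_count(
    cells_a: np.ndarray | None,
    cells_b: np.ndarray | None,
    span: int,
    a_start: int,
    b_start: int,
    t_a: int,
    t_b: int,
) -> int:
    """Count span-length words passing both thresholds (free columns
    outside a matrix accept any base with zero contribution)."""
    wa = 0 if cells_a is None else cells_a.shape[0]
    wb = 0 if cells_b is None else cells_b.shape[0]

    def contrib(cells, start, w, j):
        if cells is None or not (start <= j < start + w):
            return None  # free column
        return cells[j - start]

    # per-position contribution vectors (None = free)
    cols_a = [contrib(cells_a, a_start, wa, j) for j in range(span)]
    cols_b = [contrib(cells_b, b_start, wb, j) for j in range(span)]

    def remain(cols, agg):
        out = [0] * (span + 1)
        for j in range(span - 1, -1, -1):
            c = 0 if cols[j] is None else int(agg(cols[j]))
            out[j] = out[j + 1] + c
        return out

    max_rem_a = remain(cols_a, np.max)
    min_rem_a = remain(cols_a, np.min)
    max_rem_b = remain(cols_b, np.max)
    min_rem_b = remain(cols_b, np.min)

    states: dict[tuple, int] = {(0, 0): 1}
    for j in range(span):
        ca, cb = cols_a[j], cols_b[j]
        nxt: dict[tuple, int] = {}
        for (a, b), cnt in states.items():
            for base in range(4):
                na = a if a is _PASS or ca is None else a + int(ca[base])
                nb = b if b is _PASS or cb is None else b + int(cb[base])
                if na is not _PASS:
                    if na + max_rem_a[j + 1] < t_a:
                        continue  # can no longer pass A
                    if na + min_rem_a[j + 1] >= t_a:
                        na = _PASS
                if nb is not _PASS:
                    if nb + max_rem_b[j + 1] < t_b:
                        continue
                    if nb + min_rem_b[j + 1] >= t_b:
                        nb = _PASS
                key = (na, nb)
                nxt[key] = nxt.get(key, 0) + cnt
        states = nxt
    return sum(cnt for (a, b), cnt in states.items() if a is _PASS and b is _PASS)


def jaccard_similarity(
    m1: WeightMatrix,
    m2: WeightMatrix,
    p: float = JACCARD_PVALUE,
    d: int = JACCARD_D,
    max_shift: int | None = None,
) -> SimilarityResult:
    """Maximal Jaccard index of high-scoring word sets over all alignments.

    For each relative shift of ``m2`` against ``m1`` (overlap >= 1 column)
    and both orientations of ``m2``, both word sets are extended to the
    common span with free columns and |A∩B| / |A∪B| is computed exactly on
    the d-discretized score grid; the maximum is returned.
    """
    if not (0 < p < 1):
        raise ValueError(f"p must lie in (0, 1), got {p}")
    w1, w2 = len(m1), len(m2)
    t1, n1 = _threshold_bin(m1, p, d)
    t2, n2 = _threshold_bin(m2, p, d)
    cells1 = discretize_cells(m1, d)
    variants = {
        "direct": discretize_cells(m2, d),
        "reverse_complement": discretize_cells(m2, d)[::-1, ::-1],
    }
    best = SimilarityResult(jaccard=0.0, best_shift=0, best_orientation="direct")
    for orientation, cells2 in variants.items():
        for shift in range(-(w2 - 1), w1):
            if max_shift is not None and abs(shift) > max_shift:
                continue
            start = min(0, shift)
            span = max(w1, shift + w2) - start
            inter = _pair_word_count(
                cells1, cells2, span, -start, shift - start, t1, t2
            )
            na = n1 * 4 ** (span - w1)
            nb = n2 * 4 ** (span - w2)
            union = na + nb - inter
            jac = inter / union if union > 0 else 0.0
            if jac > best.jaccard + 1e-15:
                best = SimilarityResult(jac, shift, orientation)
    return best


def filter_artifact_catalog(
    motifs: list[MotifRecord],
    catalog: list[MotifRecord],
    threshold: float = JACCARD_THRESHOLD,
    p: float = JACCARD_PVALUE,
    d: int = JACCARD_D,
    exemptions: dict | None = None,
) -> dict:
    """Split motifs into kept and removed by catalog similarity.

    A motif is removed iff its maximal Jaccard similarity against any
    non-exempt catalog entry reaches ``threshold`` (inclusive).
    ``exemptions`` maps a motif's TF or motif_id to artifact ids that must
    not trigger removal (e.g., ETS patterns for ETS positive-control TFs).
    """
    if not catalog:
        raise ValueError("artifact catalog is empty")
    exemptions = exemptions or {}
    kept, removed = [], []
    cat_weights = [(c.motif_id, c.weights()) for c in catalog]
    for motif in motifs:
        exempt = set(exemptions.get(motif.tf, ())) | set(
            exemptions.get(motif.motif_id, ())
        )
        weights = motif.weights()
        hit = None
        for art_id, art_w in cat_weights:
            if art_id in exempt:
                continue
            sim = jaccard_similarity(weights, art_w, p=p, d=d)
            if sim.jaccard >= threshold and (hit is None or sim.jaccard > hit[1]):
                hit = (art_id, sim.jaccard)
        if hit is None:
            kept.append(motif)
        else:
            removed.append({"motif": motif, "artifact_id": hit[0], "jaccard": hit[1]})
    return {"kept": kept, "removed": removed}


def flank_filter(
    motif: WeightMatrix,
    flanks: list[str],
    p_threshold: float = FLANK_PVALUE,
    bg: BackgroundModel = UNIFORM_BACKGROUND,
    design: str = "",
    d: int = 100,
) -> dict:
    """Remove motifs that strongly match the constant ligand flanks.

    The motif's best hit over the flank sequences (joined with N runs so
    windows never straddle two flanks) is converted to a window P-value; a
    P-value below ``p_threshold`` means the motif matches the scaffold and
    is removed.  Datasets of the GFP-tagged IVT design are exempt.
    """
    for f in flanks:
        if any(c not in "ACGTacgt" for c in f):
            raise ValueError("flanks must contain only A,C,G,T")
    if design.upper() == "GFPIVT":
        return {"keep": True, "reason": "GFPIVT design exempt", "pvalue": None}
    spacer = "N" * len(motif)
    context = spacer.join(flanks)
    hit = best_hit(quantize_weights(motif, d), context, ScanConfig())
    if hit is NO_HIT:
        return {"keep": True, "reason": "no valid window in flanks", "pvalue": 1.0}
    dist = score_distribution(motif, bg, d)
    pval = pvalue_of_score(dist, hit.score)
    keep = pval >= p_threshold
    return {
        "keep": keep,
        "reason": "flank match" if not keep else "no strong flank match",
        "pvalue": pval,
        "hit": hit,
    }
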