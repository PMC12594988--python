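"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own algorithms: enumeration over all
words, O(n^2) pairwise counting, and direct step-curve construction.
"""

from __future__ import annotations

import numpy as np


def all_words(span: int) -> np.ndarray:
    """(4^span, span) array of all base-code words."""
    n = 4**span
    idx = np.arange(n)
    return np.stack([(idx // 4**j) % 4 for j in range(span - 1, -1, -1)], axis=1)


def enumerate_score_pmf(cells: np.ndarray, bg) -> dict[int, float]:
    """PMF of the discretized word score by full enumeration.

    ``cells`` is the (w, 4) integer-bin matrix; ``bg`` a BackgroundModel.
    """
    w = cells.shape[0]
    words = all_words(w)
    scores = np.zeros(len(words), dtype=np.int64)
    probs = np.ones(len(words))
    for j in range(w):
        scores += cells[j, words[:, j]]
        if bg.order == 0:
            probs *= bg.base_freqs[words[:, j]]
        elif j == 0:
            probs *= bg.base_freqs[words[:, 0]]
        else:
            probs *= bg.transitions[words[:, j - 1], words[:, j]]
    pmf: dict[int, float] = {}
    for s, p in zip(scores.tolist(), probs.tolist()):
        pmf[s] = pmf.get(s, 0.0) + p
    return pmf


def pairwise_auroc(pos, neg) -> float:
    """P(pos > neg) + 0.5 P(pos == neg) by explicit pair counting."""
    pos = np.asarray(pos, dtype=float)[:, None]
    neg = np.asarray(neg, dtype=float)[None, :]
    return float(((pos > neg).sum() + 0.5 * (pos == neg).sum()) / pos.size / neg.size)


def step_curve_auprc(pos, neg) -> float:
    """auPRC by walking distinct thresholds and summing precision * dR."""
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    thresholds = np.unique(np.concatenate([pos, neg]))[::-1]
    ap = 0.0
    prev_recall = 0.0
    for t in thresholds:
        tp = (pos >= t).sum()
        fp = (neg >= t).sum()
        recall = tp / pos.size
        precision = tp / (tp + fp)
        ap += precision * (recall - prev_recall)
        prev_recall = recall
    return float(ap)


def exhaustive_best_hit(weight_matrix: np.ndarray, seq: str):
    """Best window (score, position, strand) by explicit double loop."""
    code = {"A": 0, "C": 1, "G": 2, "T": 3}
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    w = weight_matrix.shape[0]
    best = None
    for i in range(len(seq) - w + 1):
        window = seq[i : i + w]
        if any(c not in code for c in window):
            continue
        for strand in ("+", "-"):
            target = (
                window
                if strand == "+"
                else "".join(comp[c] for c in reversed(window))
            )
            s = sum(weight_matrix[j, code[c]] for j, c in enumerate(target))
            key = (s, -i, strand == "+")
            if best is None or key > best[0]:
                best = (key, s, i, strand)
    if best is None:
        return None
    return best[1], best[2], best[3]


def word_set_jaccard(cells1, cells2, t1, t2, w1, w2) -> tuple[float, int, str]:
    """Maximal word-set Jaccard over shifts/orientations by enumeration.

    Only feasible for small spans; returns (jaccard, shift, orientation).
    """
    best = (0.0, 0, "direct")
    for orientation, c2 in (
        ("direct", cells2),
        ("reverse_complement", cells2[::-1, ::-1]),
    ):
        for shift in range(-(w2 - 1), w1):
            start = min(0, shift)
            span = max(w1, shift + w2) - start
            words = all_words(span)
            a0, b0 = -start, shift - start
            sa = np.zeros(len(words), dtype=np.int64)
            for j in range(w1):
                sa += cells1[j, words[:, a0 + j]]
            sb = np.zeros(len(words), dtype=np.int64)
            for j in range(w2):
                sb += c2[j, words[:, b0 + j]]
            in_a = sa >= t1
            in_b = sb >= t2
            union = (in_a | in_b).sum()
            if union:
                jac = (in_a & in_b).sum() / union
                if jac > best[0] + 1e-15:
                    best = (float(jac), shift, orientation)
    return best
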