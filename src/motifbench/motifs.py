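"""Motif matrix types, file I/O, the PFM->PWM log-odds transform, and
basic motif feature summaries.

Matrices are stored positions-as-rows with columns in A, C, G, T order.
Three kinds are distinguished:

* :class:`CountMatrix` — positional nucleotide counts (each row sums to the
  matrix ``total_count``).
* :class:`FrequencyMatrix` — positional frequencies (each row sums to 1);
  frequencies multiply across positions in sum-occupancy scoring.
* :class:`WeightMatrix` — additive log-odds weights produced by
  :func:`pfm_to_pwm`; weights add across positions in best-hit scoring.

The log-odds transform uses natural logarithms.  Downstream consumers are
rank- and threshold-based, so the base only rescales scores globally.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "CountMatrix",
    "FrequencyMatrix",
    "WeightMatrix",
    "MotifRecord",
    "MotifParseError",
    "read_motif",
    "write_motif",
    "pfm_to_pwm",
    "reverse_complement",
    "motif_summary",
]

ALPHABET = "ACGT"
_COMPLEMENT_ORDER = [3, 2, 1, 0]  # A<->T, C<->G under column reversal

PLATFORMS = ("CHS", "GHTS", "HTS", "SMS", "PBM")


class MotifParseError(ValueError):
    """Raised when a motif file cannot be parsed."""


def _as_matrix(positions: Iterable[Sequence[float]]) -> np.ndarray:
    mat = np.asarray(list(positions), dtype=float)
    if mat.ndim != 2 or mat.shape[1] != 4:
        raise ValueError(f"motif matrix must be Lx4, got shape {mat.shape}")
    if mat.shape[0] < 1:
        raise ValueError("motif matrix must have at least one position")
    return mat


@dataclass(frozen=True)
class CountMatrix:
    """Positional nucleotide counts; rows sum to ``total_count``."""

    matrix: np.ndarray
    total_count: float
    source_kind: str = "observed_counts"  # or "normalized_pfm_scaled"

    def __post_init__(self):
        mat = _as_matrix(self.matrix)
        object.__setattr__(self, "matrix", mat)
        if np.any(mat < 0):
            raise ValueError("counts must be nonnegative")
        sums = mat.sum(axis=1)
        if not np.allclose(sums, self.total_count, rtol=1e-3):
            raise ValueError(
                f"rows must sum to total_count={self.total_count}; got {sums}"
            )

    def __len__(self) -> int:
        return self.matrix.shape[0]

    def to_frequencies(self) -> "FrequencyMatrix":
        return FrequencyMatrix(self.matrix / self.matrix.sum(axis=1, keepdims=True))

    def __eq__(self, other):
        return (
            isinstance(other, CountMatrix)
            and np.array_equal(self.matrix, other.matrix)
            and self.total_count == other.total_count
        )


@dataclass(frozen=True)
class FrequencyMatrix:
    """Positional nucleotide frequencies; rows sum to 1."""

    matrix: np.ndarray

    def __post_init__(self):
        mat = _as_matrix(self.matrix)
        object.__setattr__(self, "matrix", mat)
        if np.any(mat < -1e-12) or np.any(mat > 1 + 1e-12):
            raise ValueError("frequencies must lie in [0, 1]")
        sums = mat.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError(f"rows must sum to 1; got {sums}")

    def __len__(self) -> int:
        return self.matrix.shape[0]

    def __eq__(self, other):
        return isinstance(other, FrequencyMatrix) and np.array_equal(
            self.matrix, other.matrix
        )


@dataclass(frozen=True)
class WeightMatrix:
    """Additive log-odds weights (natural log) plus the originating count."""

    matrix: np.ndarray
    origin_count: float = 100.0

    def __post_init__(self):
        mat = _as_matrix(self.matrix)
        object.__setattr__(self, "matrix", mat)
        if not np.all(np.isfinite(mat)):
            raise ValueError("weights must be finite")

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @property
    def max_score(self) -> float:
        return float(self.matrix.max(axis=1).sum())

    @property
    def min_score(self) -> float:
        return float(self.matrix.min(axis=1).sum())

    def __eq__(self, other):
        return isinstance(other, WeightMatrix) and np.array_equal(
            self.matrix, other.matrix
        )


@dataclass
class MotifRecord:
    """A motif matrix with benchmarking provenance.

    ``platform`` is the experimental platform the motif was discovered from
    (CHS = ChIP-Seq, GHTS = genomic HT-SELEX, HTS = HT-SELEX,
    SMS = SMiLE-Seq, PBM = protein-binding microarray); ``tool`` the
    discovery tool; ``rank_in_tool_output`` the motif's 1-based rank in that
    tool's output list.
    """

    motif_id: str
    matrix: CountMatrix | FrequencyMatrix
    tf: str = ""
    platform: str = "CHS"
    tool: str = ""
    rank_in_tool_output: int = 1

    def __post_init__(self):
        if self.platform not in PLATFORMS:
            raise ValueError(f"unknown platform {self.platform!r}")
        if self.rank_in_tool_output < 1:
            raise ValueError("rank_in_tool_output must be >= 1")

    def frequencies(self) -> FrequencyMatrix:
        if isinstance(self.matrix, FrequencyMatrix):
            return self.matrix
        return self.matrix.to_frequencies()

    def weights(self, count: float | None = None) -> WeightMatrix:
        """Log-odds weights; observed-count matrices use their true total."""
        if count is None:
            if isinstance(self.matrix, CountMatrix) and (
                self.matrix.source_kind == "observed_counts"
            ):
                count = self.matrix.total_count
            else:
                count = 100.0
        return pfm_to_pwm(self.frequencies(), count)


# ---------------------------------------------------------------------------
# transforms


def pfm_to_pwm(freqs: FrequencyMatrix, count: float = 100.0) -> WeightMatrix:
    """Convert positional frequencies to log-odds weights.

    With ``count_ij = count * freq_ij`` and
    ``pseudocount = log(max(2, count))`` each weight is

        pwm_ij = log((count_ij + 0.25 * pseudocount)
                     / (0.25 * (count + pseudocount)))

    Logs are natural.  The uniform column maps to zero weights for any
    ``count``; the transform is strictly increasing in ``freq_ij``.
    """
    if count <= 0:
        raise ValueError(f"count must be positive, got {count}")
    pseudocount = math.log(max(2.0, count))
    counts = count * freqs.matrix
    weights = np.log((counts + 0.25 * pseudocount) / (0.25 * (count + pseudocount)))
    return WeightMatrix(weights, origin_count=count)


def reverse_complement(matrix):
    """Reverse-complement a motif matrix (reverse positions, swap A<->T, C<->G)."""
    rc = matrix.matrix[::-1, _COMPLEMENT_ORDER].copy()
    if isinstance(matrix, CountMatrix):
        return CountMatrix(rc, matrix.total_count, matrix.source_kind)
    if isinstance(matrix, FrequencyMatrix):
        return FrequencyMatrix(rc)
    if isinstance(matrix, WeightMatrix):
        return WeightMatrix(rc, matrix.origin_count)
    raise TypeError(f"unsupported matrix type {type(matrix)!r}")


def motif_summary(freqs: FrequencyMatrix) -> dict:
    """Length, GC fraction and information content (bits) of a motif.

    Per-position IC is ``2 + sum_b f_b log2 f_b`` with ``0 log 0 = 0``;
    GC fraction is the mean over positions of ``f_C + f_G``.
    """
    mat = freqs.matrix
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(mat > 0, mat * np.log2(np.where(mat > 0, mat, 1.0)), 0.0)
    ic = 2.0 + plogp.sum(axis=1)
    gc = float(mat[:, 1:3].sum(axis=1).mean())
    return {
        "length": mat.shape[0],
        "gc_fraction": gc,
        "ic_per_position": ic,
        "ic_total": float(ic.sum()),
    }


# ---------------------------------------------------------------------------
# file I/O

_DIALECTS = ("plain", "jaspar", "meme_minimal")


def _classify(mat: np.ndarray) -> CountMatrix | FrequencyMatrix:
    """Rows summing to 1 within 1e-3 are frequencies, otherwise counts.

    All-integer matrices are counts even when rows sum to 1 (a one-hot
    alignment of a single word); the two readings give identical
    frequencies there anyway.
    """
    sums = mat.sum(axis=1)
    integral = np.allclose(mat, np.round(mat), atol=1e-9)
    if np.allclose(sums, 1.0, atol=1e-3) and not integral:
        return FrequencyMatrix(mat / mat.sum(axis=1, keepdims=True))
    total = float(np.median(sums))
    return CountMatrix(mat, total_count=total)


def _parse_plain(text: str, path: str) -> tuple[str | None, np.ndarray]:
    motif_id = None
    rows = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            motif_id = line[1:].split()[0] if len(line) > 1 else None
            continue
        fields = line.split()
        if len(fields) != 4:
            raise MotifParseError(
                f"{path}:{lineno}: expected 4 fields (A C G T), got {len(fields)}"
            )
        try:
            row = [float(f) for f in fields]
        except ValueError as exc:
            raise MotifParseError(f"{path}:{lineno}: non-numeric entry") from exc
        if any(v < 0 for v in row):
            raise MotifParseError(f"{path}:{lineno}: negative matrix entry")
        rows.append(row)
    if not rows:
        raise MotifParseError(f"{path}: no matrix rows found")
    return motif_id, np.array(rows)


def _parse_jaspar(text: str, path: str) -> tuple[str | None, np.ndarray]:
    """JASPAR 2020 style: '>ID name' then four 'A  [ 1 2 3 ]' rows."""
    motif_id = None
    per_base: dict[str, list[float]] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            motif_id = line[1:].split()[0] if len(line) > 1 else None
            continue
        m = re.match(r"^([ACGTacgt])\s*\[?\s*([-0-9.eE+\s]+?)\s*\]?\s*$", line)
        if not m:
            raise MotifParseError(f"{path}:{lineno}: unrecognized JASPAR row")
        base = m.group(1).upper()
        vals = [float(v) for v in m.group(2).split()]
        if any(v < 0 for v in vals):
            raise MotifParseError(f"{path}:{lineno}: negative matrix entry")
        per_base[base] = vals
    if set(per_base) != set(ALPHABET):
        raise MotifParseError(f"{path}: JASPAR record must have A,C,G,T rows")
    lengths = {len(v) for v in per_base.values()}
    if len(lengths) != 1:
        raise MotifParseError(f"{path}: unequal row lengths {lengths}")
    return motif_id, np.array([per_base[b] for b in ALPHABET]).T


def _parse_meme_minimal(text: str, path: str) -> tuple[str | None, np.ndarray]:
    motif_id = None
    rows: list[list[float]] = []
    in_matrix = False
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if stripped.startswith("MOTIF"):
            parts = stripped.split()
            motif_id = parts[1] if len(parts) > 1 else None
            in_matrix = False
            continue
        if stripped.startswith("letter-probability matrix"):
            in_matrix = True
            continue
        if in_matrix and stripped:
            fields = stripped.split()
            if len(fields) != 4:
                if rows:
                    break
                raise MotifParseError(
                    f"{path}:{lineno}: expected 4 fields, got {len(fields)}"
                )
            rows.append([float(f) for f in fields])
        elif in_matrix and not stripped and rows:
            break
    if not rows:
        raise MotifParseError(f"{path}: no letter-probability matrix found")
    mat = np.array(rows)
    if np.any(mat < 0):
        raise MotifParseError(f"{path}: negative matrix entry")
    return motif_id, mat


def read_motif(path, dialect: str = "plain", **record_kwargs) -> MotifRecord:
    """Read a motif file into a :class:`MotifRecord`.

    Counts vs frequencies are auto-detected: rows summing to 1 within 1e-3
    yield a :class:`FrequencyMatrix`, anything else a :class:`CountMatrix`.
    """
    if dialect not in _DIALECTS:
        raise ValueError(f"unsupported dialect {dialect!r}; choose from {_DIALECTS}")
    path = Path(path)
    text = path.read_text()
    parser = {
        "plain": _parse_plain,
        "jaspar": _parse_jaspar,
        "meme_minimal": _parse_meme_minimal,
    }[dialect]
    motif_id, mat = parser(text, str(path))
    matrix = _classify(mat)
    record_kwargs.setdefault("motif_id", motif_id or path.stem)
    return MotifRecord(matrix=matrix, **record_kwargs)


def write_motif(record: MotifRecord, path, dialect: str = "plain") -> None:
    """Write a motif to disk; values keep 6 significant digits."""
    path = Path(path)
    mat = record.matrix.matrix
    if dialect == "plain":
        lines = [f">{record.motif_id}"]
        lines += [" ".join(f"{v:.6g}" for v in row) for row in mat]
    elif dialect == "jaspar":
        lines = [f">{record.motif_id} {record.tf or record.motif_id}"]
        for i, base in enumerate(ALPHABET):
            vals = "  ".join(f"{v:.6g}" for v in mat[:, i])
            lines.append(f"{base}  [ {vals} ]")
    elif dialect == "meme_minimal":
        freqs = record.frequencies().matrix
        lines = [
            "MEME version 4",
            "",
            "ALPHABET= ACGT",
            "",
            f"MOTIF {record.motif_id}",
            f"letter-probability matrix: alength= 4 w= {len(freqs)}",
        ]
        lines += ["  " + "  ".join(f"{v:.6f}" for v in row) for row in freqs]
    else:
        raise ValueError(f"unsupported dialect {dialect!r}")
    path.write_text("\n".join(lines) + "\n")
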