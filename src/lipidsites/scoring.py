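"""Peptide similarity and weighted group scoring.

Two primitives drive both clustering and prediction:

* a peptide-peptide similarity ``S(A, B)``: the fraction of window positions
  carrying a conserved substitution (a residue pair with a positive BLOSUM62
  score), with distance ``D = 1/S`` (``inf`` when ``S = 0``);
* a weighted group score: the average, over a group's positive training
  peptides, of the position-weighted sum of substitution scores between the
  query window and the training window.

The substitution matrix is BLOSUM62 plus a trainable symmetric delta
``dS(a, b)`` over the 210 unordered standard-residue pairs; position weights
are ``1 + dw_i``, clamped at zero. Terminal padding ``*`` scores 0 against
everything so truncated windows are neither rewarded nor penalised, and the
ambiguous residue ``X`` scores via the BLOSUM62 X row.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from Bio.Align import substitution_matrices

from .seqio import AA20, ALPHABET, PAD, PeptideWindow

N_SYMBOLS = len(ALPHABET)  # 22: 20 standard + X + *
_INDEX = {a: i for i, a in enumerate(ALPHABET)}
PAD_INDEX = _INDEX[PAD]

#: The 210 unordered pairs of standard residues, in a fixed canonical order.
STANDARD_PAIRS: tuple[tuple[str, str], ...] = tuple(
    (AA20[i], AA20[j]) for i in range(20) for j in range(i, 20)
)
N_PAIRS = len(STANDARD_PAIRS)  # 210


def _blosum62_base() -> np.ndarray:
    """BLOSUM62 over our 22-symbol alphabet; any pair involving '*' is 0."""
    b = substitution_matrices.load("BLOSUM62")
    m = np.zeros((N_SYMBOLS, N_SYMBOLS))
    for i, a in enumerate(ALPHABET[:-1]):  # skip '*'
        for j, c in enumerate(ALPHABET[:-1]):
            m[i, j] = b[a, c]
    return m


_BLOSUM62 = _blosum62_base()
_BLOSUM62.setflags(write=False)


def encode(peptide: str | PeptideWindow) -> np.ndarray:
    """Encode a peptide string into integer symbol codes."""
    s = peptide.residues if isinstance(peptide, PeptideWindow) else peptide
    try:
        return np.fromiter((_INDEX[a] for a in s), dtype=np.intp, count=len(s))
    except KeyError as exc:
        raise ValueError(f"symbol {exc.args[0]!r} not in alphabet {ALPHABET!r}") from exc


def encode_many(peptides: Sequence[str | PeptideWindow]) -> np.ndarray:
    """Encode equal-length peptides into an (n, L) code matrix."""
    rows = [encode(p) for p in peptides]
    if len({r.size for r in rows}) > 1:
        raise ValueError("peptides must share one window length")
    return np.vstack(rows)


class SubstitutionMatrix:
    """BLOSUM62 base plus a symmetric trainable delta.

    ``entries(a, b)`` returns base + delta. Deltas live only on standard
    residue pairs; '*' pairs are pinned to 0 and 'X' keeps its BLOSUM62 row.
    """

    def __init__(self, deltas: np.ndarray | None = None):
        # deltas stored dense 22x22, symmetric, zero outside the 20x20 block
        if deltas is None:
            self._deltas = np.zeros((N_SYMBOLS, N_SYMBOLS))
        else:
            deltas = np.asarray(deltas, dtype=float)
            if deltas.shape != (N_SYMBOLS, N_SYMBOLS):
                raise ValueError(f"delta matrix must be {N_SYMBOLS}x{N_SYMBOLS}")
            if not np.allclose(deltas, deltas.T):
                raise ValueError("delta matrix must be symmetric")
            self._deltas = deltas.copy()
            self._deltas[20:, :] = 0.0
            self._deltas[:, 20:] = 0.0

    @classmethod
    def from_pair_deltas(cls, pair_deltas: np.ndarray) -> "SubstitutionMatrix":
        """Build from a length-210 vector over :data:`STANDARD_PAIRS`."""
        pair_deltas = np.asarray(pair_deltas, dtype=float)
        if pair_deltas.shape != (N_PAIRS,):
            raise ValueError(f"expected {N_PAIRS} pair deltas")
        d = np.zeros((N_SYMBOLS, N_SYMBOLS))
        for (a, b), v in zip(STANDARD_PAIRS, pair_deltas):
            i, j = _INDEX[a], _INDEX[b]
            d[i, j] = v
            d[j, i] = v
        return cls(d)

    def pair_deltas(self) -> np.ndarray:
        """The length-210 delta vector over :data:`STANDARD_PAIRS`."""
        return np.array([self._deltas[_INDEX[a], _INDEX[b]] for a, b in STANDARD_PAIRS])

    def as_array(self) -> np.ndarray:
        """Dense (22, 22) score array, base + deltas."""
        return _BLOSUM62 + self._deltas

    def entries(self, a: str, b: str) -> float:
        if a not in _INDEX or b not in _INDEX:
            bad = a if a not in _INDEX else b
            raise ValueError(f"unknown symbol {bad!r}")
        return float(self.as_array()[_INDEX[a], _INDEX[b]])

    @property
    def is_base(self) -> bool:
        return bool(np.all(self._deltas == 0))

    def to_text(self) -> str:
        """BLOSUM-style labelled square table of base + deltas."""
        arr = self.as_array()
        lines = ["   " + " ".join(f"{a:>6}" for a in ALPHABET)]
        for i, a in enumerate(ALPHABET):
            lines.append(f"{a:>2} " + " ".join(f"{arr[i, j]:6.2f}" for j in range(N_SYMBOLS)))
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "SubstitutionMatrix":
        lines = [ln for ln in text.splitlines() if ln.strip()]
        labels = lines[0].split()
        if labels != list(ALPHABET):
            raise ValueError("matrix table labels do not match the alphabet")
        arr = np.zeros((N_SYMBOLS, N_SYMBOLS))
        for ln in lines[1:]:
            parts = ln.split()
            i = _INDEX[parts[0]]
            arr[i, :] = [float(x) for x in parts[1:]]
        return cls(arr - _BLOSUM62)


@dataclass
class WeightVector:
    """Per-position scoring weights ``w_i = max(0, 1 + dw_i)``."""

    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(self.weights < 0):
            raise ValueError("weights must be non-negative")

    @classmethod
    def ones(cls, length: int) -> "WeightVector":
        return cls(np.ones(length))

    @classmethod
    def from_deltas(cls, deltas: np.ndarray) -> "WeightVector":
        return cls(np.clip(1.0 + np.asarray(deltas, dtype=float), 0.0, None))

    def __len__(self) -> int:
        return len(self.weights)


@dataclass(frozen=True)
class PairwiseSimilarity:
    """S(A, B) in [0, 1] and its distance D = 1/S (inf when S = 0)."""

    s: float
    d: float


def is_conserved(a: str, b: str, matrix: SubstitutionMatrix | None = None) -> bool:
    """True iff the substitution score of (a, b) is strictly positive."""
    matrix = matrix or SubstitutionMatrix()
    return matrix.entries(a, b) > 0


def conservation_table(matrix: SubstitutionMatrix | None = None) -> np.ndarray:
    """Boolean (22, 22) table of conserved substitutions."""
    matrix = matrix or SubstitutionMatrix()
    return matrix.as_array() > 0


def similarity(
    a: PeptideWindow | str,
    b: PeptideWindow | str,
    matrix: SubstitutionMatrix | None = None,
) -> PairwiseSimilarity:
    """Fraction of window positions with a conserved substitution.

    Normalised by the full window length, so '*'-padded positions (which are
    never conserved) count against the similarity of truncated windows.
    """
    ca, cb = encode(a), encode(b)
    if ca.size != cb.size:
        raise ValueError(f"window length mismatch: {ca.size} vs {cb.size}")
    cons = conservation_table(matrix)
    s = float(np.mean(cons[ca, cb]))
    d = 1.0 / s if s > 0 else math.inf
    return PairwiseSimilarity(s=s, d=d)


def pairwise_similarity_matrix(
    peptides: Sequence[PeptideWindow | str],
    matrix: SubstitutionMatrix | None = None,
) -> np.ndarray:
    """Dense (n, n) matrix of S(A, B) over a peptide list."""
    codes = encode_many(peptides)
    cons = conservation_table(matrix)
    n = codes.shape[0]
    sim = np.empty((n, n))
    for i in range(n):
        sim[i] = cons[codes[i][None, :], codes].mean(axis=1)
    return sim


def peptide_score(query: PeptideWindow | str, group) -> float:
    """Weighted group score of a query window against a trained group.

    The score is the mean over the group's positive peptides of the
    position-weighted substitution scores (weights and matrix taken from the
    group). Linear in the weight vector; invariant to peptide order.
    """
    positives = group.positives
    if not positives:
        raise ValueError("cannot score against an empty group")
    q = encode(query)
    codes = encode_many(positives)
    if codes.shape[1] != q.size:
        raise ValueError(
            f"query length {q.size} != group window length {codes.shape[1]}"
        )
    arr = group.matrix.as_array()
    w = group.weights.weights
    per_pep = (arr[q[None, :], codes] * w[None, :]).sum(axis=1)
    return float(per_pep.mean())
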