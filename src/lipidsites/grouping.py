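"""Site grouping: motif classes and similarity-based k-means.

One modification type can be written by enzymes that recognise different
motifs, so positive sites are split into groups and each group gets its own
scoring model:

* N-myristoylation — consensus (N-terminal ``MGXXXS/T``) vs non-consensus;
* S-farnesylation — consensus (C-terminal ``CAAX``) vs non-consensus;
* S-geranylgeranylation — ``CAAX``, terminal ``CC``/``CXC``, non-consensus;
* S-palmitoylation — no published consensus; peptides are clustered by
  k-means under the distance ``D(A, B) = 1/S(A, B)``, with each cluster's
  centroid being the member with the highest average similarity to its
  cluster (a medoid), and three clusters by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .seqio import PeptideWindow, Protein
from .scoring import (
    SubstitutionMatrix,
    WeightVector,
    pairwise_similarity_matrix,
)

logger = logging.getLogger(__name__)

#: Aliphatic residues for the optional strict CAAX filter (off by default).
ALIPHATIC = frozenset("AVLICMF")


@dataclass
class GroupModel:
    """One group's scoring model: positive peptides, weights, matrix,
    stringency thresholds."""

    group_id: str
    mod_type: str
    kind: str  # consensus | nonconsensus | kmeans-cluster
    positives: list[PeptideWindow]
    weights: WeightVector
    matrix: SubstitutionMatrix
    thresholds: dict[str, float] = field(default_factory=dict)
    #: indices into the training set's positive list, for LOO bookkeeping
    member_indices: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.positives:
            raise ValueError(f"group {self.group_id!r} has no positive peptides")
        lengths = {len(p) for p in self.positives}
        if len(lengths) > 1:
            raise ValueError(f"group {self.group_id!r}: mixed window lengths {lengths}")
        if len(self.weights) != lengths.pop():
            raise ValueError(f"group {self.group_id!r}: weight length mismatch")


def classify_myristoylation(protein: Protein, position: int) -> str:
    """Consensus iff the glycine is position 2 of an N-terminal MGXXXS/T."""
    if protein.residue(position) != "G":
        raise ValueError(
            f"{protein.id} position {position} is not glycine"
        )
    seq = protein.sequence
    if (
        position == 2
        and seq.startswith("MG")
        and len(seq) >= 6
        and seq[5] in ("S", "T")
    ):
        return "consensus"
    return "nonconsensus"


def classify_farnesylation(
    protein: Protein, position: int, aliphatic_filter: bool = False
) -> str:
    """Consensus iff the cysteine heads a C-terminal CAAX box.

    The positional rule (Cys at the 4th-to-last residue) is the default; the
    optional filter additionally requires the two A positions to be aliphatic.
    """
    if protein.residue(position) != "C":
        raise ValueError(f"{protein.id} position {position} is not cysteine")
    seq = protein.sequence
    if position == len(seq) - 3:
        if not aliphatic_filter:
            return "consensus"
        a1, a2 = seq[position], seq[position + 1]
        if a1 in ALIPHATIC and a2 in ALIPHATIC:
            return "consensus"
    return "nonconsensus"


def classify_geranylgeranylation(
    protein: Protein, position: int, aliphatic_filter: bool = False
) -> str:
    """CAAX, terminal CC/CXC, or non-consensus."""
    if protein.residue(position) != "C":
        raise ValueError(f"{protein.id} position {position} is not cysteine")
    seq = protein.sequence
    L = len(seq)
    if position == L - 3:
        if not aliphatic_filter or (seq[position] in ALIPHATIC and seq[position + 1] in ALIPHATIC):
            return "consensus_caax"
    # terminal CC: positions L-1 and L both C
    if L >= 2 and seq[-2] == "C" and seq[-1] == "C" and position in (L - 1, L):
        return "consensus_cc_cxc"
    # terminal CXC: positions L-2 and L both C
    if L >= 3 and seq[-3] == "C" and seq[-1] == "C" and position in (L - 2, L):
        return "consensus_cc_cxc"
    return "nonconsensus"


@dataclass
class ClusterAssignment:
    """k-means result: labels per peptide, medoid indices, mean
    intra-cluster similarity (the maximised objective)."""

    labels: np.ndarray
    centroids: list[int]
    mean_intra_similarity: float


def _objective(sim: np.ndarray, labels: np.ndarray, k: int) -> float:
    """Mean over peptides of average similarity to same-cluster co-members.

    Singleton clusters contribute 1.0 for their lone member (a peptide is
    perfectly similar to itself).
    """
    total = 0.0
    n = labels.size
    for c in range(k):
        idx = np.flatnonzero(labels == c)
        if idx.size == 0:
            continue
        if idx.size == 1:
            total += 1.0
            continue
        block = sim[np.ix_(idx, idx)]
        # exclude self-similarity from the average
        total += ((block.sum(axis=1) - np.diag(block)) / (idx.size - 1)).sum()
    return total / n


def kmeans_cluster(
    peptides: Sequence[PeptideWindow | str],
    k: int,
    restarts: int = 5,
    seed: int = 0,
    matrix: SubstitutionMatrix | None = None,
    max_iter: int = 100,
) -> ClusterAssignment:
    """Cluster peptides under D = 1/S with medoid centroid updates.

    Assignment goes to the centroid with the highest similarity (equivalently
    the shortest distance); ties break toward the lowest cluster id. The
    centroid update picks the member with the highest average similarity to
    its cluster, ties toward the lowest peptide index. Best of ``restarts``
    seeded initialisations; deterministic given ``seed``.
    """
    n = len(peptides)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k = {k} exceeds number of peptides ({n})")
    sim = pairwise_similarity_matrix(peptides, matrix)
    rng = np.random.default_rng(seed)

    best: ClusterAssignment | None = None
    for _ in range(restarts):
        centroids = list(rng.choice(n, size=k, replace=False))
        labels = np.full(n, -1, dtype=np.intp)
        for _ in range(max_iter):
            # assignment: highest similarity to a centroid, ties -> lowest id
            simc = sim[:, centroids]  # (n, k)
            new_labels = np.argmax(simc, axis=1).astype(np.intp)
            orphan = simc.max(axis=1) == 0.0
            if np.any(orphan):
                # zero similarity to every centroid: park in cluster 0
                logger.info(
                    "%d peptide(s) with zero similarity to all centroids "
                    "assigned to cluster 0", int(orphan.sum())
                )
                new_labels[orphan] = 0
            # keep clusters non-empty: give an empty cluster its own centroid back
            for c in range(k):
                if not np.any(new_labels == c):
                    new_labels[centroids[c]] = c
            if np.array_equal(new_labels, labels):
                break
            labels = new_labels
            # medoid update
            for c in range(k):
                idx = np.flatnonzero(labels == c)
                avg = sim[np.ix_(idx, idx)].mean(axis=1)
                centroids[c] = int(idx[int(np.argmax(avg))])
        obj = _objective(sim, labels, k)
        if best is None or obj > best.mean_intra_similarity:
            best = ClusterAssignment(
                labels=labels.copy(),
                centroids=list(centroids),
                mean_intra_similarity=obj,
            )
    assert best is not None
    return best


def classify_site(protein: Protein, position: int, mod_type: str) -> str:
    """Motif-based group label for one site (PALM has no motif rule)."""
    if mod_type == "MYR":
        return classify_myristoylation(protein, position)
    if mod_type == "FARN":
        return classify_farnesylation(protein, position)
    if mod_type == "GERA":
        return classify_geranylgeranylation(protein, position)
    raise ValueError(f"no motif classification for mod_type {mod_type!r}")
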