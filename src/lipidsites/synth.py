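"""Seeded synthetic sequence data with planted lipid-modification motifs.

The generator emulates the sequence features each modification type is
recognised by, so the whole pipeline — grouping, training, evaluation and
the crosstalk statistics — is testable without any external dataset:

* **MYR** proteins start ``MG`` with the glycine annotated, and carry S/T at
  position 6 with probability ``signal_strength`` (the MGXXXS/T consensus);
* **FARN** proteins end in a CAAX box (annotated cysteine 4th from the end)
  whose two A positions are aliphatic with probability ``signal_strength``;
* **GERA** proteins cycle through CAAX, terminal CC and CXC termini;
* **PALM** proteins embed one of three planted 7-residue family consensus
  patterns around an internal cysteine, the three families drawn from
  mutually non-conserved residues so the clustering stage has a recoverable
  structure.

Prenylated termini additionally carry an upstream polybasic stretch (K/R
with probability ``signal_strength``), mimicking the membrane-targeting
context of prenylation substrates. Every protein also contains decoy
candidate residues, which become the negative set.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .coregulation import AnnotatedLibrary
from .seqio import AA20, MOD_TYPES, ModSite, Protein

#: Swiss-Prot-like background composition (fractions over the 20 residues).
SWISSPROT_COMPOSITION: dict[str, float] = {
    "A": 0.0825, "R": 0.0553, "N": 0.0406, "D": 0.0545, "C": 0.0138,
    "Q": 0.0393, "E": 0.0675, "G": 0.0707, "H": 0.0227, "I": 0.0596,
    "L": 0.0966, "K": 0.0584, "M": 0.0242, "F": 0.0386, "P": 0.0470,
    "S": 0.0656, "T": 0.0534, "W": 0.0109, "Y": 0.0292, "V": 0.0687,
}

#: Three palmitoylation family consensus 7-mers (positions -3..+3 around the
#: cysteine). Residues at matching positions are pairwise non-conserved
#: across families (negative BLOSUM62 scores), so families are separable.
PALM_FAMILIES: tuple[str, ...] = ("LKLCLKL", "DWDCDWD", "GPGCGPG")

ALIPHATIC_CHOICES = "AVLI"
ST = "ST"
NON_ST = "".join(a for a in AA20 if a not in ST)
BASIC = "KR"


@dataclass(frozen=True)
class SynthSpec:
    """Conditions for one per-type synthetic dataset."""

    mod_type: str
    n_positive: int = 60
    length_range: tuple[int, int] = (100, 160)
    composition: str = "uniform"  # uniform | swissprot
    signal_strength: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mod_type not in MOD_TYPES:
            raise ValueError(f"unknown mod_type {self.mod_type!r}")
        if not 0.5 <= self.signal_strength <= 1.0:
            raise ValueError("signal_strength must lie in [0.5, 1]")
        if self.length_range[0] < 20:
            raise ValueError("minimum length must cover the planted motif span")
        if self.composition not in ("uniform", "swissprot"):
            raise ValueError("composition must be 'uniform' or 'swissprot'")


def _probs(composition: str) -> np.ndarray:
    if composition == "uniform":
        return np.full(20, 1 / 20)
    p = np.array([SWISSPROT_COMPOSITION[a] for a in AA20])
    return p / p.sum()


def _background(rng: np.random.Generator, length: int, probs: np.ndarray) -> list[str]:
    return list(np.array(list(AA20))[rng.choice(20, size=length, p=probs)])


def _ensure_decoy(
    seq: list[str], residue: str, protected: set[int], rng: np.random.Generator
) -> None:
    """Guarantee at least one unannotated candidate residue in the chain."""
    if any(a == residue and (i + 1) not in protected for i, a in enumerate(seq)):
        return
    interior = [i for i in range(5, len(seq) - 5) if (i + 1) not in protected]
    seq[int(rng.choice(interior))] = residue


def _maybe(rng: np.random.Generator, p: float, wanted: str, fallback: str) -> str:
    """One character from ``wanted`` with probability p, else from ``fallback``."""
    pool = wanted if rng.random() < p else fallback
    return pool[int(rng.integers(len(pool)))]


def generate(spec: SynthSpec) -> tuple[list[Protein], list[ModSite]]:
    """Generate positive-substrate proteins and their ground-truth sites.

    Deterministic given ``spec.seed``; every protein carries exactly one
    annotated site plus decoy candidate residues.
    """
    rng = np.random.default_rng(spec.seed)
    probs = _probs(spec.composition)
    s = spec.signal_strength
    proteins: list[Protein] = []
    sites: list[ModSite] = []
    residue = MOD_TYPES[spec.mod_type]
    for i in range(spec.n_positive):
        L = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
        seq = _background(rng, L, probs)
        if spec.mod_type == "MYR":
            seq[0], seq[1] = "M", "G"
            seq[5] = _maybe(rng, s, ST, NON_ST)
            site_pos = 2
        elif spec.mod_type == "PALM":
            fam = PALM_FAMILIES[i % len(PALM_FAMILIES)]
            c_pos = int(rng.integers(10, L - 10))  # 1-based centre
            for off, consensus in zip(range(-3, 4), fam):
                if off == 0:
                    seq[c_pos - 1] = "C"
                else:
                    seq[c_pos - 1 + off] = _maybe(rng, s, consensus, AA20)
            site_pos = c_pos
        else:  # prenylation: FARN always CAAX; GERA cycles CAAX/CC/CXC
            if spec.mod_type == "FARN" or i % 3 == 0:
                seq[L - 4] = "C"
                seq[L - 3] = _maybe(rng, s, ALIPHATIC_CHOICES, AA20)
                seq[L - 2] = _maybe(rng, s, ALIPHATIC_CHOICES, AA20)
                site_pos = L - 3
            elif i % 3 == 1:  # terminal CC
                seq[L - 2], seq[L - 1] = "C", "C"
                site_pos = L
            else:  # terminal CXC
                seq[L - 3], seq[L - 1] = "C", "C"
                site_pos = L
            # polybasic membrane-targeting stretch upstream of the motif
            for j in range(L - 9, L - 4):
                seq[j] = _maybe(rng, s, BASIC, AA20)
        _ensure_decoy(seq, residue, {site_pos}, rng)
        pid = f"{spec.mod_type.lower()}_{i:03d}"
        proteins.append(Protein(id=pid, sequence="".join(seq)))
        sites.append(
            ModSite(protein_id=pid, position=site_pos, residue=residue,
                    mod_type=spec.mod_type)
        )
    return proteins, sites


def generate_all_types(
    seed: int = 0, **overrides
) -> dict[str, tuple[list[Protein], list[ModSite]]]:
    """One dataset per modification type, seeds derived from ``seed``."""
    out = {}
    for i, mod_type in enumerate(MOD_TYPES):
        spec = SynthSpec(mod_type=mod_type, seed=seed + i, **overrides)
        out[mod_type] = generate(spec)
    return out


@dataclass(frozen=True)
class NullLibrarySpec:
    """Conditions for a null crosstalk library: sites of each type placed
    independently and uniformly over candidate residues."""

    n_proteins: int = 100
    length_range: tuple[int, int] = (150, 200)
    composition: str = "uniform"
    sites_per_type: Mapping[str, int] = field(
        default_factory=lambda: {"PALM": 200, "MYR": 200, "FARN": 80, "GERA": 80}
    )
    seed: int = 0


def generate_null_library(spec: NullLibrarySpec) -> AnnotatedLibrary:
    """A library with no built-in association between modification types —
    the null for the co-occurrence, proximity and in-situ tests."""
    rng = np.random.default_rng(spec.seed)
    probs = _probs(spec.composition)
    proteins = []
    for i in range(spec.n_proteins):
        L = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
        proteins.append(
            Protein(id=f"null_{i:03d}", sequence="".join(_background(rng, L, probs)))
        )
    # candidate pools per residue, as (protein index, position) pairs
    pools: dict[str, list[tuple[int, int]]] = {"C": [], "G": []}
    for pi, prot in enumerate(proteins):
        for pos, aa in enumerate(prot.sequence, start=1):
            if aa in pools:
                pools[aa].append((pi, pos))
    sites: list[ModSite] = []
    for mod_type, n_sites in sorted(spec.sites_per_type.items()):
        pool = pools[MOD_TYPES[mod_type]]
        if n_sites > len(pool):
            raise ValueError(
                f"cannot place {n_sites} {mod_type} sites on {len(pool)} candidates"
            )
        chosen = rng.choice(len(pool), size=n_sites, replace=False)
        for ci in chosen:
            pi, pos = pool[int(ci)]
            sites.append(
                ModSite(protein_id=proteins[pi].id, position=pos,
                        residue=MOD_TYPES[mod_type], mod_type=mod_type)
            )
    return AnnotatedLibrary(proteins=proteins, sites=sites)
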