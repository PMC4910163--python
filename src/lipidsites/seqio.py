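"""Sequence and site-annotation I/O.

Proteins come in as FASTA; annotated lipid-modification sites come in as a
tab-separated table (``protein_id, position, residue, mod_type[, evidence]``,
1-based positions). Candidate residues are cysteines (S-palmitoylation and
prenylation) or glycines (N-myristoylation), and every scoring operation works
on a fixed-width peptide window centred on the candidate residue, padded with
``*`` where the window runs off a terminus.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

#: The 20 standard amino acids, alphabetical one-letter codes.
AA20 = "ACDEFGHIKLMNPQRSTVWY"
#: Full scoring alphabet: standard residues, ambiguous 'X', terminal pad '*'.
ALPHABET = AA20 + "X*"
#: Terminal padding character.
PAD = "*"

#: Supported modification types mapped to the residue they target.
MOD_TYPES: dict[str, str] = {
    "PALM": "C",  # S-palmitoylation
    "MYR": "G",   # N-myristoylation
    "FARN": "C",  # S-farnesylation
    "GERA": "C",  # S-geranylgeranylation
}

EVIDENCE_LEVELS = ("experimental", "predicted")

_NONSTANDARD = re.compile(f"[^{AA20}]")


class SeqIOError(ValueError):
    """Raised for malformed sequence or site input."""


@dataclass(frozen=True)
class Protein:
    """A protein sequence with a unique identifier."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise SeqIOError("protein id must be non-empty")
        if len(self.sequence) < 1:
            raise SeqIOError(f"protein {self.id!r}: empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)

    def residue(self, position: int) -> str:
        """1-based residue lookup."""
        if not 1 <= position <= len(self.sequence):
            raise SeqIOError(
                f"position {position} out of range for protein {self.id!r} "
                f"(length {len(self.sequence)})"
            )
        return self.sequence[position - 1]


@dataclass(frozen=True)
class ModSite:
    """An annotated or predicted lipid-modification site.

    ``position`` is 1-based. ``residue`` must match the protein sequence and
    be compatible with the modification type (G for MYR, C otherwise).
    Predicted sites additionally carry the winning group and score.
    """

    protein_id: str
    position: int
    residue: str
    mod_type: str
    evidence: str = "experimental"
    score: float | None = None
    cutoff: float | None = None
    group_id: str | None = None
    peptide: str | None = None

    def __post_init__(self) -> None:
        if self.mod_type not in MOD_TYPES:
            raise SeqIOError(f"unknown mod_type {self.mod_type!r}")
        expected = MOD_TYPES[self.mod_type]
        if self.residue != expected:
            raise SeqIOError(
                f"{self.mod_type} requires residue {expected}, got {self.residue!r}"
            )
        if self.evidence not in EVIDENCE_LEVELS:
            raise SeqIOError(f"unknown evidence level {self.evidence!r}")
        if self.position < 1:
            raise SeqIOError(f"position must be >= 1, got {self.position}")

    @property
    def key(self) -> tuple[str, int, str]:
        """Deduplication key: (protein, position, type)."""
        return (self.protein_id, self.position, self.mod_type)


@dataclass(frozen=True)
class PeptideWindow:
    """A PSP(m, n) peptide: the candidate residue with m upstream and n
    downstream flanking residues, ``*``-padded at termini."""

    center_pos: int
    m: int
    n: int
    residues: str

    def __post_init__(self) -> None:
        if len(self.residues) != self.m + self.n + 1:
            raise SeqIOError(
                f"window length {len(self.residues)} != m+n+1 = {self.m + self.n + 1}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def center(self) -> str:
        return self.residues[self.m]

    def trim(self, m: int, n: int) -> "PeptideWindow":
        """Return a narrower window around the same centre."""
        if m > self.m or n > self.n:
            raise SeqIOError(
                f"cannot trim ({self.m},{self.n}) window to ({m},{n})"
            )
        s = self.residues[self.m - m : self.m + n + 1]
        return PeptideWindow(center_pos=self.center_pos, m=m, n=n, residues=s)


def normalize_sequence(raw: str) -> str:
    """Uppercase, drop ``*``/``-``, and map non-standard letters to ``X``."""
    s = raw.upper().replace("*", "").replace("-", "")
    return _NONSTANDARD.sub("X", s)


def read_fasta(path: str | Path) -> list[Protein]:
    """Read a FASTA file into a list of :class:`Protein`.

    Sequences are normalised (see :func:`normalize_sequence`); the id is the
    first whitespace-delimited token of the header. Duplicate ids and empty
    files are errors.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise SeqIOError(f"no FASTA records found in {path}")
    proteins: list[Protein] = []
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise SeqIOError(f"duplicate protein id {rec.id!r} in {path}")
        seen.add(rec.id)
        proteins.append(Protein(id=rec.id, sequence=normalize_sequence(str(rec.seq))))
    return proteins


def write_fasta(proteins: Iterable[Protein], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for p in proteins:
            fh.write(f">{p.id}\n")
            for i in range(0, len(p.sequence), width):
                fh.write(p.sequence[i : i + width] + "\n")


def extract_window(protein: Protein, position: int, m: int, n: int) -> PeptideWindow:
    """Extract the PSP(m, n) window centred at ``position`` (1-based).

    Positions before the N-terminus or past the C-terminus are filled
    with ``*``.
    """
    if not 1 <= position <= len(protein.sequence):
        raise SeqIOError(
            f"position {position} out of range for protein {protein.id!r}"
        )
    seq = protein.sequence
    i = position - 1
    left = seq[max(0, i - m) : i]
    right = seq[i + 1 : i + 1 + n]
    residues = PAD * (m - len(left)) + left + seq[i] + right + PAD * (n - len(right))
    return PeptideWindow(center_pos=position, m=m, n=n, residues=residues)


def enumerate_candidates(protein: Protein, residue: str) -> list[int]:
    """All 1-based positions of ``residue`` (C or G) in the sequence."""
    if residue not in ("C", "G"):
        raise SeqIOError(f"candidate residue must be C or G, got {residue!r}")
    return [i + 1 for i, a in enumerate(protein.sequence) if a == residue]


SITE_COLUMNS = ("protein_id", "position", "residue", "mod_type", "evidence")


def read_sites(path: str | Path, proteins: Sequence[Protein]) -> list[ModSite]:
    """Read and validate a site TSV against a protein dataset.

    The table must carry a header line with at least the first four of
    ``protein_id, position, residue, mod_type, evidence``. Each row is checked
    against the sequence: the stated residue must occupy the stated 1-based
    position. Violations raise with the offending row number.
    """
    by_id = {p.id: p for p in proteins}
    sites: list[ModSite] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[: 4] != list(SITE_COLUMNS[:4]):
            raise SeqIOError(
                f"{path}: expected header starting with {SITE_COLUMNS[:4]}, got {header}"
            )
        has_evidence = len(header) >= 5 and header[4] == "evidence"
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            try:
                pid, pos_s, res, mod = fields[:4]
                evidence = fields[4] if has_evidence and len(fields) > 4 else "experimental"
                position = int(pos_s)
                if pid not in by_id:
                    raise SeqIOError(f"unknown protein id {pid!r}")
                prot = by_id[pid]
                actual = prot.residue(position)
                if actual != res:
                    raise SeqIOError(
                        f"residue mismatch: annotation says {res!r} but "
                        f"{pid} position {position} is {actual!r}"
                    )
                sites.append(
                    ModSite(protein_id=pid, position=position, residue=res,
                            mod_type=mod, evidence=evidence)
                )
            except (ValueError, IndexError) as exc:
                raise SeqIOError(f"{path}:{lineno}: {exc}") from exc
    return sites


def write_sites(sites: Iterable[ModSite], path: str | Path) -> None:
    """Write sites in the TSV dialect read by :func:`read_sites`."""
    with open(path, "w") as fh:
        fh.write("\t".join(SITE_COLUMNS) + "\n")
        for s in sites:
            fh.write(
                f"{s.protein_id}\t{s.position}\t{s.residue}\t{s.mod_type}\t{s.evidence}\n"
            )


def filter_proteins(proteins: Sequence[Protein], keep_ids: Iterable[str]) -> list[Protein]:
    """Optional homology-reduction hook: keep only a pre-clustered id list.

    Redundancy removal itself (e.g. 40% identity clustering) is delegated to
    external tools; this accepts their output.
    """
    keep = set(keep_ids)
    return [p for p in proteins if p.id in keep]
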