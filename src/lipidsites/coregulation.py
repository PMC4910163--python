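"""Dual-lipid co-regulation statistics.

Three tests probe how two lipid modification types relate within an annotated
sequence library (experimental sites merged with high-stringency
predictions):

* **co-occurrence** — a protein-level 2x2 chi-square: does carrying type A
  predict carrying type B?
* **spatial proximity** — a residue-level 2x2 chi-square: are A-modified
  residues more likely than unmodified candidate residues of the same amino
  acid to have a B site within a flanking window such as (5,5), (10,10),
  (15,15)?
* **in-situ crosstalk** — a hypergeometric test on cysteines: do two
  cysteine-directed modifications target the very same residues more often
  than chance, with an enrichment ratio (k/n)/(K/N)?

Significance is reported as ``-ln(p)``, so p = 0.05 maps to 2.99 and
p = 0.01 to 4.61.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .seqio import MOD_TYPES, ModSite, Protein, enumerate_candidates
from .training import PredictorModel, predict

logger = logging.getLogger(__name__)

#: Significance cap used when p underflows to zero.
SIG_CAP = -math.log(5e-324)

PROXIMITY_WINDOWS = ((5, 5), (10, 10), (15, 15))


@dataclass
class AnnotatedLibrary:
    """Proteins plus merged, deduplicated modification sites."""

    proteins: list[Protein]
    sites: list[ModSite]

    def __post_init__(self) -> None:
        by_id = {p.id: p for p in self.proteins}
        seen: set[tuple[str, int, str]] = set()
        deduped: list[ModSite] = []
        for s in self.sites:
            if s.protein_id not in by_id:
                raise ValueError(f"site references unknown protein {s.protein_id!r}")
            if by_id[s.protein_id].residue(s.position) != s.residue:
                raise ValueError(
                    f"site {s.protein_id}:{s.position} does not match the sequence"
                )
            if s.key in seen:
                continue
            seen.add(s.key)
            deduped.append(s)
        self.sites = deduped

    def sites_of(self, mod_type: str) -> list[ModSite]:
        return [s for s in self.sites if s.mod_type == mod_type]

    def positions_of(self, mod_type: str) -> dict[str, set[int]]:
        out: dict[str, set[int]] = {}
        for s in self.sites_of(mod_type):
            out.setdefault(s.protein_id, set()).add(s.position)
        return out

    def counts(self) -> dict[str, int]:
        out = {t: 0 for t in MOD_TYPES}
        for s in self.sites:
            out[s.mod_type] += 1
        return out


@dataclass(frozen=True)
class ContingencyTable2x2:
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")
        if self.a + self.b + self.c + self.d < 1:
            raise ValueError("table total must be >= 1")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)

    @property
    def degenerate(self) -> bool:
        """True when a row or column margin is zero."""
        t = self.as_array()
        return bool(
            np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0)
        )


@dataclass(frozen=True)
class CrosstalkResult:
    """Outcome of one dual-lipid statistical test."""

    pair: tuple[str, str]
    test: str  # cooccurrence | proximity | insitu
    statistic: float
    p: float
    significance: float
    window: tuple[int, int] | None = None
    enrichment_ratio: float | None = None
    table: ContingencyTable2x2 | None = None
    degenerate: bool = False
    applicable: bool = True


def significance(p: float) -> float:
    """The -ln(p) significance transform; p = 0.05 -> 2.99, 0.01 -> 4.61.

    p at or below the machine floor is capped (and flagged in the log); p
    outside (0, 1] is a sentinel cap.
    """
    if p <= 0:
        logger.warning("p <= 0 passed to significance; returning cap %.1f", SIG_CAP)
        return SIG_CAP
    if p > 1:
        raise ValueError(f"p must be <= 1, got {p}")
    return min(-math.log(p), SIG_CAP)


def chi_square_2x2(table: ContingencyTable2x2) -> tuple[float, float]:
    """Pearson chi-square (df = 1, no continuity correction) and its p-value.

    A zero margin makes the test undefined; the statistic is reported as 0
    with p = 1.
    """
    if table.degenerate:
        return 0.0, 1.0
    stat, p, _, _ = stats.chi2_contingency(table.as_array(), correction=False)
    return float(stat), float(p)


def build_library(
    proteins: Sequence[Protein],
    experimental_sites: Sequence[ModSite],
    models: Mapping[str, PredictorModel],
) -> AnnotatedLibrary:
    """Merge experimental sites with high-stringency predictions from each
    available per-type model, deduplicating on (protein, position, type)."""
    sites = list(experimental_sites)
    for mod_type in MOD_TYPES:
        model = models.get(mod_type)
        if model is None:
            logger.warning("no model for %s; predictions skipped", mod_type)
            continue
        sites.extend(predict(model, proteins, stringency="high"))
    lib = AnnotatedLibrary(proteins=list(proteins), sites=sites)
    logger.info("library site counts: %s", lib.counts())
    return lib


def cooccurrence_test(
    lib: AnnotatedLibrary, type_a: str, type_b: str
) -> CrosstalkResult:
    """Protein-level dependence of carrying type A on carrying type B."""
    has_a = set(lib.positions_of(type_a))
    has_b = set(lib.positions_of(type_b))
    all_ids = {p.id for p in lib.proteins}
    a = len(has_a & has_b)
    b = len(has_a - has_b)
    c = len(has_b - has_a)
    d = len(all_ids - has_a - has_b)
    table = ContingencyTable2x2(a=a, b=b, c=c, d=d)
    applicable = bool(has_a) and bool(has_b)
    stat, p = chi_square_2x2(table)
    return CrosstalkResult(
        pair=(type_a, type_b), test="cooccurrence", statistic=stat, p=p,
        significance=significance(p), table=table,
        degenerate=table.degenerate, applicable=applicable,
    )


def proximity_test(
    lib: AnnotatedLibrary,
    type_a: str,
    type_b: str,
    window: tuple[int, int] = (10, 10),
) -> CrosstalkResult:
    """Are B sites enriched in the flanking regions of A-modified residues,
    relative to unmodified candidate residues of the same amino acid?

    A residue's own position is excluded from its window, so an in-situ
    overlap does not count as proximity.
    """
    if type_a == type_b:
        raise ValueError("proximity test needs two distinct types")
    up, down = window
    residue_a = MOD_TYPES[type_a]
    a_pos = lib.positions_of(type_a)
    b_pos = lib.positions_of(type_b)
    if not any(a_pos.values()):
        raise ValueError(f"no {type_a} sites in the library")
    mod_near = mod_far = other_near = other_far = 0
    for prot in lib.proteins:
        a_here = a_pos.get(prot.id, set())
        b_here = b_pos.get(prot.id, set())
        for pos in enumerate_candidates(prot, residue_a):
            near = any(
                (pos - up) <= q <= (pos + down) and q != pos for q in b_here
            )
            if pos in a_here:
                mod_near += near
                mod_far += not near
            else:
                other_near += near
                other_far += not near
    table = ContingencyTable2x2(a=mod_near, b=mod_far, c=other_near, d=other_far)
    stat, p = chi_square_2x2(table)
    return CrosstalkResult(
        pair=(type_a, type_b), test="proximity", statistic=stat, p=p,
        significance=significance(p), window=window, table=table,
        degenerate=table.degenerate,
    )


def insitu_test(
    lib: AnnotatedLibrary, prenyl_type: str, other_type: str
) -> CrosstalkResult:
    """Upper-tail hypergeometric test of two cysteine-directed modifications
    hitting the same cysteines.

    Population: all cysteines of library proteins carrying at least one
    lipid annotation. K = cysteines with ``other_type``, n = cysteines with
    ``prenyl_type``, k = overlap; p = P(X >= k).
    """
    for t in (prenyl_type, other_type):
        if MOD_TYPES[t] != "C":
            raise ValueError(f"{t} is not cysteine-directed")
    annotated = {s.protein_id for s in lib.sites}
    a_pos = lib.positions_of(prenyl_type)
    b_pos = lib.positions_of(other_type)
    N = K = n = k = 0
    for prot in lib.proteins:
        if prot.id not in annotated:
            continue
        cys = set(enumerate_candidates(prot, "C"))
        N += len(cys)
        ka = cys & a_pos.get(prot.id, set())
        kb = cys & b_pos.get(prot.id, set())
        n += len(ka)
        K += len(kb)
        k += len(ka & kb)
    if N == 0:
        raise ValueError("no cysteines in annotated library proteins")
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    p = min(max(p, 0.0), 1.0)
    enrichment = (k / n) / (K / N) if n > 0 and K > 0 else math.nan
    return CrosstalkResult(
        pair=(prenyl_type, other_type), test="insitu",
        statistic=float(k), p=p, significance=significance(p),
        enrichment_ratio=enrichment,
    )


def all_pairs() -> list[tuple[str, str]]:
    """The six unordered dual-lipid combinations."""
    types = list(MOD_TYPES)
    return [(a, b) for i, a in enumerate(types) for b in types[i + 1 :]]
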