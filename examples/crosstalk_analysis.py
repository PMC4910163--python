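"""Dual-lipid crosstalk statistics on a null library and a coupled one.

First a null library (sites of each type placed independently over candidate
residues) — all three tests should be unremarkable. Then a library in which
farnesylation and geranylgeranylation share C-terminal cysteines — the
in-situ hypergeometric test should flag strong enrichment. Significance is
-ln(p): values above 2.99 correspond to p < 0.05, above 4.61 to p < 0.01.
"""

from lipidsites.coregulation import (
    AnnotatedLibrary,
    cooccurrence_test,
    insitu_test,
    proximity_test,
)
from lipidsites.seqio import ModSite, Protein
from lipidsites.synth import NullLibrarySpec, generate_null_library

lib = generate_null_library(NullLibrarySpec(seed=0))
print("null library:", lib.counts())
r = cooccurrence_test(lib, "PALM", "MYR")
print(f"  co-occurrence PALM/MYR: chi2={r.statistic:.2f} p={r.p:.3f} "
      f"significance={r.significance:.2f}")
r = proximity_test(lib, "PALM", "MYR", window=(10, 10))
print(f"  proximity (10,10):      chi2={r.statistic:.2f} p={r.p:.3f} "
      f"significance={r.significance:.2f}")
r = insitu_test(lib, "FARN", "PALM")
print(f"  in-situ FARN/PALM:      overlap k={r.statistic:.0f} p={r.p:.3f} "
      f"enrichment={r.enrichment_ratio:.2f}")

# a library where the two prenylation types target the same cysteines
proteins, sites = [], []
for i in range(40):
    # two unmodified decoy cysteines keep the overlap non-trivial
    seq = "M" + "AKL" * 5 + "C" + "AKL" * 5 + "C" + "AKL" * 2 + "CVIM"
    pid = f"dual_{i:02d}"
    proteins.append(Protein(id=pid, sequence=seq))
    pos = len(seq) - 3
    sites.append(ModSite(protein_id=pid, position=pos, residue="C", mod_type="FARN"))
    if i % 2 == 0:
        sites.append(ModSite(protein_id=pid, position=pos, residue="C", mod_type="GERA"))
dual = AnnotatedLibrary(proteins=proteins, sites=sites)
r = insitu_test(dual, "GERA", "FARN")
print(f"\ncoupled library, in-situ GERA/FARN: k={r.statistic:.0f} "
      f"p={r.p:.3g} significance={r.significance:.2f} "
      f"enrichment={r.enrichment_ratio:.2f}")
print("(every geranylgeranylated cysteine is also farnesylated -> "
      "strong in-situ crosstalk)")
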