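"""Dual-lipid crosstalk statistics: chi-square, hypergeometric, -ln p."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import comb

from lipidsites.coregulation import (
    AnnotatedLibrary,
    ContingencyTable2x2,
    SIG_CAP,
    build_library,
    chi_square_2x2,
    cooccurrence_test,
    insitu_test,
    proximity_test,
    significance,
)
from lipidsites.seqio import ModSite, Protein
from lipidsites.synth import NullLibrarySpec, generate_null_library


class TestSignificance:
    def test_alpha_anchors(self):
        # printed thresholds: 2.99 (truncated from 2.9957) and 4.61
        # (rounded from 4.6052); check one unit in the last printed digit
        assert abs(significance(0.05) - 2.99) < 0.01
        assert abs(significance(0.01) - 4.61) < 0.01

    def test_p_one_is_zero(self):
        assert significance(1.0) == 0.0

    def test_nonpositive_p_capped(self):
        assert significance(0.0) == SIG_CAP
        assert significance(-1.0) == SIG_CAP

    def test_p_above_one_rejected(self):
        with pytest.raises(ValueError):
            significance(1.5)


def closed_form_chi2(a, b, c, d):
    n = a + b + c + d
    return n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))


class TestChiSquare:
    def test_exact_independence(self):
        stat, p = chi_square_2x2(ContingencyTable2x2(10, 10, 10, 10))
        assert stat == 0.0 and p == 1.0

    def test_association_statistic(self):
        stat, _ = chi_square_2x2(ContingencyTable2x2(30, 10, 10, 30))
        assert stat == pytest.approx(20.0)

    def test_zero_margin_degenerate(self):
        t = ContingencyTable2x2(0, 0, 5, 5)
        assert t.degenerate
        stat, p = chi_square_2x2(t)
        assert stat == 0.0 and p == 1.0

    @given(
        st.integers(0, 50), st.integers(0, 50),
        st.integers(0, 50), st.integers(0, 50),
    )
    @settings(derandomize=True, max_examples=100)
    def test_matches_closed_form(self, a, b, c, d):
        if a + b + c + d == 0:
            return
        t = ContingencyTable2x2(a, b, c, d)
        if t.degenerate:
            return
        stat, _ = chi_square_2x2(t)
        assert stat == pytest.approx(closed_form_chi2(a, b, c, d))


def enumeration_hypergeom_tail(N, K, n, k):
    """P(X >= k) by direct summation of the hypergeometric pmf."""
    total = comb(N, n, exact=True)
    acc = 0
    for j in range(k, min(K, n) + 1):
        acc += comb(K, j, exact=True) * comb(N - K, n - j, exact=True)
    return acc / total


def _cys_library(n_cys, farn_at, palm_at):
    prot = Protein(id="p1", sequence="C" * n_cys)
    sites = [
        ModSite(protein_id="p1", position=i, residue="C", mod_type="FARN")
        for i in farn_at
    ] + [
        ModSite(protein_id="p1", position=i, residue="C", mod_type="PALM")
        for i in palm_at
    ]
    return AnnotatedLibrary(proteins=[prot], sites=sites)


class TestInSitu:
    def test_complete_overlap_small_population(self):
        # N=10 cysteines, K=n=5, full overlap: p = C(5,5) C(5,0) / C(10,5)
        lib = _cys_library(10, range(1, 6), range(1, 6))
        r = insitu_test(lib, "FARN", "PALM")
        assert r.p == pytest.approx(1 / 252)
        assert r.enrichment_ratio == pytest.approx(2.0)

    def test_zero_overlap_is_vacuous(self):
        lib = _cys_library(10, range(1, 4), range(5, 8))
        r = insitu_test(lib, "FARN", "PALM")
        assert r.p == pytest.approx(1.0)

    def test_enrichment_one_at_independence_rate(self):
        # k/n = 1/2 equals K/N = 5/10
        lib = _cys_library(10, [1, 2], [1, 5, 6, 7, 8])
        r = insitu_test(lib, "FARN", "PALM")
        assert r.enrichment_ratio == pytest.approx(1.0)

    def test_rejects_glycine_directed_type(self):
        lib = _cys_library(5, [1], [2])
        with pytest.raises(ValueError):
            insitu_test(lib, "FARN", "MYR")

    @given(st.data())
    @settings(derandomize=True, max_examples=80)
    def test_matches_enumeration_oracle(self, data):
        N = data.draw(st.integers(1, 30))
        K = data.draw(st.integers(0, N))
        n = data.draw(st.integers(0, N))
        k_max = min(K, n)
        k = data.draw(st.integers(0, k_max))
        from scipy import stats as sps

        p = float(sps.hypergeom.sf(k - 1, N, K, n))
        assert p == pytest.approx(enumeration_hypergeom_tail(N, K, n, k))


def _proximity_library():
    """Every PALM cysteine has an adjacent MYR glycine; decoy cysteines
    far from any glycine."""
    proteins, sites = [], []
    for i in range(30):
        # C at 10 with G at 12 (within +-5); decoy C at 30, no G nearby
        seq = list("A" * 40)
        seq[9], seq[11], seq[29] = "C", "G", "C"
        pid = f"x{i}"
        proteins.append(Protein(id=pid, sequence="".join(seq)))
        sites.append(ModSite(protein_id=pid, position=10, residue="C", mod_type="PALM"))
        sites.append(ModSite(protein_id=pid, position=12, residue="G", mod_type="MYR"))
    return AnnotatedLibrary(proteins=proteins, sites=sites)


class TestProximity:
    def test_constructed_association_is_significant(self):
        lib = _proximity_library()
        r = proximity_test(lib, "PALM", "MYR", window=(5, 5))
        # modified C's all have a neighbouring B site; decoys never do
        assert r.table.a == 30 and r.table.b == 0
        assert r.table.c == 0 and r.table.d == 30
        assert r.p < 1e-10

    def test_null_library_not_significant(self):
        lib = generate_null_library(NullLibrarySpec(seed=0))
        r = proximity_test(lib, "PALM", "MYR", window=(10, 10))
        assert r.p > 0.05

    def test_widening_window_never_loses_neighbours(self):
        lib = generate_null_library(NullLibrarySpec(seed=3))
        near = [
            proximity_test(lib, "PALM", "MYR", window=w).table.a
            for w in ((5, 5), (10, 10), (15, 15))
        ]
        assert near[0] <= near[1] <= near[2]

    def test_self_position_excluded(self):
        # a lone C that is both A-modified and B-modified, no other B nearby:
        # its own position must not count as a neighbour
        prot = Protein(id="p", sequence="AAAACAAAA")
        sites = [
            ModSite(protein_id="p", position=5, residue="C", mod_type="PALM"),
            ModSite(protein_id="p", position=5, residue="C", mod_type="FARN"),
        ]
        lib = AnnotatedLibrary(proteins=[prot], sites=sites)
        r = proximity_test(lib, "PALM", "FARN", window=(5, 5))
        assert r.table.a == 0

    def test_no_a_sites_errors(self):
        lib = _cys_library(5, [1], [2])
        with pytest.raises(ValueError, match="MYR"):
            proximity_test(lib, "MYR", "PALM")

    def test_same_type_rejected(self):
        lib = _proximity_library()
        with pytest.raises(ValueError):
            proximity_test(lib, "PALM", "PALM")


class TestCooccurrence:
    def _lib(self):
        proteins = [Protein(id=f"p{i}", sequence="MGCAAAC") for i in range(40)]
        sites = []
        for i in range(40):
            if i < 25:
                sites.append(ModSite(protein_id=f"p{i}", position=3, residue="C", mod_type="PALM"))
            if i < 20 or i >= 35:
                sites.append(ModSite(protein_id=f"p{i}", position=2, residue="G", mod_type="MYR"))
        return AnnotatedLibrary(proteins=proteins, sites=sites)

    def test_symmetric_in_pair_order(self):
        lib = self._lib()
        r1 = cooccurrence_test(lib, "PALM", "MYR")
        r2 = cooccurrence_test(lib, "MYR", "PALM")
        assert r1.statistic == pytest.approx(r2.statistic)
        assert r1.p == pytest.approx(r2.p)

    def test_missing_type_degenerate(self):
        lib = self._lib()
        r = cooccurrence_test(lib, "PALM", "FARN")
        assert r.degenerate and r.p == 1.0 and not r.applicable


class TestLibrary:
    def test_duplicate_sites_removed(self):
        prot = Protein(id="p", sequence="MGCAA")
        s = ModSite(protein_id="p", position=3, residue="C", mod_type="PALM")
        lib = AnnotatedLibrary(proteins=[prot], sites=[s, s])
        assert len(lib.sites) == 1

    def test_same_position_distinct_types_kept(self):
        prot = Protein(id="p", sequence="AAAACAAAA")
        sites = [
            ModSite(protein_id="p", position=5, residue="C", mod_type="PALM"),
            ModSite(protein_id="p", position=5, residue="C", mod_type="FARN"),
        ]
        lib = AnnotatedLibrary(proteins=[prot], sites=sites)
        assert len(lib.sites) == 2

    def test_build_library_merges_predictions(self, myr_model, myr_data):
        proteins, sites = myr_data
        lib = build_library(proteins, sites, {"MYR": myr_model})
        keys = [s.key for s in lib.sites]
        assert len(keys) == len(set(keys))
        # every experimental site survives the merge
        assert {s.key for s in sites} <= set(keys)

    def test_empty_prediction_set_leaves_experimental(self, myr_data):
        proteins, sites = myr_data
        lib = build_library(proteins, sites, {})
        assert {s.key for s in lib.sites} == {s.key for s in sites}


def test_null_calibration_rejection_and_uniformity():
    """Over 100 null libraries the co-occurrence p-values are approximately
    uniform and the proximity test rejects at roughly its nominal rate."""
    from scipy import stats as sps

    cooc_p, prox_p = [], []
    for seed in range(100):
        lib = generate_null_library(NullLibrarySpec(seed=seed))
        cooc_p.append(cooccurrence_test(lib, "PALM", "MYR").p)
        prox_p.append(proximity_test(lib, "PALM", "MYR", window=(10, 10)).p)
    assert sps.kstest(cooc_p, "uniform").pvalue > 0.01
    assert 0.0 <= np.mean(np.array(prox_p) < 0.05) <= 0.10
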