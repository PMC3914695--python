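"""Homoplasy classification: pattern enumeration, brute-force equivalence,
window aggregation, double-hit expectation."""

from __future__ import annotations

from itertools import combinations

import dendropy
import numpy as np
import pytest

from clonalscan.alignment import SnpRecord
from clonalscan import recombination as rec
from conftest import random_bifurcating_newick


def snp(alleles: str, ancestral=None, ref_pos=0, n_alleles=None) -> SnpRecord:
    return SnpRecord(
        ref_pos=ref_pos, column=ref_pos, alleles=alleles, outgroup_allele=ancestral or "N",
        n_alleles=n_alleles or len(set(alleles)), is_polymorphic=len(set(alleles)) > 1,
        is_divergent=False, ancestral=ancestral,
    )


class TestPatternEnumeration:
    def test_ten_leaf_tree_has_18_polarised_configurations(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            t = rec.ClonalTree.from_newick(random_bifurcating_newick(10, rng))
            assert len(rec.enumerate_single_mutation_patterns(t, polarized=True)) == 18
            assert len(rec.enumerate_single_mutation_patterns(t, polarized=False)) == 17

    def test_two_leaf_tree(self):
        t = rec.ClonalTree.from_newick("(A:1,B:1);")
        assert len(rec.enumerate_single_mutation_patterns(t, polarized=True)) == 2
        assert len(rec.enumerate_single_mutation_patterns(t, polarized=False)) == 1

    def test_balanced_four_leaf_tree_patterns_explicit(self):
        t = rec.ClonalTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        pats = rec.enumerate_single_mutation_patterns(t, polarized=True)
        assert {p.members for p in pats} == {
            ("A",), ("B",), ("C",), ("D",), ("A", "B"), ("C", "D"),
        }

    def test_nonbifurcating_tree_rejected(self):
        with pytest.raises(rec.TreeStructureError):
            rec.ClonalTree.from_newick("(A:1,B:1,C:1);")

    def test_leaf_mismatch_rejected(self):
        with pytest.raises(rec.TreeStructureError, match="ingroup"):
            rec.ClonalTree.from_newick("(A:1,B:1);", ingroup_ids=["A", "C"])


class TestClassification:
    @pytest.fixture()
    def clf(self):
        tree = rec.ClonalTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        return rec.HomoplasyClassifier(tree, ["A", "B", "C", "D"])

    def test_singleton_is_clonal(self, clf):
        assert clf.classify(snp("GAAA", ancestral="A")) == "clonal"

    def test_cross_clade_pair_is_recombinant(self, clf):
        # derived in {A, C}: no edge of ((A,B),(C,D)) subtends that clade
        assert clf.classify(snp("GAGA", ancestral="A")) == "recombinant"

    def test_cherry_clade_is_clonal(self, clf):
        assert clf.classify(snp("GGAA", ancestral="A")) == "clonal"

    def test_multiallelic_excluded(self, clf):
        s = snp("GCAA", ancestral="A")
        assert clf.classify(s) == "excluded"
        assert s.pattern is None

    def test_unpolarised_fallback_uses_bipartition(self, clf):
        # outgroup matches neither allele: {A,B}|{C,D} is a tree split
        assert clf.classify(snp("GGAA", ancestral=None)) == "clonal"
        assert clf.classify(snp("GAGA", ancestral=None)) == "recombinant"


def iter_biallelic_patterns(labels):
    """Every nonempty proper subset as a derived set."""
    for r in range(1, len(labels)):
        yield from combinations(labels, r)


class TestBruteForceEquivalence:
    def test_classification_agrees_with_independent_edge_membership(self):
        """200 random trees (n <= 8) x all biallelic patterns: the classifier
        must agree with direct bipartition-table membership from dendropy."""
        rng = np.random.default_rng(2024)
        for rep in range(200):
            n = int(rng.integers(3, 9))
            labels = [chr(65 + i) for i in range(n)]
            newick = random_bifurcating_newick(n, rng, labels=labels)
            ctree = rec.ClonalTree.from_newick(newick)
            clf = rec.HomoplasyClassifier(ctree, labels)

            # independent oracle: clade sets via dendropy bipartition encoding
            dtree = dendropy.Tree.get(data=newick, schema="newick")
            dtree.is_rooted = True
            dtree.encode_bipartitions()
            taxa = {t.label: i for i, t in enumerate(dtree.taxon_namespace)}
            clades = set()
            for edge in dtree.preorder_edge_iter():
                if edge.head_node is dtree.seed_node:
                    continue
                mask = edge.bipartition.leafset_bitmask
                clades.add(frozenset(l for l, i in taxa.items() if mask >> i & 1))

            for derived in iter_biallelic_patterns(labels):
                alleles = "".join("G" if l in derived else "A" for l in labels)
                got = clf.classify(snp(alleles, ancestral="A"))
                want = "clonal" if frozenset(derived) in clades else "recombinant"
                assert got == want, (newick, derived)
                # unpolarised: compatible iff either side is a clade
                got_u = clf.classify(snp(alleles, ancestral=None))
                comp = frozenset(labels) - frozenset(derived)
                want_u = (
                    "clonal"
                    if frozenset(derived) in clades or comp in clades
                    else "recombinant"
                )
                assert got_u == want_u, (newick, derived)


class TestWindowAggregation:
    def make_windows(self, n=2, width=100):
        from clonalscan.alignment import WindowRow
        return [
            WindowRow(i, i * width, (i + 1) * width, width, 0, True) for i in range(n)
        ]

    def test_no_recombinant_snps(self):
        tree = rec.ClonalTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        clf = rec.HomoplasyClassifier(tree, list("ABCD"))
        snps = [snp("GAAA", "A", ref_pos=i) for i in range(10)]
        for s in snps:
            clf.classify(s)
        (w, _) = rec.window_recombination(self.make_windows(), snps, 100)
        assert (w.n_recombinant, w.recombinant_proportion, w.n_unique_topologies) == (0, 0.0, 0)

    def test_shared_pattern_counts_once_and_distinct_patterns_counted(self):
        tree = rec.ClonalTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        clf = rec.HomoplasyClassifier(tree, list("ABCD"))
        same = [snp("GAGA", "A", ref_pos=i) for i in range(3)]
        others = [snp("GAAG", "A", ref_pos=3), snp("AGGA", "A", ref_pos=4)]
        for s in same + others:
            assert clf.classify(s) == "recombinant"
        (w, _) = rec.window_recombination(self.make_windows(), same + others, 100)
        assert w.n_recombinant == 5
        assert w.n_unique_topologies == 3
        assert w.recombinant_proportion == 1.0

    def test_empty_window_reports_missing_proportion(self):
        (w0, w1) = rec.window_recombination(self.make_windows(), [], 100)
        assert w0.recombinant_proportion is None

    def test_class_counts_partition_polymorphic_snps(self, constant_analysis):
        windows = constant_analysis["windows"]
        snps = constant_analysis["snps"]
        for w in windows:
            n_poly = sum(
                1 for s in snps if s.is_polymorphic and w.start <= s.ref_pos < w.end
            )
            assert w.n_clonal + w.n_recombinant + w.n_excluded == n_poly


class TestDoubleHitExpectation:
    def test_degenerate_inputs_give_zero(self):
        tree = rec.ClonalTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        assert rec.expected_double_hit_homoplasies(0, 1000, tree) == 0.0
        assert rec.expected_double_hit_homoplasies(1, 1000, tree) == 0.0

    def test_birthday_bound_dominates_monte_carlo(self):
        tree = rec.ClonalTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        S, L = 300, 5_000
        est = rec.expected_double_hit_homoplasies(S, L, tree, n_reps=200, seed=1)
        bound = S * (S - 1) / (2 * L)
        assert est <= bound * 1.1

    def test_clonal_dataset_recombinant_calls_consistent_with_double_hits(
        self, constant_analysis
    ):
        """Without recombination every recombinant call is a multi-hit
        artifact; the Monte-Carlo expectation over the full genealogy
        (including outgroup mispolarisation) must match their count."""
        snps = constant_analysis["snps"]
        observed = sum(1 for s in snps if s.clonal_class == "recombinant")
        n_poly = sum(1 for s in snps if s.is_polymorphic)
        total_records = len(snps)   # polymorphic + divergent mutation footprint
        core_len = int(constant_analysis["core"].sum())
        expected = rec.expected_double_hit_homoplasies(
            total_records, core_len, constant_analysis["full_tree"],
            n_reps=30, seed=5, outgroup="OUT",
        )
        assert observed <= 0.05 * n_poly          # a small fraction of SNPs
        assert 0.2 * expected <= observed <= 3.0 * expected
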