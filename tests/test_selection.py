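"""Selection statistics: NG86 vs exhaustive pathway oracle, MK G-test,
Bonferroni threshold, Tajima's D vs an independent implementation."""

from __future__ import annotations

from itertools import permutations, product

import numpy as np
import pytest

from clonalscan import selection as sel
from clonalscan.alignment import AlignmentMatrix, SnpRecord, encode_sequence


def build_matrix(rows: dict[str, str], reference=None, outgroup="O") -> AlignmentMatrix:
    ids = list(rows)
    data = np.stack([encode_sequence(rows[s]) for s in ids])
    return AlignmentMatrix(
        ids=ids, data=data,
        reference_id=reference or ids[0], outgroup_id=outgroup,
    )


# --- independent NG86 oracle (test-local, recursive path enumeration) -------

def oracle_path_counts(a: str, b: str):
    """Average (syn, nonsyn) steps over stop-free orderings, by recursion."""
    tr = sel.translate_codon
    results = []

    def walk(cur, remaining, syn, non):
        if not remaining:
            results.append((syn, non))
            return
        for pos in remaining:
            nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
            if tr(nxt) == "*":
                continue
            walk(nxt, [p for p in remaining if p != pos],
                 syn + (tr(nxt) == tr(cur)), non + (tr(nxt) != tr(cur)))

    walk(a, [i for i in range(3) if a[i] != b[i]], 0, 0)
    if not results:
        return None
    # each full ordering contributes len(order)! / branching... enumerate orderings
    # directly instead to weight orderings equally:
    results = []
    for order in permutations([i for i in range(3) if a[i] != b[i]]):
        cur, syn, non, ok = a, 0, 0, True
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
            if tr(nxt) == "*":
                ok = False
                break
            syn += tr(nxt) == tr(cur)
            non += tr(nxt) != tr(cur)
            cur = nxt
        if ok:
            results.append((syn, non))
    if not results:
        return None
    return (
        sum(r[0] for r in results) / len(results),
        sum(r[1] for r in results) / len(results),
    )


SENSE_CODONS = [
    "".join(c) for c in product("ACGT", repeat=3) if sel.translate_codon("".join(c)) != "*"
]


class TestNg86:
    def test_identical_codons(self):
        r = sel.ng86_pairwise("ATG", "ATG")
        assert (r.n_diffs, r.s_diffs) == (0.0, 0.0)
        assert r.dn == 0.0

    def test_single_synonymous_difference(self):
        r = sel.ng86_pairwise("TTT", "TTC")
        assert (r.s_diffs, r.n_diffs) == (1.0, 0.0)
        assert r.s_sites == pytest.approx(1 / 3)

    def test_pathway_averaging_matches_exhaustive_enumeration(self):
        """All 2- and 3-difference sense-codon pairs against the recursive
        oracle (full standard-code sweep)."""
        rng = np.random.default_rng(0)
        pairs = [
            (a, b) for a in SENSE_CODONS for b in SENSE_CODONS
            if sum(x != y for x, y in zip(a, b)) >= 2
        ]
        for a, b in pairs:
            want = oracle_path_counts(a, b)
            got = sel._pathway_diffs(a, b)
            if want is None:
                assert got is None, (a, b)
            else:
                assert got[0] == pytest.approx(want[0]), (a, b)
                assert got[1] == pytest.approx(want[1]), (a, b)

    def test_syn_site_counts_match_direct_tabulation(self):
        # serine TCT: third position fully synonymous, others not
        assert sel._codon_syn_sites("TCT") == pytest.approx(1.0)
        # methionine ATG has no synonymous change at all
        assert sel._codon_syn_sites("ATG") == pytest.approx(0.0)

    def test_length_validation(self):
        with pytest.raises(ValueError):
            sel.ng86_pairwise("ATGA", "ATGA")
        with pytest.raises(ValueError):
            sel.ng86_pairwise("ATG", "ATGATG")


class TestGeneDnds:
    def test_equal_dn_ds_by_construction_gives_ratio_one(self):
        """3 codons with a synonymous diff (TTT/TTC: 1/3 syn site each) plus
        16 with a nonsynonymous diff (AAA/AGA: 1/2 syn site each, since
        AGA's first position is 1/3 synonymous) give pS = 3/9 = pN = 16/48,
        so dN/dS = 1 exactly."""
        ing = "TTT" * 3 + "AAA" * 16
        out = "TTC" * 3 + "AGA" * 16
        r = sel.ng86_pairwise(ing, out)
        assert r.ratio == pytest.approx(1.0)

        m = build_matrix({"A": ing, "B": ing, "O": out})
        gene = sel.GeneModel("g1", 0, len(ing))
        assert sel.gene_dnds(gene, m, ("A", "B")) == pytest.approx(1.0)

    def test_identical_gene_is_skipped(self):
        m = build_matrix({"A": "ATGAAA", "B": "ATGAAA", "O": "ATGAAA"})
        assert sel.gene_dnds(sel.GeneModel("g", 0, 6), m, ("A", "B")) is None

    def test_purely_synonymous_gene_has_ratio_zero(self):
        # identical filler codons keep pS below Jukes-Cantor saturation
        ing = "TTTGGA" + "GGA" * 4
        out = "TTCGGG" + "GGA" * 4
        m = build_matrix({"A": ing, "B": ing, "O": out})
        assert sel.gene_dnds(sel.GeneModel("g", 0, len(ing)), m, ("A", "B")) == 0.0

    def test_minus_strand_gene_uses_reverse_complement(self):
        # gene CAT|GAA on the minus strand appears as TTCATG on the plus
        plus_ing = "TTCATG"
        # reverse complement of plus = CATGAA; an outgroup change of the
        # final plus base T->C is a first-codon-position change in cds
        plus_out = "TTCATA"
        m = build_matrix({"A": plus_ing, "B": plus_ing, "O": plus_out})
        gene = sel.GeneModel("g", 0, 6, strand="-")
        r = sel.gene_dnds(gene, m, ("A", "B"))
        # cds: ing CATGAA vs out TATGAA -> H->Y nonsynonymous, dS = 0
        assert r is None


class TestMkTest:
    def test_g_zero_when_table_proportional(self):
        assert sel.g_statistic(sel.MkTable(5, 5, 5, 5)) == 0.0

    def test_g_matches_hand_formula(self):
        t = sel.MkTable(10, 2, 2, 10)
        obs = t.counts
        exp = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
        assert sel.g_statistic(t) == pytest.approx(2 * (obs * np.log(obs / exp)).sum())

    def test_zero_margin_excluded(self):
        assert sel.g_statistic(sel.MkTable(5, 5, 0, 0)) is None

    def test_g_nonnegative_random_tables(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            t = sel.MkTable(*rng.integers(1, 50, size=4))
            assert sel.g_statistic(t) >= 0

    def test_codon_classification_on_constructed_gene(self):
        # codon 1 GGA/GGG fixed synonymous (Gly); codon 2 ATG vs ACG fixed
        # nonsynonymous (M->T); codon 3 ingroup split TTT/TTC polymorphic
        # synonymous; codon 4 ingroup split AAA/ACA polymorphic nonsynonymous
        m = build_matrix({
            "A": "GGA" + "ATG" + "TTT" + "AAA",
            "B": "GGA" + "ATG" + "TTC" + "ACA",
            "C": "GGA" + "ATG" + "TTT" + "AAA",
            "O": "GGG" + "ACG" + "TTT" + "AAA",
        })
        table, g = sel.mk_test(sel.GeneModel("g", 0, 12), m)
        assert (table.fixed_syn, table.fixed_nonsyn) == (1, 1)
        assert (table.poly_syn, table.poly_nonsyn) == (1, 1)
        assert g == 0.0

    def test_gene_without_polymorphism_has_undefined_g(self):
        m = build_matrix({"A": "GGA", "B": "GGA", "O": "GGG"})
        table, g = sel.mk_test(sel.GeneModel("g", 0, 3), m)
        assert g is None


class TestBonferroni:
    def test_study_threshold(self):
        per, crit = sel.bonferroni_g_threshold(0.05, 606)
        assert per == pytest.approx(8.25e-5, rel=1e-3)
        assert crit == pytest.approx(15.5, abs=0.05)

    def test_single_test_reduces_to_chi_square(self):
        _, crit = sel.bonferroni_g_threshold(0.05, 1)
        assert crit == pytest.approx(3.841, abs=1e-3)

    def test_alpha_near_one_drives_threshold_to_zero(self):
        _, crit = sel.bonferroni_g_threshold(0.9999, 1)
        assert crit < 1e-4


def independent_tajimas_d(hap: np.ndarray):
    """Second implementation straight from the published constant formulas."""
    n, S = hap.shape
    if S == 0:
        return None
    k = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            k += (hap[i] != hap[j]).sum()
    k /= n * (n - 1) / 2
    a1 = sum(1 / i for i in range(1, n))
    a2 = sum(1 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1, e2 = c1 / a1, c2 / (a1**2 + a2)
    return (k - S / a1) / np.sqrt(e1 * S + e2 * S * (S - 1))


def snps_from_hap(hap: np.ndarray) -> list[SnpRecord]:
    out = []
    for j in range(hap.shape[1]):
        alleles = "".join("G" if x else "A" for x in hap[:, j])
        out.append(SnpRecord(
            ref_pos=j, column=j, alleles=alleles, outgroup_allele="A",
            n_alleles=len(set(alleles)), is_polymorphic=len(set(alleles)) > 1,
            is_divergent=False, ancestral="A",
        ))
    return out


class TestTajimasD:
    def test_undefined_without_segregating_sites(self):
        assert sel.tajimas_d(0.0, 0, 10) is None

    def test_hand_computed_four_haplotype_example(self):
        # three singleton SNPs all on one haplotype: pi = 1.5,
        # theta_W = 3/a1 with a1 = 1 + 1/2 + 1/3
        hap = np.zeros((4, 3), dtype=int)
        hap[0] = 1
        pi, S = sel.pairwise_diversity(snps_from_hap(hap), 4)
        assert pi == pytest.approx(1.5)
        a1 = 1 + 0.5 + 1 / 3
        assert pi - S / a1 == pytest.approx(-0.13636, abs=1e-4)
        d = sel.tajimas_d(pi, S, 4)
        assert d == pytest.approx(independent_tajimas_d(hap))

    def test_matches_independent_implementation_on_random_matrices(self):
        rng = np.random.default_rng(12)
        checked = 0
        for _ in range(100):
            n = int(rng.integers(4, 11))   # n = 3 degenerates (variance 0)
            S = int(rng.integers(1, 30))
            hap = (rng.random((n, S)) < rng.uniform(0.1, 0.9)).astype(int)
            seg = hap[:, (hap.any(axis=0)) & (~hap.all(axis=0))]
            if seg.shape[1] == 0:
                continue
            got = sel.tajimas_d_from_snps(snps_from_hap(seg), n)
            assert got == pytest.approx(independent_tajimas_d(seg), rel=1e-9)
            checked += 1
        assert checked >= 80

    def test_neutral_coalescent_mean_near_zero(self, genome216_constant):
        """Per-window D over many independent neutral genealogies averages
        near zero; the ratio form carries a known small negative
        finite-sample bias, so the band is asymmetric."""
        snps = genome216_constant["snps"]
        cfg = genome216_constant["config"]
        ds = []
        for w in genome216_constant["windows"]:
            in_w = [s for s in snps if w.start <= s.ref_pos < w.end and s.is_polymorphic]
            d = sel.tajimas_d_from_snps(in_w, cfg.n_ingroup)
            if d is not None:
                ds.append(d)
        assert len(ds) > 150
        assert -0.4 < np.mean(ds) < 0.1


class TestGeneModels:
    GFF = (
        "##gff-version 3\n"
        "ref\tsrc\tCDS\t101\t190\t.\t+\t0\tID=geneA\n"
        "ref\tsrc\tCDS\t12001\t12300\t.\t-\t0\tID=geneB\n"
    )

    def test_gff3_intervals_strands_and_window_assignment(self, tmp_path):
        gff = tmp_path / "genes.gff3"
        gff.write_text(self.GFF)
        genes = sel.read_gene_models(gff)
        assert [g.gene_id for g in genes] == ["geneA", "geneB"]
        a, b = genes
        assert (a.start, a.end, a.strand) == (100, 190, "+")   # 1-based -> 0-based
        assert (b.start, b.end, b.strand) == (12000, 12300, "-")
        assert a.window_index(10_000) == 0
        assert b.window_index(10_000) == 1
        assert b.window_index(10_000, rule="midpoint") == 1


class TestPermutation:
    def test_zero_permutations_empty_distribution(self):
        res = sel.permute_gene_windows([1.0, 2.0, 3.0], [0, 1, 2],
                                       {0: 5, 1: 6, 2: 7}, n_perm=0)
        assert res["permuted"].size == 0

    def test_regionally_clustered_signal_beats_permutation_null(self):
        rng = np.random.default_rng(9)
        n_win = 20
        metric = {w: float(w) for w in range(n_win)}
        gene_windows = np.repeat(np.arange(n_win), 5)
        gene_values = gene_windows + rng.normal(0, 1.0, size=gene_windows.size)
        res = sel.permute_gene_windows(gene_values, gene_windows, metric,
                                       n_perm=200, seed=17)
        assert res["observed_rho"] > np.quantile(res["permuted"], 0.95)
        assert res["percentile"] > 95
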