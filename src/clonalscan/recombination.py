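"""Homoplasy-based recombinant-SNP detection against a clonal genealogy.

A biallelic site is compatible with purely vertical descent iff its allele
pattern can be produced by a single mutation on a single branch of the clonal
genealogy.  For a rooted strictly bifurcating tree over n strains there are
2n - 2 such patterns when sites are outgroup-polarised (one derived clade per
edge; 18 for n = 10) and 2n - 3 distinct bipartitions when they are not (the
two root-adjacent edges induce the same split).  Sites that fit none of these
patterns are homoplasies, called recombinant SNPs.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import dendropy
import numpy as np

from .alignment import SnpRecord, WindowRow

logger = logging.getLogger(__name__)


class TreeStructureError(ValueError):
    """The clonal genealogy is not a rooted strictly bifurcating tree."""


@dataclass(frozen=True)
class SitePattern:
    """Canonical encoding of an ingroup allele bipartition.

    ``members`` is the derived-allele clade when the site is polarised, and
    the lexicographically smaller side of the split otherwise.
    """

    members: tuple[str, ...]
    polarized: bool

    @classmethod
    def polarised(cls, derived: Iterable[str]) -> "SitePattern":
        return cls(tuple(sorted(derived)), True)

    @classmethod
    def unpolarised(cls, side: Iterable[str], all_ids: Iterable[str]) -> "SitePattern":
        side = frozenset(side)
        other = frozenset(all_ids) - side
        a, b = tuple(sorted(side)), tuple(sorted(other))
        return cls(min(a, b), False)


class ClonalTree:
    """Rooted bifurcating genealogy whose edges define the clonal patterns."""

    def __init__(self, tree: dendropy.Tree, ingroup_ids: Optional[Sequence[str]] = None):
        tree.is_rooted = True
        self.tree = tree
        self.leaf_ids = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
        if ingroup_ids is not None and sorted(ingroup_ids) != self.leaf_ids:
            raise TreeStructureError(
                "tree leaves do not match the alignment ingroup: "
                f"{sorted(ingroup_ids)} vs {self.leaf_ids}"
            )
        for node in tree.preorder_internal_node_iter():
            if len(node.child_nodes()) != 2:
                raise TreeStructureError(
                    f"node with {len(node.child_nodes())} children; tree must be strictly bifurcating"
                )
        # clade (leaf set) below every non-root edge
        self.clades: list[frozenset[str]] = [
            frozenset(lf.taxon.label for lf in node.leaf_iter())
            for node in tree.preorder_node_iter()
            if node is not tree.seed_node
        ]
        if len(self.clades) != 2 * len(self.leaf_ids) - 2:
            raise TreeStructureError("edge count != 2n - 2")

    @classmethod
    def from_newick(cls, source: str | Path, ingroup_ids: Optional[Sequence[str]] = None) -> "ClonalTree":
        src = str(source)
        looks_like_tree = src.lstrip().startswith("(")
        if not looks_like_tree and Path(src).exists():
            tree = dendropy.Tree.get(path=src, schema="newick")
        else:
            tree = dendropy.Tree.get(data=src, schema="newick")
        return cls(tree, ingroup_ids)

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)


def enumerate_single_mutation_patterns(tree: ClonalTree, polarized: bool = True) -> set[SitePattern]:
    """All site patterns explicable by one mutation on one branch.

    Polarised: one derived-clade pattern per edge (2n - 2 of them).
    Unpolarised: one pattern per distinct bipartition (2n - 3; the two
    root-adjacent edges collapse into one split).
    """
    if polarized:
        return {SitePattern.polarised(clade) for clade in tree.clades}
    return {SitePattern.unpolarised(clade, tree.leaf_ids) for clade in tree.clades}


class HomoplasyClassifier:
    """Classify SNPs as clonal or recombinant against a clonal genealogy.

    Outgroup polarisation is used when the outgroup unambiguously matches one
    ingroup allele; otherwise the site falls back to unpolarised bipartition
    matching.  Ingroup columns with >= 3 alleles are excluded (flagged, never
    forced into either class).
    """

    def __init__(self, tree: ClonalTree, ingroup_ids: Sequence[str]):
        if sorted(ingroup_ids) != tree.leaf_ids:
            raise TreeStructureError("classifier ingroup ids do not match tree leaves")
        self.tree = tree
        self.ingroup_ids = list(ingroup_ids)   # matrix row order for SnpRecord.alleles
        self.polarised_patterns = enumerate_single_mutation_patterns(tree, polarized=True)
        self.unpolarised_patterns = enumerate_single_mutation_patterns(tree, polarized=False)

    def classify(self, snp: SnpRecord) -> str:
        """Set and return ``snp.clonal_class``; also records ``snp.pattern``."""
        if not snp.is_polymorphic:
            snp.clonal_class = "unclassified"
            return snp.clonal_class
        if snp.n_alleles >= 3:
            snp.clonal_class = "excluded"
            snp.pattern = None
            return snp.clonal_class
        alleles = snp.alleles
        distinct = sorted(set(alleles))
        if snp.ancestral in distinct:
            derived_allele = distinct[0] if distinct[1] == snp.ancestral else distinct[1]
            pattern = SitePattern.polarised(
                s for s, a in zip(self.ingroup_ids, alleles) if a == derived_allele
            )
            clonal = pattern in self.polarised_patterns
        else:
            pattern = SitePattern.unpolarised(
                (s for s, a in zip(self.ingroup_ids, alleles) if a == distinct[0]),
                self.ingroup_ids,
            )
            clonal = pattern in self.unpolarised_patterns
        snp.pattern = pattern
        snp.clonal_class = "clonal" if clonal else "recombinant"
        return snp.clonal_class

    def classify_all(self, snps: Iterable[SnpRecord]) -> dict[str, int]:
        tally: Counter = Counter(self.classify(s) for s in snps if s.is_polymorphic)
        logger.info("classified SNPs: %s", dict(tally))
        return dict(tally)


def window_recombination(
    windows: Sequence[WindowRow], snps: Sequence[SnpRecord], window_bp: Optional[int] = None
) -> list[WindowRow]:
    """Fill per-window recombinant counts, proportion, and unique recombinant
    topology counts (distinct patterns among the window's recombinant SNPs).

    Excluded (multi-allelic) SNPs are omitted from both terms of the
    proportion; windows with zero classifiable SNPs report it as missing.
    """
    if window_bp is None:
        window_bp = windows[0].end - windows[0].start if windows else 0
    per_window: dict[int, list[SnpRecord]] = {}
    for snp in snps:
        if snp.ref_pos >= 0 and snp.is_polymorphic:
            per_window.setdefault(snp.ref_pos // window_bp, []).append(snp)
    for row in windows:
        ws = per_window.get(row.index, [])
        row.n_clonal = sum(1 for s in ws if s.clonal_class == "clonal")
        row.n_recombinant = sum(1 for s in ws if s.clonal_class == "recombinant")
        row.n_excluded = sum(1 for s in ws if s.clonal_class == "excluded")
        classifiable = row.n_clonal + row.n_recombinant
        row.recombinant_proportion = (
            row.n_recombinant / classifiable if classifiable else None
        )
        rec_patterns = {s.pattern for s in ws if s.clonal_class == "recombinant"}
        row.n_unique_topologies = len(rec_patterns)
        row.unique_topologies_per_snp = (
            len(rec_patterns) / classifiable if classifiable else None
        )
    return list(windows)


def expected_double_hit_homoplasies(
    total_snps: int,
    core_length: int,
    tree: ClonalTree,
    n_reps: int = 100,
    seed: int | np.random.Generator = 0,
    outgroup: Optional[str] = None,
) -> float:
    """Monte-Carlo expectation of multi-hit sites that look recombinant.

    Places ``total_snps`` mutations uniformly over ``core_length`` sites and
    branch-length-proportionally over the genealogy's edges, resolves each
    multiply hit site's alleles (each mutation replaces the current state
    with one of the other three bases, uniformly), and counts sites whose
    resulting ingroup pattern would be classified recombinant.

    When ``outgroup`` names a leaf of ``tree``, the tree should be the full
    genealogy including the outgroup: mutations then also land on the deep
    outgroup path, and each multi-hit site is classified exactly as the
    pipeline would (outgroup polarisation when the outgroup allele matches
    one ingroup allele, bipartition matching otherwise).  This captures
    mispolarisation by parallel outgroup-branch mutations, the dominant
    double-hit artifact when divergence is high.  Without ``outgroup`` the
    tree is treated as ingroup-only and the root state polarises.

    An analytic upper bound on multi-hit sites is the birthday term
    S(S-1)/(2L).
    """
    if total_snps <= 1 or core_length <= 0:
        return 0.0
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    nodes = [nd for nd in tree.tree.preorder_node_iter() if nd is not tree.tree.seed_node]
    lengths = np.array([nd.edge.length or 0.0 for nd in nodes], dtype=float)
    if lengths.sum() <= 0:
        lengths = np.ones(len(nodes))
    probs = lengths / lengths.sum()
    leaf_index = {lbl: i for i, lbl in enumerate(tree.leaf_ids)}
    clade_idx = [
        np.array([leaf_index[lf.taxon.label] for lf in nd.leaf_iter()]) for nd in nodes
    ]
    n = tree.n_leaves

    if outgroup is not None:
        if outgroup not in leaf_index:
            raise ValueError(f"outgroup {outgroup!r} is not a leaf of the tree")
        ingroup_tree = ClonalTree(
            tree.tree.extract_tree_without_taxa_labels([outgroup])
        )
        out_idx = leaf_index[outgroup]
        ing_idx = np.array([i for i in range(n) if i != out_idx])
        ing_ids = [tree.leaf_ids[i] for i in ing_idx]
        pol_set = {SitePattern.polarised(c) for c in ingroup_tree.clades}
        unpol_set = {SitePattern.unpolarised(c, ing_ids) for c in ingroup_tree.clades}
    else:
        out_idx = None
        ing_idx = np.arange(n)
        ing_ids = list(tree.leaf_ids)
        pol_set = {SitePattern.polarised(c) for c in tree.clades}
        unpol_set = {SitePattern.unpolarised(c, ing_ids) for c in tree.clades}

    total = 0
    for _ in range(n_reps):
        sites = rng.integers(core_length, size=total_snps)
        _, counts = np.unique(sites, return_counts=True)
        for hits in counts[counts >= 2]:
            edges = rng.choice(len(nodes), size=int(hits), p=probs)
            edges.sort()                       # preorder rank: ancestors first
            states = np.zeros(n, dtype=np.int64)
            for e in edges:
                idx = clade_idx[e]
                cur = states[idx[0]]
                new = (cur + 1 + rng.integers(3)) % 4
                states[idx] = new
            ing_states = states[ing_idx]
            alleles = np.unique(ing_states)
            if alleles.size != 2:
                continue                       # monomorphic or >= 3 alleles: never called
            ancestral = int(states[out_idx]) if out_idx is not None else 0
            if ancestral in alleles:           # polarisable
                derived = [s for s, v in zip(ing_ids, ing_states) if v != ancestral]
                clonal = SitePattern.polarised(derived) in pol_set
            else:
                side = [s for s, v in zip(ing_ids, ing_states) if v == alleles[0]]
                clonal = SitePattern.unpolarised(side, ing_ids) in unpol_set
            if not clonal:
                total += 1
    return total / n_reps
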