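"""Per-gene selection statistics over the core alignment.

* Nei–Gojobori (1986) pairwise dN/dS with pathway averaging for
  multi-difference codons and Jukes–Cantor distance correction, computed for
  two representative ingroup strains against the outgroup and averaged;
* McDonald–Kreitman 2x2 tables (fixed/polymorphic x synonymous/
  nonsynonymous) from direct codon analysis of the whole-genome alignment,
  tested with the G statistic (1 df) under a Bonferroni family threshold;
* Tajima's D from the ingroup SNPs of a gene or window.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import permutations
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats as sps
from Bio.Data import CodonTable

from .alignment import AlignmentMatrix, SnpRecord, decode_sequence
from .stats import spearman

logger = logging.getLogger(__name__)

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
CODON_TO_AA: dict[str, str] = dict(_STANDARD.forward_table)
for _stop in _STANDARD.stop_codons:
    CODON_TO_AA[_stop] = "*"
BASES = "ACGT"


def translate_codon(codon: str) -> str:
    return CODON_TO_AA[codon.upper()]


@dataclass
class GeneModel:
    """A protein-coding gene interval on reference coordinates."""

    gene_id: str
    start: int          # 0-based half-open on the reference
    end: int
    strand: str = "+"
    frame: int = 0

    def window_index(self, window_bp: int, rule: str = "start") -> int:
        if rule == "midpoint":
            return ((self.start + self.end) // 2) // window_bp
        return self.start // window_bp


def read_gene_models(gff_path: str | Path, feature_types: Sequence[str] = ("CDS",)) -> list[GeneModel]:
    """Load gene models from a GFF3 file on reference coordinates."""
    import gffutils

    db = gffutils.create_db(
        str(gff_path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes = []
    for ftype in feature_types:
        for feat in db.features_of_type(ftype):
            frame = int(feat.frame) if feat.frame not in (None, ".") else 0
            genes.append(
                GeneModel(gene_id=feat.id, start=feat.start - 1, end=feat.end,
                          strand=feat.strand or "+", frame=frame)
            )
    genes.sort(key=lambda g: g.start)
    return genes


# ---------------------------------------------------------------------------
# Nei–Gojobori pairwise dN/dS
# ---------------------------------------------------------------------------


@dataclass
class NgResult:
    n_sites: float
    s_sites: float
    n_diffs: float
    s_diffs: float
    dn: Optional[float]
    ds: Optional[float]

    @property
    def ratio(self) -> Optional[float]:
        if self.dn is None or self.ds is None or self.ds == 0:
            return None
        return self.dn / self.ds


def _codon_syn_sites(codon: str) -> float:
    """Synonymous site count of one codon: at each position, the fraction of
    the three possible changes that preserve the amino acid.  Changes creating
    a stop codon count as nonsynonymous."""
    aa = translate_codon(codon)
    s = 0.0
    for pos in range(3):
        for b in BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if translate_codon(alt) == aa:
                s += 1.0 / 3.0
    return s


def _pathway_diffs(codon_a: str, codon_b: str) -> Optional[tuple[float, float]]:
    """(syn, nonsyn) difference counts averaged over all minimal mutational
    pathways between two codons; pathways through stop codons are excluded.
    Returns None if every pathway is blocked."""
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_pos:
        return (0.0, 0.0)
    totals = []
    for order in permutations(diff_pos):
        cur = codon_a
        syn = nonsyn = 0
        ok = True
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
            if translate_codon(nxt) == "*":
                ok = False
                break
            if translate_codon(nxt) == translate_codon(cur):
                syn += 1
            else:
                nonsyn += 1
            cur = nxt
        if ok:
            totals.append((syn, nonsyn))
    if not totals:
        return None
    s = sum(t[0] for t in totals) / len(totals)
    n = sum(t[1] for t in totals) / len(totals)
    return (s, n)


def jukes_cantor(p: float) -> Optional[float]:
    """JC-corrected distance from a difference proportion; None at saturation."""
    if p == 0:
        return 0.0
    if p >= 0.75:
        return None
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def ng86_pairwise(seq_a: str, seq_b: str) -> NgResult:
    """Nei–Gojobori (1986) counts and JC-corrected dN, dS for two aligned,
    gap-free coding sequences.

    Codons containing ambiguity in either sequence, stop codons, and codon
    pairs whose every mutational pathway crosses a stop are skipped pairwise.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must be equal length")
    if len(seq_a) % 3:
        raise ValueError("sequence length must be a multiple of 3")
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    s_sites = n_sites = s_diffs = n_diffs = 0.0
    for i in range(0, len(seq_a), 3):
        ca, cb = seq_a[i : i + 3], seq_b[i : i + 3]
        if any(ch not in BASES for ch in ca + cb):
            continue
        if translate_codon(ca) == "*" or translate_codon(cb) == "*":
            continue
        path = _pathway_diffs(ca, cb)
        if path is None:
            continue
        s_codon = (_codon_syn_sites(ca) + _codon_syn_sites(cb)) / 2.0
        s_sites += s_codon
        n_sites += 3.0 - s_codon
        s_diffs += path[0]
        n_diffs += path[1]
    ds = jukes_cantor(s_diffs / s_sites) if s_sites > 0 else None
    dn = jukes_cantor(n_diffs / n_sites) if n_sites > 0 else None
    return NgResult(n_sites, s_sites, n_diffs, s_diffs, dn, ds)


def _gene_coding_columns(
    gene: GeneModel, matrix: AlignmentMatrix, strain_ids: Sequence[str]
) -> Optional[np.ndarray]:
    """Per-strain coding sequences over the gene's reference span, keeping
    only codons at which every requested strain has a real base.

    Returns a (n_strains, 3*k) uint8 matrix in coding orientation, or None
    when no clean codon survives.
    """
    start = gene.start + (gene.frame if gene.strand == "+" else 0)
    end = gene.end - (gene.frame if gene.strand == "-" else 0)
    span = end - start
    span -= span % 3
    if span < 3:
        return None
    cols = matrix.col_of_ref[start : start + span]
    rows = np.stack([matrix.row(s)[cols] for s in strain_ids])
    if gene.strand == "-":
        rows = rows[:, ::-1].copy()
        comp = np.array([3, 2, 1, 0, 4, 5], dtype=np.uint8)   # A<->T, C<->G
        rows = comp[rows]
    k = rows.shape[1] // 3
    codons = rows.reshape(rows.shape[0], k, 3)
    clean = np.all(codons < 4, axis=(0, 2))
    if not clean.any():
        return None
    return codons[:, clean, :].reshape(rows.shape[0], -1)


def gene_dnds(
    gene: GeneModel,
    matrix: AlignmentMatrix,
    rep_strains: tuple[str, str],
    outgroup_id: Optional[str] = None,
) -> Optional[float]:
    """Mean of the two representative-strain vs outgroup dN/dS ratios.

    Returns None when the gene has no clean codons or either comparison has
    dS = 0 / is saturated (logged and skipped).
    """
    outgroup_id = outgroup_id or matrix.outgroup_id
    rows = _gene_coding_columns(gene, matrix, list(rep_strains) + [outgroup_id])
    if rows is None:
        logger.info("gene %s: no aligned clean codons; skipped", gene.gene_id)
        return None
    out_seq = decode_sequence(rows[-1])
    ratios = []
    for i, strain in enumerate(rep_strains):
        res = ng86_pairwise(decode_sequence(rows[i]), out_seq)
        if res.ratio is None:
            logger.info("gene %s vs %s: dN/dS undefined (dS=0 or saturated)", gene.gene_id, strain)
            return None
        ratios.append(res.ratio)
    return float(np.mean(ratios))


# ---------------------------------------------------------------------------
# McDonald–Kreitman test
# ---------------------------------------------------------------------------


@dataclass
class MkTable:
    fixed_syn: int = 0
    fixed_nonsyn: int = 0
    poly_syn: int = 0
    poly_nonsyn: int = 0

    @property
    def counts(self) -> np.ndarray:
        return np.array(
            [[self.fixed_syn, self.fixed_nonsyn], [self.poly_syn, self.poly_nonsyn]], dtype=float
        )

    @property
    def has_zero_margin(self) -> bool:
        c = self.counts
        return bool((c.sum(axis=0) == 0).any() or (c.sum(axis=1) == 0).any())


def g_statistic(table: MkTable) -> Optional[float]:
    """Log-likelihood-ratio G = 2 sum O ln(O/E), 1 df, no Williams correction.

    Undefined (None) when any row or column margin is zero.
    """
    if table.has_zero_margin:
        return None
    obs = table.counts
    exp = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / obs.sum()
    nz = obs > 0
    return float(2.0 * (obs[nz] * np.log(obs[nz] / exp[nz])).sum())


def mk_test(
    gene: GeneModel, matrix: AlignmentMatrix, outgroup_id: Optional[str] = None
) -> tuple[MkTable, Optional[float]]:
    """MK contingency table from direct analysis of individual codons.

    A variant codon position is *fixed* when the ingroup is monomorphic and
    differs from the outgroup, *polymorphic* when the ingroup varies.  The
    synonymous/nonsynonymous call translates the most common ingroup codon
    with each allele substituted at the focal position.
    """
    outgroup_id = outgroup_id or matrix.outgroup_id
    strains = matrix.ingroup_ids + [outgroup_id]
    rows = _gene_coding_columns(gene, matrix, strains)
    table = MkTable()
    if rows is None:
        return table, None
    n_codons = rows.shape[1] // 3
    ing = rows[:-1].reshape(len(strains) - 1, n_codons, 3)
    out = rows[-1].reshape(n_codons, 3)
    for c in range(n_codons):
        codons = ["".join(BASES[b] for b in ing[s, c]) for s in range(ing.shape[0])]
        context = min(sorted(set(codons)), key=lambda x: (-codons.count(x), x))
        for pos in range(3):
            alleles = sorted({cd[pos] for cd in codons})
            variants = lambda allele: context[:pos] + allele + context[pos + 1 :]
            if len(alleles) >= 2:
                aas = {translate_codon(variants(a)) for a in alleles}
                if len(aas) == 1:
                    table.poly_syn += 1
                else:
                    table.poly_nonsyn += 1
            else:
                out_base = BASES[out[c, pos]]
                if out_base != alleles[0]:
                    if translate_codon(variants(out_base)) == translate_codon(context):
                        table.fixed_syn += 1
                    else:
                        table.fixed_nonsyn += 1
    return table, g_statistic(table)


def bonferroni_g_threshold(alpha: float = 0.05, m: int = 1) -> tuple[float, float]:
    """Per-test alpha and the matching chi-square(1 df) critical G for a
    Bonferroni family-wise correction over ``m`` tested genes."""
    if m < 1:
        raise ValueError("m must be >= 1")
    per_test = alpha / m
    return per_test, float(sps.chi2.isf(per_test, df=1))


# ---------------------------------------------------------------------------
# Tajima's D
# ---------------------------------------------------------------------------


def tajima_constants(n: int) -> dict[str, float]:
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n**2 + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1**2
    return {
        "a1": a1, "a2": a2, "b1": b1, "b2": b2,
        "c1": c1, "c2": c2, "e1": c1 / a1, "e2": c2 / (a1**2 + a2),
    }


def tajimas_d(pi: float, n_segregating: int, n_haplotypes: int) -> Optional[float]:
    """Tajima's (1989) D from mean pairwise diversity and segregating sites.

    None when S = 0 (the statistic is undefined).
    """
    if n_haplotypes < 2:
        raise ValueError("need >= 2 haplotypes")
    S = n_segregating
    if S < 1:
        return None
    k = tajima_constants(n_haplotypes)
    var = k["e1"] * S + k["e2"] * S * (S - 1)
    if var <= 0:
        # the variance estimate degenerates to 0 at n = 3 (c1 = c2 = 0)
        return None
    return float((pi - S / k["a1"]) / math.sqrt(var))


def pairwise_diversity(snps: Iterable[SnpRecord], n_haplotypes: int) -> tuple[float, int]:
    """(pi, S): mean pairwise difference count and segregating sites from
    ingroup-polymorphic SNP records (gap-free ingroup columns)."""
    total_pairs = n_haplotypes * (n_haplotypes - 1) / 2.0
    pi = 0.0
    S = 0
    for snp in snps:
        if not snp.is_polymorphic:
            continue
        S += 1
        counts = [snp.alleles.count(b) for b in set(snp.alleles)]
        diff_pairs = sum(
            ci * cj for i, ci in enumerate(counts) for cj in counts[i + 1 :]
        )
        pi += diff_pairs / total_pairs
    return pi, S


def tajimas_d_from_snps(snps: Iterable[SnpRecord], n_haplotypes: int) -> Optional[float]:
    pi, S = pairwise_diversity(snps, n_haplotypes)
    return tajimas_d(pi, S, n_haplotypes)


# ---------------------------------------------------------------------------
# Gene-window permutation
# ---------------------------------------------------------------------------


def permute_gene_windows(
    gene_values: Sequence[float],
    gene_windows: Sequence[int],
    window_metric: dict[int, float],
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
) -> dict:
    """Null distribution of the window-level dN/dS ~ polymorphism rank
    correlation under random reassignment of genes to windows.

    Returns the observed rho, the permuted rho array, and the observed
    value's percentile within the permuted distribution.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    values = np.asarray(gene_values, dtype=float)
    assign = np.asarray(gene_windows)

    def window_rho(assignment: np.ndarray) -> float:
        sums: dict[int, list[float]] = {}
        for v, w in zip(values, assignment):
            sums.setdefault(int(w), []).append(v)
        ws = [w for w in sums if w in window_metric]
        if len(ws) < 3:
            return float("nan")
        rho, _ = spearman(
            [float(np.mean(sums[w])) for w in ws], [window_metric[w] for w in ws]
        )
        return rho

    observed = window_rho(assign)
    perm = np.empty(n_perm)
    for i in range(n_perm):
        perm[i] = window_rho(rng.permutation(assign))
    pct = float((perm < observed).mean() * 100.0) if n_perm else float("nan")
    return {"observed_rho": observed, "permuted": perm, "percentile": pct}
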