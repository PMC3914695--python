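"""End-to-end orchestration: simulate and/or analyze a dataset.

``run_analyze`` sequences the whole method over one core-genome alignment:
SNP and divergence calling → 10-kb windows with gap filtering and
back-mutation correction → homoplasy classification against the clonal
genealogy → binomial expectation bands → low-recombination zones with LD and
fixed-zone status → per-gene selection statistics → genome-wide summary.

``run_simulate`` writes a synthetic dataset with truth; ``run_both`` runs the
analysis on it, classifying each window's SNPs against its true genealogy,
and emits a truth-vs-called comparison for injected recombinant columns.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__, alignment as aln, lrz as lrzmod, recombination as rec
from . import selection as sel, simulate as sim, stats as st

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    mode: str = "both"                  # analyze | simulate | both
    alignment: Optional[str] = None
    tree: Optional[str] = None
    gff: Optional[str] = None
    partition: Optional[str] = None     # strain<TAB>group, two groups
    reference_id: Optional[str] = None
    outgroup_id: Optional[str] = None
    window_bp: int = 10_000
    gap_cap_bp: int = 5_000
    exclude_intervals: list = field(default_factory=list)
    min_run: int = 31
    conf: float = 0.95
    alpha: float = 0.05
    rep_strains: Optional[list] = None  # two ingroup strains for dN/dS
    gene_window_rule: str = "start"
    zns_sims: int = 200                 # per-LRZ LD null replicates; 0 disables
    seed: int = 0
    out_dir: str = "clonalscan_out"
    sim: sim.SimConfig = field(default_factory=sim.SimConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim_raw = raw.pop("sim", {})
        tracts = [sim.TractSpec(**t) for t in sim_raw.pop("recombination_events", [])]
        gaps = [tuple(g) for g in sim_raw.pop("gap_spec", [])]
        sim_cfg = sim.SimConfig(recombination_events=tuple(tracts), gap_spec=tuple(gaps), **sim_raw)
        return cls(sim=sim_cfg, **raw)

    def digest(self) -> str:
        enc = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(enc.encode()).hexdigest()[:12]


def _provenance(config: RunConfig) -> str:
    return f"# clonalscan v{__version__} seed={config.seed} config={config.digest()}\n"


def _write_tsv(df: pd.DataFrame, path: Path, config: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance(config))
        df.to_csv(fh, sep="\t", index=False)


def read_partition(path: str | Path) -> dict[str, str]:
    out = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        strain, group = line.split("\t")
        out[strain] = group
    return out


def run_simulate(config: RunConfig) -> dict:
    out = Path(config.out_dir)
    matrix, truth = sim.simulate_dataset(config.sim)
    paths = sim.write_dataset(matrix, truth, out / "simulated")
    logger.info("simulated %d windows x %d bp, %d strains",
                config.sim.n_windows, config.sim.window_length_bp, len(matrix.ids))
    return {"matrix": matrix, "truth": truth, "paths": paths}


def run_analyze(
    config: RunConfig,
    matrix: Optional[aln.AlignmentMatrix] = None,
    truth: Optional[sim.SimTruth] = None,
) -> dict:
    """Run the full analysis; returns the summary dict (also written as JSON).

    When ``truth`` is supplied (simulation mode), each window's SNPs are
    classified against that window's true genealogy; otherwise the single
    clonal genealogy from ``config.tree`` is used genome-wide.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=config.seed, spawn_key=(99,)))

    if matrix is None:
        if not config.alignment:
            raise ValueError("analyze mode requires an alignment path")
        matrix = aln.read_alignment(config.alignment, config.reference_id, config.outgroup_id)
    ingroup_ids = matrix.ingroup_ids
    logger.info("alignment: %d strains x %d columns", len(matrix.ids), matrix.n_columns)

    snps, core_mask = aln.extract_core_and_snps(matrix)
    windows = aln.make_windows(
        matrix, snps, core_mask, config.window_bp, config.gap_cap_bp,
        [tuple(iv) for iv in config.exclude_intervals],
    )
    logger.info("%d SNP records, %d/%d windows analyzed",
                len(snps), sum(w.analyzed for w in windows), len(windows))

    # --- homoplasy classification -----------------------------------------
    if truth is not None:
        classifiers = {}
        for w, newick in enumerate(truth.genealogies):
            full = rec.ClonalTree.from_newick(newick)
            ingroup = sim.ingroup_subtree(full.tree, matrix.outgroup_id)
            classifiers[w] = rec.HomoplasyClassifier(rec.ClonalTree(ingroup), ingroup_ids)
        for snp in snps:
            if snp.is_polymorphic and snp.ref_pos >= 0:
                classifiers[snp.ref_pos // config.window_bp].classify(snp)
        tree_used = "per-window truth genealogies"
    elif config.tree:
        ctree = rec.ClonalTree.from_newick(config.tree, ingroup_ids)
        clf = rec.HomoplasyClassifier(ctree, ingroup_ids)
        clf.classify_all(snps)
        tree_used = str(config.tree)
    else:
        raise ValueError("analyze mode requires a clonal genealogy (tree) or simulation truth")
    rec.window_recombination(windows, snps, config.window_bp)

    poly_snps = [s for s in snps if s.is_polymorphic]
    n_clonal = sum(1 for s in poly_snps if s.clonal_class == "clonal")
    n_recomb = sum(1 for s in poly_snps if s.clonal_class == "recombinant")
    n_excl = sum(1 for s in poly_snps if s.clonal_class == "excluded")
    q = n_recomb / (n_clonal + n_recomb) if (n_clonal + n_recomb) else float("nan")

    # --- binomial expectation bands ---------------------------------------
    analyzed = [w for w in windows if w.analyzed]
    band_summaries = {}
    if analyzed:
        poly_classes, band_summaries["polymorphism"] = st.classify_windows(
            [w.n_polymorphic for w in analyzed], [w.core_sites for w in analyzed], conf=config.conf
        )
        div_classes, band_summaries["divergence"] = st.classify_windows(
            [w.n_divergent for w in analyzed], [w.core_sites for w in analyzed], conf=config.conf
        )
        rec_ns = [(w.n_clonal or 0) + (w.n_recombinant or 0) for w in analyzed]
        rec_vals = [w.n_recombinant or 0 for w in analyzed]
        keep = [i for i, n in enumerate(rec_ns) if n >= 1]
        rec_classes, band_summaries["recombination"] = st.classify_windows(
            [rec_vals[i] for i in keep], [rec_ns[i] for i in keep],
            p=q if np.isfinite(q) else 0.0, conf=config.conf,
        )
        for w, pc, dc in zip(analyzed, poly_classes, div_classes):
            w.poly_band, w.div_band = pc, dc
        for i, rc in zip(keep, rec_classes):
            analyzed[i].recomb_band = rc

    # --- low recombination zones ------------------------------------------
    core_at_ref = np.zeros(matrix.reference_length, dtype=bool)
    core_at_ref[matrix.ref_coords[matrix.col_of_ref]] = core_mask[matrix.col_of_ref]
    zones = lrzmod.find_lrzs(snps, config.min_run)
    genome_rate = (
        sum(1 for s in poly_snps if s.clonal_class == "clonal") / core_at_ref.sum()
        if core_at_ref.any() else 0.0
    )
    partition = read_partition(config.partition) if config.partition else None
    for z in zones:
        lrzmod.lrz_stats(z, core_at_ref, genome_rate, config.conf)
        lrzmod.fixed_zone_flag(z, partition, ingroup_ids)
        if config.zns_sims > 0 and len(z.snps) >= 2:
            hap = np.array(
                [[s.alleles[i] for s in z.snps] for i in range(len(ingroup_ids))], dtype="U1"
            )
            # site columns must be biallelic; excluded SNPs never enter zones
            z.zns = st.kellys_zns(hap)
            z.zns_p, _ = st.zns_significance(
                z.zns, len(ingroup_ids), len(z.snps), n_sims=config.zns_sims,
                seed=rng, subpop_sizes=_partition_sizes(partition, ingroup_ids),
                subpop_split_time=config.sim.subpop_split_time,
            )
    zns_ps = [z.zns_p for z in zones if z.zns_p is not None]
    if zns_ps:
        for z, adj in zip([z for z in zones if z.zns_p is not None], st.bh_fdr(zns_ps)):
            z.zns_q = float(adj)
    size_rho = lrzmod.size_polymorphism_correlation(zones)

    # --- selection ---------------------------------------------------------
    genes_df = None
    gene_summary = {}
    if config.gff:
        genes = sel.read_gene_models(config.gff)
        rep = tuple(config.rep_strains) if config.rep_strains else tuple(ingroup_ids[:2])
        rows = []
        snps_by_gene = _snps_in_intervals(poly_snps, [(g.start, g.end) for g in genes])
        for g, gsnps in zip(genes, snps_by_gene):
            table, gstat = sel.mk_test(g, matrix)
            rows.append({
                "gene_id": g.gene_id, "start": g.start, "end": g.end, "strand": g.strand,
                "window": g.window_index(config.window_bp, config.gene_window_rule),
                "dnds": sel.gene_dnds(g, matrix, rep),
                "mk_fixed_syn": table.fixed_syn, "mk_fixed_nonsyn": table.fixed_nonsyn,
                "mk_poly_syn": table.poly_syn, "mk_poly_nonsyn": table.poly_nonsyn,
                "mk_g": gstat,
                "tajimas_d": sel.tajimas_d_from_snps(gsnps, len(ingroup_ids)),
            })
        genes_df = pd.DataFrame(rows)
        tested = genes_df["mk_g"].notna().sum()
        if tested:
            per_alpha, crit = sel.bonferroni_g_threshold(config.alpha, int(tested))
            gene_summary = {
                "n_genes": len(genes), "n_mk_tested": int(tested),
                "bonferroni_per_test_alpha": per_alpha, "critical_g": crit,
                "n_mk_significant": int((genes_df["mk_g"] > crit).sum()),
            }

    # --- genome-wide statistics --------------------------------------------
    poly = [w.n_polymorphic for w in analyzed]
    summary = {
        "version": __version__, "seed": config.seed, "config": config.digest(),
        "tree": tree_used,
        "n_snp_records": len(snps),
        "n_polymorphic": len(poly_snps),
        "n_divergent": sum(1 for s in snps if s.is_divergent),
        "n_clonal": n_clonal, "n_recombinant": n_recomb, "n_excluded_multiallelic": n_excl,
        "recombinant_fraction": q,
        "n_windows": len(windows), "n_windows_analyzed": len(analyzed),
        "min_run": config.min_run,
        "run_null_p_at_min_run": lrzmod.run_null_probability(q, config.min_run)
        if np.isfinite(q) else None,
        "run_null_p_at_min_run_minus_1": lrzmod.run_null_probability(q, config.min_run - 1)
        if np.isfinite(q) else None,
        "n_lrz": len(zones),
        "lrz_sizes_bp": [z.span_bp for z in zones],
        "lrz_size_poly_rho": size_rho[0], "lrz_size_poly_p": size_rho[1],
        "bands": band_summaries,
        "genes": gene_summary,
    }
    if len(analyzed) >= 3:
        rho, p = st.spearman([w.n_divergent for w in analyzed], poly)
        summary["divergence_polymorphism_rho"], summary["divergence_polymorphism_p"] = rho, p
        props = [w.recombinant_proportion for w in analyzed]
        if sum(v is not None for v in props) >= 3:
            rho, p = st.spearman(props, poly)
            summary["recombination_polymorphism_rho"], summary["recombination_polymorphism_p"] = rho, p
            rho, p = st.spearman([w.unique_topologies_per_snp for w in analyzed], poly)
            summary["topologies_polymorphism_rho"], summary["topologies_polymorphism_p"] = rho, p
    wilc = _mutagenic_recombination_test(poly_snps)
    summary["wilcoxon_1kb_p"] = wilc

    # --- outputs ------------------------------------------------------------
    _write_tsv(_windows_frame(windows), out / "windows.tsv", config)
    _write_tsv(_snps_frame(snps), out / "snps.tsv", config)
    _write_tsv(_lrz_frame(zones), out / "lrz.tsv", config)
    with open(out / "lrz.bed", "w") as fh:
        for z in zones:
            fh.write(f"ref\t{z.start}\t{z.end}\tLRZ_{z.start}\t{z.run_length}\n")
    if genes_df is not None:
        _write_tsv(genes_df, out / "genes.tsv", config)
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, default=_jsonable)
    summary["_windows"] = windows
    summary["_snps"] = snps
    summary["_zones"] = zones
    summary["_genes"] = genes_df
    return summary


def run_both(config: RunConfig) -> dict:
    """Simulate, analyze against truth genealogies, and compare homoplasy
    calls with the injected-tract registry (recall/precision)."""
    bundle = run_simulate(config)
    summary = run_analyze(config, matrix=bundle["matrix"], truth=bundle["truth"])
    truth = bundle["truth"]
    truth_cols = {r["column"] for r in truth.tract_registry}
    called = {
        s.column for s in summary["_snps"]
        if s.clonal_class == "recombinant" and s.ref_pos >= 0
    }
    if truth_cols:
        homoplasic = {
            r["column"] for r in truth.tract_registry if r.get("homoplasic")
        }
        tp = len(called & truth_cols)
        comparison = {
            "n_truth_columns": len(truth_cols),
            "n_truth_homoplasic": len(homoplasic),
            "n_called": len(called),
            "true_positives": tp,
            "recall": tp / len(truth_cols),
            "recall_homoplasic": len(called & homoplasic) / len(homoplasic)
            if homoplasic else None,
            "precision": tp / len(called) if called else None,
        }
        summary["tract_recovery"] = comparison
        pd.DataFrame([comparison]).to_csv(
            Path(config.out_dir) / "tract_recovery.tsv", sep="\t", index=False
        )
    return summary


# ---------------------------------------------------------------------------


def _partition_sizes(partition, ingroup_ids) -> Optional[tuple[int, int]]:
    if not partition:
        return None
    groups = sorted(set(partition.values()))
    return tuple(sum(1 for s in ingroup_ids if partition[s] == g) for g in groups)


def _mutagenic_recombination_test(poly_snps, bin_bp: int = 1000) -> Optional[float]:
    """Paired Wilcoxon of recombinant vs nonrecombinant counts over 1-kb bins
    that contain at least one recombinant SNP."""
    recs: dict[int, int] = {}
    nonrecs: dict[int, int] = {}
    for s in poly_snps:
        if s.ref_pos < 0:
            continue
        b = s.ref_pos // bin_bp
        if s.clonal_class == "recombinant":
            recs[b] = recs.get(b, 0) + 1
        elif s.clonal_class == "clonal":
            nonrecs[b] = nonrecs.get(b, 0) + 1
    bins = sorted(recs)
    if not bins:
        return None
    return st.wilcoxon_paired(
        [recs[b] for b in bins], [nonrecs.get(b, 0) for b in bins]
    )


def _snps_in_intervals(snps, intervals):
    out = []
    for start, end in intervals:
        out.append([s for s in snps if start <= s.ref_pos < end])
    return out


def _windows_frame(windows) -> pd.DataFrame:
    cols = [f.name for f in dataclasses.fields(aln.WindowRow)]
    df = pd.DataFrame([{c: getattr(w, c) for c in cols} for w in windows])
    df["start_1based"] = df["start"] + 1   # reports are 1-based inclusive
    return df


def _snps_frame(snps) -> pd.DataFrame:
    rows = []
    for s in snps:
        rows.append({
            "ref_pos": s.ref_pos, "ref_pos_1based": s.ref_pos + 1, "column": s.column,
            "alleles": s.alleles, "outgroup": s.outgroup_allele, "n_alleles": s.n_alleles,
            "polymorphic": s.is_polymorphic, "divergent": s.is_divergent,
            "ancestral": s.ancestral or ".", "clonal_class": s.clonal_class,
            "pattern": "|".join(s.pattern.members) if s.pattern else ".",
        })
    return pd.DataFrame(rows)


def _lrz_frame(zones) -> pd.DataFrame:
    rows = []
    for z in zones:
        rows.append({
            "start": z.start, "end": z.end, "start_1based": z.start + 1,
            "span_bp": z.span_bp, "run_length": z.run_length,
            "core_length": z.core_length, "n_polymorphisms": z.n_polymorphisms,
            "poly_level": z.poly_level, "poly_class": z.poly_class,
            "zns": z.zns, "zns_p": z.zns_p, "zns_q": getattr(z, "zns_q", None),
            "fixed_zone": z.fixed_zone,
        })
    return pd.DataFrame(rows)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return str(obj)
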