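"""Synthetic whole-genome alignments with known truth.

Emulates the study design used to test mutation-rate hypotheses: 10 ingroup
haplotypes plus 1 deeply diverged outgroup, sampled from a neutral coalescent
with a population split placing the outgroup lineage at time 30 (in units of
4N generations, the ``ms`` convention, so a split parameter of 30 matches
``-ej 30 1 2``), sequences evolved under HKY at a per-window substitution
rate that is either constant (0.0018/site) or cycles through
{0.001, 0.002, 0.003}/site.

Extensions beyond that design, used only to validate downstream detectors and
off by default: donor-tract replacement (recombination with a known column
registry), alignment gaps, and a shared clonal genealogy across windows so
that injected tracts are the only source of homoplasy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import dendropy
import msprime
import numpy as np

from .alignment import AlignmentMatrix, GAP

EQUAL_FREQS = (0.25, 0.25, 0.25, 0.25)


class ConfigError(ValueError):
    """A simulation configuration field is invalid."""


@dataclass(frozen=True)
class TractSpec:
    """A donor→recipient replacement tract (0-based, length in bp)."""

    donor: str
    recipient: str
    start: int
    length: int


@dataclass
class SimConfig:
    n_ingroup: int = 10
    split_time: float = 30.0          # outgroup merge time, units of 4N generations
    subpop_sizes: tuple[int, int] = (5, 5)
    subpop_split_time: float = 0.0    # 0 = panmictic ingroup (the default design)
    window_length_bp: int = 10_000
    n_windows: int = 216
    rate_mode: str = "constant"       # constant | variable
    constant_rate: float = 0.0018
    variable_rates: tuple[float, ...] = (0.001, 0.002, 0.003)
    hky_kappa: float = 2.0
    base_freqs: tuple[float, float, float, float] = EQUAL_FREQS
    shared_genealogy: bool = False    # one clonal genealogy for all windows
    recombination_events: tuple[TractSpec, ...] = ()
    gap_spec: tuple[tuple[str, int, int], ...] = ()   # (strain, start, length)
    seed: int = 0

    n_outgroup: int = field(default=1, init=False)    # single outgroup by design

    def __post_init__(self) -> None:
        if self.n_ingroup < 1:
            raise ConfigError("n_ingroup must be >= 1")
        if sum(self.subpop_sizes) != self.n_ingroup:
            raise ConfigError(
                f"subpop_sizes {self.subpop_sizes} must sum to n_ingroup={self.n_ingroup}"
            )
        if self.split_time <= 0:
            raise ConfigError("split_time must be positive")
        if self.window_length_bp <= 0:
            raise ConfigError("window_length_bp must be positive")
        if self.n_windows < 1:
            raise ConfigError("n_windows must be >= 1")
        if self.rate_mode not in ("constant", "variable"):
            raise ConfigError(f"rate_mode must be constant|variable, got {self.rate_mode!r}")
        rates = (self.constant_rate,) if self.rate_mode == "constant" else tuple(self.variable_rates)
        if any(r <= 0 for r in rates):
            raise ConfigError("substitution rates must be positive")
        if self.hky_kappa <= 0:
            raise ConfigError("hky_kappa must be positive")
        if abs(sum(self.base_freqs) - 1.0) > 1e-9 or any(f <= 0 for f in self.base_freqs):
            raise ConfigError("base_freqs must be positive and sum to 1")

    @property
    def ingroup_ids(self) -> list[str]:
        return [f"S{i + 1:02d}" for i in range(self.n_ingroup)]

    @property
    def outgroup_id(self) -> str:
        return "OUT"

    @property
    def genome_length(self) -> int:
        return self.n_windows * self.window_length_bp

    def rate_for_window(self, w: int) -> float:
        if self.rate_mode == "constant":
            return self.constant_rate
        return self.variable_rates[w % len(self.variable_rates)]


@dataclass
class SimTruth:
    """Ground truth for one simulated dataset."""

    genealogies: list[str]                # newick per window, ms time units
    rates: list[float]                    # substitution rate per window
    site_mutation_counts: np.ndarray      # observed state changes per column
    tract_registry: list[dict]            # columns whose allele a tract changed
    config: SimConfig


def _window_seed(seed: int, window_index: int, stream: int) -> int:
    """Deterministic per-window, per-stream 31-bit seed."""
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(window_index, stream))
    return int(ss.generate_state(1)[0] % (2**31 - 1)) + 1


def _demography(config: SimConfig) -> tuple[msprime.Demography, list]:
    """Backward-time demography matching the two-population ``ms`` design.

    Haploid lineages with population size 0.5 give E[pairwise coalescence]
    = 0.5, i.e. time is measured in units of 4N generations as in ``ms``.
    """
    size = 0.5
    dem = msprime.Demography()
    dem.add_population(name="outgroup_pop", initial_size=size)
    samples = []
    if config.subpop_split_time > 0 and all(s > 0 for s in config.subpop_sizes):
        dem.add_population(name="red", initial_size=size)
        dem.add_population(name="blue", initial_size=size)
        dem.add_population(name="ingroup", initial_size=size)
        dem.add_population(name="ancestral", initial_size=size)
        dem.add_population_split(
            time=config.subpop_split_time, derived=["red", "blue"], ancestral="ingroup"
        )
        dem.add_population_split(
            time=config.split_time, derived=["ingroup", "outgroup_pop"], ancestral="ancestral"
        )
        samples = [
            msprime.SampleSet(config.subpop_sizes[0], population="red", ploidy=1),
            msprime.SampleSet(config.subpop_sizes[1], population="blue", ploidy=1),
            msprime.SampleSet(1, population="outgroup_pop", ploidy=1),
        ]
    else:
        dem.add_population(name="ingroup", initial_size=size)
        dem.add_population(name="ancestral", initial_size=size)
        dem.add_population_split(
            time=config.split_time, derived=["ingroup", "outgroup_pop"], ancestral="ancestral"
        )
        samples = [
            msprime.SampleSet(config.n_ingroup, population="ingroup", ploidy=1),
            msprime.SampleSet(1, population="outgroup_pop", ploidy=1),
        ]
    dem.sort_events()
    return dem, samples


def simulate_genealogy(config: SimConfig, window_index: int = 0) -> dendropy.Tree:
    """Draw one coalescent genealogy of ``n_ingroup + 1`` tips.

    The outgroup lineage can only coalesce with the ingroup at or above
    ``split_time``; branch lengths are in units of 4N generations.
    """
    dem, samples = _demography(config)
    ts = msprime.sim_ancestry(
        samples=samples,
        demography=dem,
        ploidy=1,
        random_seed=_window_seed(config.seed, window_index, 0),
    )
    labels = config.ingroup_ids + [config.outgroup_id]
    return _tskit_to_dendropy(ts.first(), labels)


def _tskit_to_dendropy(tree, labels: list[str]) -> dendropy.Tree:
    taxa = dendropy.TaxonNamespace(labels)
    dt = dendropy.Tree(taxon_namespace=taxa)

    def build(u) -> dendropy.Node:
        node = dendropy.Node()
        children = tree.children(u)
        if not children:
            node.taxon = taxa.get_taxon(labels[u])
        for ch in children:
            child = build(ch)
            child.edge.length = tree.time(tree.parent(ch)) - tree.time(ch)
            node.add_child(child)
        return node

    dt.seed_node = build(tree.root)
    dt.is_rooted = True
    return dt


# ---------------------------------------------------------------------------
# HKY sequence evolution
# ---------------------------------------------------------------------------

_TRANSITION = np.zeros((4, 4), dtype=bool)
_TRANSITION[0, 2] = _TRANSITION[2, 0] = True   # A <-> G
_TRANSITION[1, 3] = _TRANSITION[3, 1] = True   # C <-> T


def hky_rate_matrix(kappa: float, freqs: Sequence[float] = EQUAL_FREQS) -> np.ndarray:
    """HKY generator normalised to one expected substitution per unit time."""
    pi = np.asarray(freqs, dtype=float)
    Q = np.where(_TRANSITION, kappa, 1.0) * pi[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = -(pi * np.diag(Q)).sum()
    return Q / mu


class HkyModel:
    """HKY substitution model with spectral transition probabilities.

    The generator is similar to a symmetric matrix via a pi^(1/2) scaling,
    so P(d) = D^{-1/2} U exp(Lambda d) U' D^{1/2} with a real eigensystem.
    """

    def __init__(self, kappa: float = 2.0, freqs: Sequence[float] = EQUAL_FREQS):
        self.kappa = float(kappa)
        self.freqs = np.asarray(freqs, dtype=float)
        self.Q = hky_rate_matrix(kappa, freqs)
        d_half = np.sqrt(self.freqs)
        S = (self.Q * d_half[:, None]) / d_half[None, :]
        S = (S + S.T) / 2.0  # guard rounding; exactly symmetric analytically
        lam, U = np.linalg.eigh(S)
        self._lam = lam
        self._left = U / d_half[:, None]
        self._right = U.T * d_half[None, :]

    def transition_matrix(self, distance: float) -> np.ndarray:
        """P(d): row = current base, column = descendant base, for expected
        substitution load ``d`` per site."""
        if distance < 0:
            raise ValueError("distance must be non-negative")
        P = (self._left * np.exp(self._lam * distance)) @ self._right
        P = np.clip(P, 0.0, None)
        return P / P.sum(axis=1, keepdims=True)


def evolve_sequences(
    tree: dendropy.Tree,
    rate: float,
    length_bp: int,
    kappa: float = 2.0,
    freqs: Sequence[float] = EQUAL_FREQS,
    seed: int | np.random.Generator = 0,
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Evolve a gapless alignment down ``tree`` under HKY.

    ``rate`` scales branch lengths into expected substitutions per site, the
    Seq-Gen ``-s`` convention.  Returns ``(tip_labels, matrix, changes)``
    where ``matrix`` is uint8-coded (A=0..T=3) of shape (n_tips, length_bp)
    and ``changes`` counts observed state changes per column over all edges.
    """
    if rate < 0:
        raise ConfigError("substitution rate must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    model = HkyModel(kappa, freqs)
    root_seq = rng.choice(4, size=length_bp, p=model.freqs).astype(np.uint8)
    changes = np.zeros(length_bp, dtype=np.int64)

    seqs: dict[int, np.ndarray] = {id(tree.seed_node): root_seq}
    labels: list[str] = []
    rows: list[np.ndarray] = []
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            seq = root_seq
        else:
            parent_seq = seqs[id(node.parent_node)]
            d = rate * (node.edge.length or 0.0)
            seq = _evolve_branch(parent_seq, model, d, rng)
            changes += seq != parent_seq
            seqs[id(node)] = seq
        if node.is_leaf():
            labels.append(node.taxon.label)
            rows.append(seq)
    # free internal sequences eagerly is unnecessary at these sizes
    return labels, np.stack(rows), changes


def _evolve_branch(
    parent: np.ndarray, model: HkyModel, distance: float, rng: np.random.Generator
) -> np.ndarray:
    if distance == 0:
        return parent
    P = model.transition_matrix(distance)
    cum = np.cumsum(P, axis=1)
    u = rng.random(parent.size)
    child = (u[:, None] > cum[parent]).sum(axis=1).astype(np.uint8)
    return np.minimum(child, 3)


# ---------------------------------------------------------------------------
# Tract injection, gaps, dataset assembly
# ---------------------------------------------------------------------------


def inject_tracts(
    matrix: AlignmentMatrix,
    truth: SimTruth,
    tracts: Sequence[TractSpec],
    clonal_tree: Optional[dendropy.Tree] = None,
) -> tuple[AlignmentMatrix, SimTruth]:
    """Copy donor sequence over the recipient within each tract.

    Every column whose recipient allele actually changed is appended to the
    truth registry.  When the (ingroup) clonal genealogy is supplied, each
    registry entry is additionally flagged ``homoplasic``: whether the
    column's final ingroup bipartition is incompatible with the genealogy.
    Compatible changed columns mimic single mutations and are undetectable
    by any genealogy-based caller (e.g. removing one member of a two-strain
    clade leaves a singleton).
    """
    L = matrix.n_columns
    bad = [t for t in tracts if t.start < 0 or t.length < 0 or t.start + t.length > L]
    if bad:
        raise ValueError(f"tracts out of alignment bounds: {bad}")
    if any(t.donor == t.recipient for t in tracts):
        raise ValueError("tract donor and recipient must differ")
    for t in tracts:
        donor = matrix.row(t.donor)[t.start : t.start + t.length]
        rec_idx = matrix.ids.index(t.recipient)
        recipient = matrix.data[rec_idx, t.start : t.start + t.length]
        changed = np.flatnonzero(donor != recipient)
        for off in changed:
            truth.tract_registry.append(
                {
                    "recipient": t.recipient,
                    "donor": t.donor,
                    "column": int(t.start + off),
                    "old": int(recipient[off]),
                    "new": int(donor[off]),
                }
            )
        matrix.data[rec_idx, t.start : t.start + t.length] = donor
    if clonal_tree is not None:
        _flag_homoplasic_columns(matrix, truth, clonal_tree)
    return matrix, truth


def _flag_homoplasic_columns(
    matrix: AlignmentMatrix, truth: SimTruth, clonal_tree: dendropy.Tree
) -> None:
    from .recombination import ClonalTree, SitePattern, enumerate_single_mutation_patterns

    ctree = ClonalTree(clonal_tree)
    splits = enumerate_single_mutation_patterns(ctree, polarized=False)
    ids = matrix.ingroup_ids
    rows = matrix.ingroup_rows
    for entry in truth.tract_registry:
        col = rows[:, entry["column"]]
        alleles = np.unique(col)
        if alleles.size != 2 or alleles.max() >= 4:
            entry["homoplasic"] = False   # monomorphic, multi-allelic, or gapped
            continue
        side = [s for s, v in zip(ids, col) if v == alleles[0]]
        entry["homoplasic"] = SitePattern.unpolarised(side, ids) not in splits


def apply_gaps(matrix: AlignmentMatrix, gap_spec: Sequence[tuple[str, int, int]]) -> AlignmentMatrix:
    for strain, start, length in gap_spec:
        matrix.data[matrix.ids.index(strain), start : start + length] = GAP
    return matrix


def simulate_dataset(config: SimConfig) -> tuple[AlignmentMatrix, SimTruth]:
    """Simulate the full windowed genome alignment plus its truth record.

    Windows draw independent genealogies (free recombination between windows,
    matching per-window coalescent replicates) unless ``shared_genealogy`` is
    set, in which case window 0's genealogy is reused everywhere and injected
    tracts are the only source of homoplasy.
    """
    labels = config.ingroup_ids + [config.outgroup_id]
    blocks: list[np.ndarray] = []
    newicks: list[str] = []
    rates: list[float] = []
    change_blocks: list[np.ndarray] = []

    shared_tree = simulate_genealogy(config, 0) if config.shared_genealogy else None
    for w in range(config.n_windows):
        tree = shared_tree if shared_tree is not None else simulate_genealogy(config, w)
        rate = config.rate_for_window(w)
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=config.seed, spawn_key=(w, 1))
        )
        tip_labels, seqs, changes = evolve_sequences(
            tree, rate, config.window_length_bp, config.hky_kappa, config.base_freqs, rng
        )
        order = [tip_labels.index(lbl) for lbl in labels]
        blocks.append(seqs[order])
        newicks.append(tree.as_string(schema="newick", suppress_rooting=True).strip())
        rates.append(rate)
        change_blocks.append(changes)

    matrix = AlignmentMatrix(
        ids=labels,
        data=np.concatenate(blocks, axis=1),
        reference_id=labels[0],
        outgroup_id=config.outgroup_id,
    )
    truth = SimTruth(
        genealogies=newicks,
        rates=rates,
        site_mutation_counts=np.concatenate(change_blocks),
        tract_registry=[],
        config=config,
    )
    if config.recombination_events:
        ctree = (
            ingroup_subtree(shared_tree, config.outgroup_id)
            if shared_tree is not None else None
        )
        inject_tracts(matrix, truth, config.recombination_events, clonal_tree=ctree)
    if config.gap_spec:
        apply_gaps(matrix, config.gap_spec)
        matrix.__post_init__()  # reference gaps change the coordinate map
    return matrix, truth


def write_dataset(matrix: AlignmentMatrix, truth: SimTruth, out_dir: str | Path) -> dict[str, Path]:
    """Write the dataset as plain-text files; round-trips through
    :func:`clonalscan.alignment.read_alignment`."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "alignment": out / "alignment.fasta",
        "trees": out / "genealogies.nwk",
        "windows": out / "truth_windows.tsv",
        "tracts": out / "truth_tracts.tsv",
        "mutations": out / "truth_site_mutations.tsv",
        "config": out / "sim_config.json",
    }
    matrix.to_fasta(paths["alignment"])
    paths["trees"].write_text("".join(n + "\n" for n in truth.genealogies))
    with open(paths["windows"], "w") as fh:
        fh.write("window\tstart\tend\trate\n")
        W = truth.config.window_length_bp
        for w, r in enumerate(truth.rates):
            fh.write(f"{w}\t{w * W}\t{(w + 1) * W}\t{r:g}\n")
    with open(paths["tracts"], "w") as fh:
        fh.write("recipient\tdonor\tcolumn\told\tnew\thomoplasic\n")
        for rec in truth.tract_registry:
            fh.write(
                f"{rec['recipient']}\t{rec['donor']}\t{rec['column']}\t{rec['old']}\t"
                f"{rec['new']}\t{rec.get('homoplasic', '.')}\n"
            )
    with open(paths["mutations"], "w") as fh:
        fh.write("column\tn_changes\n")
        for col in np.flatnonzero(truth.site_mutation_counts):
            fh.write(f"{col}\t{truth.site_mutation_counts[col]}\n")
    cfg = asdict(truth.config)
    cfg["recombination_events"] = [asdict(t) for t in truth.config.recombination_events]
    paths["config"].write_text(json.dumps(cfg, indent=1, default=list))
    return paths


# ---------------------------------------------------------------------------
# Fixed-S mutation placement (shared by the LD null and the double-hit bound)
# ---------------------------------------------------------------------------


def ingroup_subtree(tree: dendropy.Tree, outgroup_label: str) -> dendropy.Tree:
    """Extract the ingroup clade as its own rooted tree."""
    sub = tree.extract_tree_without_taxa_labels([outgroup_label])
    sub.is_rooted = True
    return sub


def place_mutations_fixed_s(
    tree: dendropy.Tree, n_sites: int, rng: np.random.Generator
) -> np.ndarray:
    """Place exactly ``n_sites`` mutations on the tree, branch-length
    proportionally, one per site; returns a binary (n_sites, n_tips) matrix
    of derived-allele carriers in leaf-label sorted order.

    Only edges below the root are eligible (a root-edge mutation would not
    segregate), so every row has at least one 0 and one 1.
    """
    leaves = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    index = {lbl: i for i, lbl in enumerate(leaves)}
    nodes = [nd for nd in tree.preorder_node_iter() if nd is not tree.seed_node]
    lengths = np.array([nd.edge.length or 0.0 for nd in nodes], dtype=float)
    if lengths.sum() <= 0:
        raise ValueError("tree has no positive branch lengths")
    clades = []
    for nd in nodes:
        clades.append([index[lf.taxon.label] for lf in nd.leaf_iter()])
    picks = rng.choice(len(nodes), size=n_sites, p=lengths / lengths.sum())
    out = np.zeros((n_sites, len(leaves)), dtype=np.uint8)
    for row, k in enumerate(picks):
        out[row, clades[k]] = 1
    return out
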