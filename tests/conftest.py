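"""Shared fixtures: small synthetic datasets with known truth."""

from __future__ import annotations

import numpy as np
import pytest

from clonalscan import alignment as aln
from clonalscan import recombination as rec
from clonalscan import simulate as sim


@pytest.fixture(scope="session")
def constant_dataset():
    """Constant-rate, shared-genealogy (clonal) 12-window genome, no tracts."""
    cfg = sim.SimConfig(n_windows=12, rate_mode="constant", shared_genealogy=True, seed=101)
    matrix, truth = sim.simulate_dataset(cfg)
    return cfg, matrix, truth


@pytest.fixture(scope="session")
def constant_analysis(constant_dataset):
    """SNPs and windows of the clonal dataset, classified against the true
    clonal genealogy."""
    cfg, matrix, truth = constant_dataset
    snps, core = aln.extract_core_and_snps(matrix)
    windows = aln.make_windows(matrix, snps, core)
    full = rec.ClonalTree.from_newick(truth.genealogies[0])
    ingroup = rec.ClonalTree(sim.ingroup_subtree(full.tree, cfg.outgroup_id))
    clf = rec.HomoplasyClassifier(ingroup, matrix.ingroup_ids)
    clf.classify_all(snps)
    rec.window_recombination(windows, snps, cfg.window_length_bp)
    return {
        "config": cfg,
        "matrix": matrix,
        "truth": truth,
        "snps": snps,
        "core": core,
        "windows": windows,
        "tree": ingroup,
        "full_tree": full,
    }


@pytest.fixture(scope="session")
def genome216_constant():
    """Constant-rate genome at study scale: 216 independent 10-kb windows."""
    cfg = sim.SimConfig(n_windows=216, rate_mode="constant", seed=100)
    matrix, truth = sim.simulate_dataset(cfg)
    snps, core = aln.extract_core_and_snps(matrix)
    windows = aln.make_windows(matrix, snps, core)
    return {"config": cfg, "matrix": matrix, "truth": truth,
            "snps": snps, "core": core, "windows": windows}


def random_bifurcating_newick(n: int, rng: np.random.Generator, labels=None) -> str:
    """A uniformly random rooted bifurcating topology via sequential random
    pairing, with unit branch lengths."""
    nodes = list(labels) if labels else [f"T{i}" for i in range(n)]
    nodes = [f"{x}:1" for x in nodes]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(f"({a},{b}):1")
    return nodes[0] + ";"
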