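"""Cross-cutting statistics: binomial expectation bands, Kelly's Z_nS with a
coalescent null, Spearman and paired Wilcoxon wrappers.

The expectation bands follow the study's convention: a window's count is
compared with the central ``conf`` band of a binomial distribution whose
success probability is the genome-wide mean level, at n = the window's own
denominator (core sites, or classifiable SNPs for the recombinant
proportion).
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

from . import simulate as sim


def binomial_band(n: int, p: float, conf: float = 0.95) -> tuple[int, int]:
    """Central ``conf`` band of Binomial(n, p) as integer counts.

    lower = smallest k with CDF(k) >= (1-conf)/2; upper = smallest k with
    CDF(k) >= 1-(1-conf)/2.  Values exactly on a bound are "within".
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= p <= 1:
        raise ValueError("p must lie in [0, 1]")
    tail = (1.0 - conf) / 2.0
    lo = int(sps.binom.ppf(tail, n, p))
    hi = int(sps.binom.ppf(1.0 - tail, n, p))
    return lo, hi


def classify_against_band(value: float, lo: int, hi: int) -> str:
    if value < lo:
        return "low"
    if value > hi:
        return "high"
    return "within"


def classify_windows(
    values: Sequence[float], ns: Sequence[int], p: Optional[float] = None, conf: float = 0.95
) -> tuple[list[str], dict]:
    """Three-way band classification of per-window counts.

    ``p`` defaults to the pooled mean sum(values)/sum(ns).  Returns the
    per-window classes and a summary with counts and fractions.
    """
    values = list(values)
    ns = list(ns)
    if len(values) != len(ns):
        raise ValueError("values and ns must be paired")
    if p is None:
        tot = sum(ns)
        p = (sum(values) / tot) if tot else 0.0
    classes = [
        classify_against_band(v, *binomial_band(n, p, conf)) if n >= 1 else "within"
        for v, n in zip(values, ns)
    ]
    n_win = len(classes)
    summary = {"p": p, "n_windows": n_win}
    for cls in ("low", "within", "high"):
        k = classes.count(cls)
        summary[f"n_{cls}"] = k
        summary[f"frac_{cls}"] = k / n_win if n_win else float("nan")
    summary["frac_outside"] = (
        (summary["n_low"] + summary["n_high"]) / n_win if n_win else float("nan")
    )
    return classes, summary


def kellys_zns(haplotypes: np.ndarray) -> float:
    """Kelly's Z_nS: mean pairwise r^2 over all site pairs.

    ``haplotypes`` has shape (n_haplotypes, n_sites); every column must be
    biallelic with no missing calls.  r^2 for a site pair is
    D^2 / (p1 (1-p1) p2 (1-p2)) with D the two-locus disequilibrium.
    """
    H = np.asarray(haplotypes)
    if H.ndim != 2 or H.shape[0] < 2:
        raise ValueError("need a 2-D matrix with >= 2 haplotypes")
    n, S = H.shape
    if S < 2:
        raise ValueError("Z_nS needs >= 2 sites")
    # map each biallelic column onto {0, 1}
    X = np.empty((n, S), dtype=float)
    for j in range(S):
        col = H[:, j]
        alleles = np.unique(col)
        if alleles.size != 2:
            raise ValueError(f"site {j} is not biallelic (alleles: {alleles})")
        X[:, j] = col == alleles[1]
    p = X.mean(axis=0)
    joint = (X.T @ X) / n
    D = joint - np.outer(p, p)
    denom = np.outer(p * (1 - p), p * (1 - p))
    r2 = D**2 / denom
    iu = np.triu_indices(S, k=1)
    return float(r2[iu].mean())


def zns_significance(
    observed: float,
    n_haplotypes: int,
    n_sites: int,
    n_sims: int = 1000,
    seed: int | np.random.Generator = 0,
    subpop_sizes: Optional[tuple[int, int]] = None,
    subpop_split_time: float = 0.0,
    sim_config: Optional["sim.SimConfig"] = None,
) -> tuple[float, np.ndarray]:
    """One-sided coalescent-null p-value for an observed Z_nS.

    Each null replicate draws a neutral ingroup genealogy (optionally with
    the two-species population structure), places exactly ``n_sites``
    mutations branch-length-proportionally (fixed-S conditioning, matching
    the observed number of polymorphisms), and computes Z_nS.  The p-value is
    (1 + #{sim >= obs}) / (n_sims + 1), never exactly zero.
    """
    if n_sites < 2:
        raise ValueError("Z_nS significance needs >= 2 segregating sites")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if sim_config is None:
        if subpop_sizes is None:
            half = n_haplotypes // 2
            subpop_sizes = (half, n_haplotypes - half)
        sim_config = sim.SimConfig(
            n_ingroup=n_haplotypes,
            subpop_sizes=subpop_sizes,
            subpop_split_time=subpop_split_time,
            n_windows=1,
            seed=int(rng.integers(2**31 - 1)),
        )
    null = simulate_null_zns(sim_config, n_sites, n_sims, rng)
    p = (1 + int((null >= observed).sum())) / (n_sims + 1)
    return p, null


def simulate_null_zns(
    config: "sim.SimConfig", n_sites: int, n_sims: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n_sims`` null Z_nS values at fixed S under the configured
    ingroup demography (the outgroup lineage is not sampled).

    Genealogies come from one batched coalescent run; the ``n_sites``
    mutations are placed branch-length-proportionally on each genealogy's
    non-root edges, so every simulated site segregates.
    """
    import msprime

    dem, samples = sim._demography(config)
    samples = [s for s in samples if s.population != "outgroup_pop"]
    replicates = msprime.sim_ancestry(
        samples=samples,
        demography=dem,
        ploidy=1,
        num_replicates=n_sims,
        random_seed=int(rng.integers(2**31 - 2)) + 1,
    )
    vals = np.empty(n_sims)
    for i, ts in enumerate(replicates):
        tree = ts.first()
        nodes = [u for u in tree.nodes() if u != tree.root]
        lengths = np.array([tree.branch_length(u) for u in nodes])
        clades = [np.fromiter(tree.samples(u), dtype=np.int64) for u in nodes]
        picks = rng.choice(len(nodes), size=n_sites, p=lengths / lengths.sum())
        H = np.zeros((n_sites, ts.num_samples), dtype=np.uint8)
        for row, k in enumerate(picks):
            H[row, clades[k]] = 1
        vals[i] = kellys_zns(H.T)
    return vals


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with average-rank ties and t-approximation
    p-value; incomplete pairs (None/NaN) are dropped."""
    x = np.asarray([np.nan if v is None else v for v in x], dtype=float)
    y = np.asarray([np.nan if v is None else v for v in y], dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError("Spearman needs >= 3 complete pairs")
    res = sps.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def wilcoxon_paired(
    recombinant: Sequence[float], nonrecombinant: Sequence[float]
) -> Optional[float]:
    """Two-sided Wilcoxon signed-rank p-value on paired per-window counts.

    Zero differences are dropped; the normal approximation with tie
    correction is used.  Returns None when no nonzero differences remain.
    """
    a = np.asarray(recombinant, dtype=float)
    b = np.asarray(nonrecombinant, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    nz = a != b
    if not nz.any():
        return None
    res = sps.wilcoxon(a[nz], b[nz], zero_method="wilcox", method="approx")
    return float(res.pvalue)


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values."""
    return sps.false_discovery_control(np.asarray(pvalues, dtype=float), method="bh")
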