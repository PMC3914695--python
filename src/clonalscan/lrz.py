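"""Low-recombination zones: statistically long runs of nonrecombinant SNPs.

With a genome-wide recombinant SNP fraction q, a run of k consecutive
nonrecombinant SNPs occurs by chance with probability (1 - q)^k under a
constant-recombination null; at the fraction observed in the study (q = 0.21)
a run of 30 already has probability 0.79^30 < 0.001, motivating a default
minimum run of 31 SNPs (">30").
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .alignment import SnpRecord
from .recombination import SitePattern
from .stats import binomial_band, classify_against_band, spearman

logger = logging.getLogger(__name__)


@dataclass
class LrzRecord:
    """A maximal run of consecutive nonrecombinant SNPs (>= min_run long)."""

    start: int                    # reference position of the first SNP in the run
    end: int                      # last SNP position + 1 (0-based half-open)
    run_length: int               # number of consecutive nonrecombinant SNPs
    snps: list[SnpRecord] = field(default_factory=list, repr=False)
    core_length: Optional[int] = None
    n_polymorphisms: Optional[int] = None     # nonrecombinant polymorphisms in the run
    poly_level: Optional[float] = None
    poly_class: Optional[str] = None          # low | average | high
    zns: Optional[float] = None
    zns_p: Optional[float] = None
    zns_q: Optional[float] = None       # BH-adjusted across all tested zones
    fixed_zone: Optional[bool] = None

    @property
    def span_bp(self) -> int:
        return self.end - self.start


def run_null_probability(q: float, k: int) -> float:
    """P(k consecutive nonrecombinant SNPs) = (1 - q)^k."""
    if not 0 <= q <= 1:
        raise ValueError("recombinant fraction q must lie in [0, 1]")
    if k < 0:
        raise ValueError("run length must be non-negative")
    return (1.0 - q) ** k


def min_run_for_alpha(q: float, alpha: float) -> int:
    """Smallest integer k with (1 - q)^k < alpha (strict inequality).

    Computed via logarithms and then verified by direct evaluation at k - 1
    and k, so floating rounding at the boundary cannot shift the answer.
    """
    if not 0 < q < 1:
        raise ValueError("q must lie strictly between 0 and 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie strictly between 0 and 1")
    k = max(1, math.ceil(math.log(alpha) / math.log(1.0 - q)))
    while run_null_probability(q, k) >= alpha:
        k += 1
    while k > 1 and run_null_probability(q, k - 1) < alpha:
        k -= 1
    return k


def find_lrzs(snps: Sequence[SnpRecord], min_run: int = 31) -> list[LrzRecord]:
    """Scan the position-sorted classified SNP sequence for maximal runs of
    nonrecombinant (clonal) SNPs of length >= ``min_run``.

    Excluded (multi-allelic) SNPs are dropped from the sequence first; runs
    are broken only by recombinant SNPs, never by window boundaries.
    """
    seq = sorted(
        (s for s in snps if s.clonal_class in ("clonal", "recombinant") and s.ref_pos >= 0),
        key=lambda s: s.ref_pos,
    )
    zones: list[LrzRecord] = []
    run: list[SnpRecord] = []

    def close_run() -> None:
        if len(run) >= min_run:
            zones.append(
                LrzRecord(
                    start=run[0].ref_pos,
                    end=run[-1].ref_pos + 1,
                    run_length=len(run),
                    snps=list(run),
                )
            )
        run.clear()

    for snp in seq:
        if snp.clonal_class == "clonal":
            run.append(snp)
        else:
            close_run()
    close_run()
    return zones


def lrz_stats(
    lrz: LrzRecord,
    core_at_ref: np.ndarray,
    genome_poly_rate: float,
    conf: float = 0.95,
) -> LrzRecord:
    """Fill polymorphism level and its band class for one zone.

    The level is the run's nonrecombinant polymorphism count divided by the
    zone's core length; the class compares that count against the genome-wide
    binomial band at n = core length and p = ``genome_poly_rate``.
    """
    core_len = int(np.asarray(core_at_ref[lrz.start : lrz.end]).sum())
    lrz.core_length = core_len
    lrz.n_polymorphisms = sum(1 for s in lrz.snps if s.is_polymorphic)
    if core_len <= 0:
        logger.warning("LRZ %d-%d has zero core length; level undefined", lrz.start, lrz.end)
        lrz.poly_level = None
        lrz.poly_class = None
        return lrz
    lrz.poly_level = lrz.n_polymorphisms / core_len
    lo, hi = binomial_band(core_len, genome_poly_rate, conf)
    band = classify_against_band(lrz.n_polymorphisms, lo, hi)
    lrz.poly_class = {"low": "low", "within": "average", "high": "high"}[band]
    return lrz


def size_polymorphism_correlation(zones: Sequence[LrzRecord]) -> tuple[float, float]:
    """Spearman correlation between zone size (bp) and polymorphism level.

    Returns (nan, nan) when fewer than three zones have a defined level.
    """
    pairs = [(z.span_bp, z.poly_level) for z in zones if z.poly_level is not None]
    if len(pairs) < 3:
        return (float("nan"), float("nan"))
    x, y = zip(*pairs)
    return spearman(x, y)


def fixed_zone_flag(
    lrz: LrzRecord,
    species_partition: Optional[dict[str, str]],
    ingroup_ids: Sequence[str],
) -> Optional[bool]:
    """Is the zone's dominant SNP pattern the between-species split?

    The most frequent site pattern among the zone's SNPs is compared, as an
    unpolarised bipartition, with the two-species partition.  Ties for the
    most frequent pattern resolve to not-fixed with a logged warning.
    """
    if species_partition is None:
        logger.info("no species partition supplied; fixed-zone flag skipped")
        lrz.fixed_zone = None
        return None
    groups = set(species_partition.values())
    if len(groups) != 2:
        raise ValueError(f"species partition must have exactly 2 groups, got {sorted(groups)}")
    g = sorted(groups)[0]
    species_side = [s for s in ingroup_ids if species_partition[s] == g]
    species_pattern = SitePattern.unpolarised(species_side, ingroup_ids)

    counts = Counter(
        SitePattern.unpolarised(p.members, ingroup_ids) if p.polarized else p
        for p in (s.pattern for s in lrz.snps)
        if p is not None
    )
    if not counts:
        lrz.fixed_zone = False
        return False
    ranked = counts.most_common()
    top, top_n = ranked[0]
    if len(ranked) > 1 and ranked[1][1] == top_n and top != ranked[1][0]:
        tied = {pat for pat, c in ranked if c == top_n}
        if species_pattern in tied:
            logger.warning(
                "LRZ %d-%d: dominant pattern tie includes the species split; "
                "resolving to not-fixed", lrz.start, lrz.end,
            )
            lrz.fixed_zone = False
            return False
    lrz.fixed_zone = top == species_pattern
    return lrz.fixed_zone
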