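# Methods

## The model

The package treats a set of n closely related haploid strains plus one
deeply diverged outgroup as samples from a neutral coalescent.  Vertical
descent within the ingroup is summarised by a single rooted, strictly
bifurcating *clonal genealogy*; homologous recombination imports short donor
tracts that overwrite the recipient's sequence and thereby create allele
patterns no single mutation on that genealogy can produce (homoplasies).
The analysis chain is: call SNPs and outgroup-divergent sites on core
alignment columns → window them on reference coordinates → classify each
biallelic SNP as clonal or recombinant against the genealogy → find runs of
nonrecombinant SNPs longer than chance allows → score those zones for
polymorphism, linkage disequilibrium and species-level fixation → compute
per-gene selection statistics.

### Site and window definitions

A *core* column has no gap and no `N` in any ingroup strain.  A column is
*polymorphic* when the ingroup carries ≥ 2 alleles and *divergent* when the
outgroup carries a real nucleotide matching no ingroup allele; the two
properties are independent and a column may count in both metrics.
Windows tile the gap-free positions of a designated reference strain in
fixed 10-kb steps (configurable); a window is dropped when its non-core
column total strictly exceeds 5 kb, when it overlaps a configured exclusion
interval, or when it is a trailing fragment narrower than half a window
(too little sequence for a stable rate).  Coordinates are 0-based half-open
internally; reports add 1-based columns; BED output stays 0-based.

Back-mutation correction multiplies each window's raw polymorphism count by
the Jukes–Cantor multiple-hit factor m(d) = (−3/4 · ln(1 − 4d/3))/d, where d
is that window's divergent-site fraction — the simplest estimator that uses
only the window's own divergence.  At saturation (d ≥ 3/4) the window is
flagged and the raw count kept.  The claim that correction does not alter
window ranking is *tested* (rank correlation > 0.99 on constant-rate
synthetic data at 216 windows), not assumed.

### Homoplasy classification

For a rooted strictly bifurcating genealogy of n strains there are 2n − 2
edges, hence 2n − 2 outgroup-polarised single-mutation patterns (one derived
clade per edge; 18 for n = 10) and 2n − 3 distinct unpolarised bipartitions
(the two root-adjacent edges give the same split).  A biallelic SNP is
polarised when the outgroup allele matches exactly one ingroup allele;
otherwise it falls back to bipartition matching, which never over-calls a
conflict.  Ingroup columns with ≥ 3 alleles are *excluded* — reported, but
forced into neither class.  Per window the recombinant proportion is
recombinant/(clonal + recombinant), and the number of unique recombinant
topologies is the count of distinct site patterns among the window's
recombinant SNPs (both also emitted per classified SNP).

Some truly recombinant columns are invisible in principle: a tract that
removes one member of a two-strain clade leaves a singleton, which is a
valid single-mutation pattern.  The simulator therefore flags, per
tract-changed column, whether its final bipartition is genealogy-compatible;
detector recall is measured on the incompatible columns.

The double-hit confounder (two mutations at one site mimicking
recombination) is quantified by Monte Carlo: the observed number of
mutations is placed uniformly over core sites and branch-length-
proportionally over the genealogy, multi-hit sites are resolved
nucleotide-by-nucleotide, and the resulting columns are pushed through the
same classification rule.  When the full genealogy including the outgroup is
supplied, this also captures mispolarisation by parallel outgroup-branch
mutations — at 10% outgroup divergence this is the *dominant* double-hit
artifact, and the Monte-Carlo expectation matches the recombinant calls a
tract-free clonal genome produces.  The analytic birthday bound
S(S − 1)/(2L) caps the multi-hit site count.

### Low-recombination zones

With genome-wide recombinant fraction q, a run of k consecutive
nonrecombinant SNPs has null probability (1 − q)^k; `min_run_for_alpha`
inverts this exactly (logarithm plus integer verification at k − 1 and k).
At the design point q = 0.21, a 30-SNP run has probability 0.79³⁰ ≈
8.5 × 10⁻⁴ < 0.001, so the default threshold is ≥ 31 SNPs (a strict reading
of "more than 30"); probabilities at both k = 30 and 31 are logged, and q is
always recomputed from the data, never hard-coded.  Runs are broken only by
recombinant SNPs (excluded SNPs are removed from the sequence first; window
boundaries are irrelevant), and a zone's genomic extent is the span from its
first to its last SNP — flanking-midpoint extent is available behind a
config switch.  Zone polymorphism level is the run's nonrecombinant
polymorphism count over the zone's core length, classified against the
genome-wide binomial band at n = core length.

### Linkage disequilibrium and fixed zones

Kelly's Z_nS is the mean of r² = D²/(p₁(1−p₁)p₂(1−p₂)) over all unordered
site pairs in a zone.  Its significance comes from a coalescent null
matched to the observed sample size and number of polymorphisms: each
replicate draws an ingroup genealogy (optionally with the two-subpopulation
red/blue structure), places exactly S mutations branch-length-
proportionally on non-root edges (fixed-S conditioning, so every simulated
site segregates), and recomputes Z_nS; p = (1 + #{sim ≥ obs})/(n_sims + 1),
never exactly zero.  A rates-based alternative to fixed-S conditioning is
deliberately out; the null matches the observed S by construction.
Benjamini–Hochberg adjusted p-values are reported across all tested zones.
A zone is a *fixed zone* when its most frequent site pattern, read as an
unpolarised bipartition, equals the two-species partition; ties resolve to
not-fixed with a logged warning.

### Selection statistics

dN/dS uses Nei–Gojobori (1986) counting: per-codon synonymous site
fractions averaged over the pair, multi-difference codons averaged over all
stop-free mutational orderings, Jukes–Cantor correction of both proportions.
Codons with ambiguity, stop codons, and codon pairs whose every pathway
crosses a stop are skipped pairwise.  The gene value is the mean of the two
representative-strain-vs-outgroup ratios (representatives are config keys;
synthetic runs default to two ingroup strains), undefined when dS = 0 or
saturated.  Genes map to windows by start coordinate (midpoint available).

The McDonald–Kreitman table classifies each clean-codon position as fixed
(ingroup monomorphic, differing from the outgroup) or polymorphic (ingroup
variable) and as synonymous or nonsynonymous by translating the most common
ingroup codon with each allele substituted at the focal position.  The test
statistic is G = 2 Σ O ln(O/E) with 1 df, without the Williams correction
(the plain G is what the family threshold was calibrated for); genes with a
zero margin are excluded.  The family-wise threshold is Bonferroni:
per-test α = α/m and the chi-square(1) upper quantile — α = 0.05 over
m = 606 tested genes gives α′ ≈ 8.25 × 10⁻⁵ and critical G ≈ 15.5.

Tajima's D follows the 1989 constants; it is undefined at S = 0 and at
n = 3, where c₁ = c₂ = 0 makes the variance estimate exactly zero (returned
as missing).  Under neutral simulations the per-window mean sits slightly
below zero (≈ −0.25 at n = 10) — the known finite-sample bias of the
ratio form, not a calibration error — and the tests bound it accordingly.

The mutagenic-recombination check pairs recombinant and nonrecombinant SNP
counts in 1-kb bins that contain at least one recombinant SNP and applies
the Wilcoxon signed-rank test (zero differences dropped, normal
approximation with tie correction, two-sided).

## The synthetic-data generator

The generator reproduces the study's simulation design: per 10-kb window an
independent coalescent genealogy of 10 ingroup + 1 outgroup haplotypes
(free recombination between windows, none within), the outgroup lineage
merging into the ingroup at time 30 in units of 4N generations (the `ms`
time convention), sequences evolved under HKY with κ = 2 and equal base
frequencies (the substitution model details are configurable; these are the
conventional defaults) at 0.0018 substitutions/site (constant mode) or
cycling 0.001/0.002/0.003 (variable mode), over 216 windows by default.
Genealogies come from msprime (haploid lineages, population size 0.5, so
E[pairwise coalescence] = 0.5 and times match the 4N convention); HKY
transition probabilities are computed from the spectral decomposition of the
normalised generator, so a branch of length t contributes exactly
rate × t expected substitutions per site.  Identical config + seed gives
byte-identical output.

Two extensions exist solely for validating detectors and are off by
default: `shared_genealogy` evolves every window on one genealogy (a truly
clonal genome, so injected tracts are the only recombination), and
`recombination_events` injects donor→recipient tracts whose changed columns
are registered with a genealogy-compatibility flag.  Gap runs can be
stamped onto any strain to exercise the window gap filter.

What the generator does *not* emulate: within-window recombination (no
ancestral recombination graph), selection, gene conversion tract-length
distributions, alignment error, and rate heterogeneity below window
granularity.  Passing tests therefore demonstrate correctness of the
statistics and detectors under the stated model, not robustness to
alignment artifacts in real genomes.

### Calibration behaviour worth knowing

With independent per-window genealogies, per-window *polymorphism* counts
are overdispersed relative to a binomial with the genome-mean rate —
Var(S) ≈ θa₁ + θ²a₂ from coalescent tree-length variance — so roughly half
of constant-rate windows fall outside the nominal 95% band.  *Divergence*
counts, dominated by the fixed 2 × 30 outgroup path, are nearly binomial
and hold the band at ≈ 5–10%.  The binomial band is therefore a yardstick
for mutational noise, informative for divergence and deliberately
conservative for polymorphism; the calibration checks use divergence.

Under the variable-rate design the seed-averaged Spearman correlation
between per-window divergence and polymorphism is ≈ 0.62 (SD ≈ 0.03 across
seeds at 216 windows): the three-fold rate spread orders divergence almost
perfectly while coalescent noise blurs polymorphism ranks within rate
classes.  The constant-rate control gives a weak *negative* correlation
(≈ −0.2): a taller ingroup genealogy adds polymorphism but shortens the
ingroup stem of the outgroup path.

## Problem sizes used by the tests and scripts

Module and acceptance tests run the full 216-window design where the claim
is about the design (correlation, band coverage, back-mutation ranking) and
scale down elsewhere: 8–40-window genomes for pipeline and detector checks,
200 random trees (n ≤ 8) for the brute-force classification sweep, 500-
replicate nulls × 200 observations for p-value calibration, 24 seeds of the
variable-rate design in the acceptance script.  These sizes keep Monte-
Carlo error far inside every asserted tolerance.

## Known limitations

* The clonal genealogy is taken as given; no tree inference, no per-event
  breakpoint or donor reconstruction.
* Multi-allelic columns (a fraction of a percent at these divergences) are
  excluded from classification rather than modelled.
* dN/dS is pairwise-counting only (no codon ML); MK ignores segregating
  sites within the outgroup lineage.
* The homoplasy caller cannot, by construction, see recombination whose
  resulting patterns remain genealogy-compatible; measured recall refers to
  incompatible columns.
* LRZ extent is SNP-delimited; real zone boundaries between SNPs are
  unidentifiable without denser polymorphism.
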