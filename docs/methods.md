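# Methods

This note documents the statistical models implemented in `sweepscape`,
the synthetic-panel generator whose outputs the tests exercise, the
numerical choices that affect results, and what the passing tests do and do
not establish about real data.

## Data model

The atomic unit is a per-contig alignment: a sample × site matrix over
{ref, alt, missing} with strictly increasing 0-based site positions, a
count of callable invariant (monomorphic) sites, and an optional genetic
map position (chromosome 1H–7H, cM). Each accession contributes a single
haplotype: the target panels are inbred lines purified by single-seed
descent, so heterozygous diploid calls carry no reliable haplotype
information and are set to missing on input rather than resolved to a
random allele. Invariant-site counts cannot be recovered from a VCF and are
supplied through a sidecar table (`contig, n_callable_invariant`); they
enter the π denominator and pairwise-distance match counts.

Ancestral alleles are assigned from two outgroup accessions: a site is
polarized only when both outgroups carry the same non-missing allele.
Polarization never overwrites an existing assignment (idempotence), and
unpolarized sites are excluded from every unfolded-SFS statistic.

## Diversity statistics

**π** is the mean number of pairwise differences per callable site. With
missing data, a SNP site with j alternate alleles among m non-missing
calls contributes 2j(m−j)/(m(m−1)); the denominator is the invariant-site
count plus the number of SNP sites with m ≥ 2. Sites with fewer than two
calls are excluded from both numerator and denominator. This estimator
equals the average over available pairs at each site, which the test suite
verifies against a brute-force pairwise oracle on random matrices.

**Unfolded SFS.** Missing data are handled by hypergeometric projection to
a common sample size m (default: the size at which 80% of sites are
complete): a site with j derived among m_i ≥ m calls adds
P(k derived | j of m_i, draw m) to ξ_k. Projection keeps fractional
expected counts; classes 0 and m are dropped. With complete data and
m = n this is the raw derived-count histogram.

**Fay & Wu's H (normalized).** H_norm = (θ_π − θ_L)/√Var with
θ_π = Σ 2i(n−i)ξ_i / (n(n−1)), θ_L = Σ iξ_i / (n−1), and the neutral
variance evaluated with Watterson's θ̂ = S/a_n and the unbiased
θ² = S(S−1)/(a_n² + b_n) (Zeng et al. 2006):

Var = (n−2)/(6(n−1))·θ + [18n²(3n+2)·b_{n+1} − (88n³ + 9n² − 13n + 6)]
/ (9n(n−1)²) · θ².

The variance formula was checked against unconditional coalescent
simulation (empirical variance within 5% at θ = 8, n = 20). A subtlety of
the fixed-S calibration used for thresholds: conditioning on S leaves the
statistic with a small intrinsic positive mean (≈ +0.10 at n = 20,
S = 30), because rarely-sampled high-frequency classes enter θ_L with
large weights. This was cross-checked with genealogies simulated by
msprime under identical multinomial mutation placement; branch-class
proportions of the two simulators agree to three decimals. The calibration
test therefore uses enough replicates that Monte Carlo error is small
relative to the acceptance band.

**DRI** = π_wild / π_dom. π_dom = 0 with π_wild > 0 maps to +∞ and ranks
above every finite value; π_wild = 0 yields NaN and excludes the locus
from DRI ranking (exclusion happens before the percentile cutoff is
computed).

**Sliding windows** are half-open [w, w+10) cM, stepped 1 cM, per
chromosome; the statistic is recomputed over the pooled sites of member
loci (not averaged over per-locus values), matching the behaviour of the
windowed diversity tools this mirrors. Empty windows are emitted as
missing; unmapped loci are skipped with a count.

## CLR sweep test

The composite likelihood ratio contrasts the genome-wide background SFS
(pooled over all contigs, normalized, zero classes floored at 1e−12) with
a sweep model at a test position. At distance d from the position each
lineage escapes the sweep independently with p_e = 1 − exp(−αd). The k
escapees plus the collapsed swept class form an ancestral sample of size
k+1; its derived count m is drawn from the background SFS downsampled
hypergeometrically from n to k+1; the swept lineage is a carrier with
probability m/(k+1) and re-expands to n−k present-day copies, so the
present-day count is n−k+m−1 (swept-class carrier) or m (escapees only).
Counts 0 and n are unobservable and the distribution is renormalized over
1..n−1. The composite likelihood is the product of site probabilities over
the contig's SNPs; CLR = ln max_α CL_sweep − ln CL_background, maximized
on a 40-point log-α grid spanning 1e−6..1 per bp with golden-section
refinement between the best grid point's neighbours. Test positions sit at
1/3 and 2/3 of contig length (two interior grid points, symmetric
coverage); distances are clamped to ≥ 1 bp so a SNP exactly on a grid
point cannot force p_e = 0. Large α recovers the background (every lineage
escapes), so the model nests neutrality and CLR is clipped at 0. CLR
values are reported on the natural-log scale and are comparable only
within a run — absolute values from other software are scale-dependent.
With missing data, sites are downsampled hypergeometrically (seeded) to
the background's sample size; contigs with fewer than 4 usable SNPs are
skipped.

## Null thresholds and outlier calls

Thresholds come from ms-style standard-neutral coalescent simulations
without recombination, conditioned on S: a Kingman genealogy per replicate
(exponential coalescence times at rate C(k,2)), S mutations placed
multinomially on branches proportional to length. S is drawn per replicate
from the observed per-contig segregating-site counts of the scanned
subset; CLR is computed against the pooled SFS of the simulated replicates
themselves, with uniform random site positions. Cutoffs: CLR 99th
percentile; H_norm 99.9th percentile of the negative tail (sweeps generate
high-frequency derived alleles, hence only the lower tail is flagged); DRI
95th percentile of the observed finite empirical DRI values, not of
simulations. Per-test outlier sets feed a union and an "at least two
tests" consensus; overlap significance between scans is the upper-tail
hypergeometric probability.

The fixed-S null with fully linked sites has a heavy CLR tail: single
genealogies with a long basal branch place many mutations in one frequency
class, which the sweep model fits opportunistically. The threshold is
correspondingly conservative, and planted sweeps must carry a coherent
multi-site signal to clear it (see the generator below).

## Structure filters

Sites are kept at minor allele frequency > 0.05 and missing fraction
< 0.5. LD pruning is a greedy left-to-right scan in 50-site windows
stepped by 5: the later member of any pair with haplotype r² > 0.99
(pairwise-complete correlation) is dropped, and the output is audited to
contain no remaining within-window pair above the cutoff. PCA mean-imputes
missing calls per site, centers, scales to unit variance and uses SVD.
Admixture proportions are consumed, never estimated: accessions whose
largest ancestry component is below 0.95 are excluded from the wild
reference panel. Population geographic centers are coordinate-wise medians
(midpoint of the central pair at even counts).

## Ancestry reconstruction

Distances default to the JC69 ML form d = −(3/4)ln(1 − 4p/3) with
p = mismatches / callable sites and invariant sites counted as matches;
p ≥ 3/4 maps to +∞. With two biallelic haplotypes per comparison, richer
substitution models (GTR+Γ) are not identifiable pair-by-pair, and the
procedure only consumes the *ranking* of wild candidates, for which JC69
is monotone in p. The minimal-distance wild set uses a relative tie
tolerance of 1e−9 (float-safe "equally distant"); if the set's population
labels are not a single labelled population, the locus is unassigned for
that domesticate (incomplete lineage sorting, strict reading — unlabeled
or admixed carriers also unassign). Palettes drop unassigned loci and sort
`locus_population` tokens by locus name. Similarity is the standard
Jaccard J = |X∩Y|/|X∪Y|, which satisfies both documented endpoints
(identical palettes → 1, no shared origin → 0); a variant with
denominator |X|+|Y|+|X∩Y| is available behind a flag for comparison but
cannot reach 1 and is not used anywhere. Two empty palettes have undefined
similarity (signalled). The east–west contrast pools carrier-wild
longitudes (not population centers) per locus class and applies the
two-sample Kolmogorov–Smirnov test.

## Synthetic panel generator

The generator is a hierarchical infinite-sites mutation model, not a
structured coalescent: it trades genealogical realism for analytic
transparency — every level of allele sharing is a separate, directly
tunable Poisson mutation layer, so each statistical property the pipeline
must detect is planted explicitly and recoverable from ground truth.

Per locus: an ancestral sequence; `theta_anc` mutations fixed in the whole
ingroup (derived against the outgroups — polarization fodder); per
population, `theta_pop` mutations split into a fixed part (population-
diagnostic markers — these dominate the between-population distance
signal the nearest-wild assignment relies on) and a segregating part
(`pop_seg_fraction`) whose frequencies are uniform on [0.1, 0.6] —
standing variation;
frequencies are capped because a near-fixed standing variant is
indistinguishable from the fixed class. A haplotype drawn from a
population carries the fixed variants plus a Bernoulli(f) draw of each
standing variant. Wild accessions add `theta_acc` private mutations;
domesticates are recent copies of population haplotypes plus only
`theta_dom` privates (the domestication bottleneck leaves no deep
accession-level divergence within the crop). Two outgroups carry only
their own `outgroup_divergence` privates.

Gene flow is a two-donor mosaic: each neutral locus has a base population
and a single donor population, and each domesticate descends from the
donor block with probability `gene_flow_prob` (default 0.4). This shuffles
ancestry tokens (driving the neutral palette similarity down to ≈ 0.33)
without the genome-wide spray of one-off foreign haplotypes that a
per-domesticate uniform re-draw would cause — such a spray floods the SFS
with singletons and near-fixed complement classes and would mask sweep
signatures in the background spectrum. With `gene_flow_prob = 0` every
locus is monophyletic (all domesticates descend from the base
population).

Sweep loci have a single founder haplotype: a draw from the source
population plus an accession-level draw plus `founder_age_theta` private
derived mutations — the founder lineage was sampled from the wild
population at the onset of domestication, so it carries mutations of its
own branch relative to *modern* wild haplotypes. All domesticates copy the
founder plus `theta_dom` privates, except that each domesticate is a
recombinant escapee with a per-locus probability drawn from
`sweep_escape_range` (escape rates differ between sweeps of different age
and strength); an escapee exchanges each founder-distinctive variant
independently with probability `escape_recomb_fraction` for a fresh draw
from the source population. The outcome at a sweep locus is the classic
post-sweep spectrum: strongly reduced π_dom, the founder's derived
variants at high but sub-fixed frequency, and a scatter of low-frequency
recombinant alleles — detectable by CLR and H_norm, with DRI elevated.
Sweep sources alternate between the configured western and eastern
populations (longitude centers > 5° apart), making the longitudinal
KS contrast testable. Truth (per-locus, per-domesticate sources; sweep
set; sample populations) is recorded for parameter-recovery tests.

Default panel: 9 wild populations × 8 accessions, 40 domesticates,
100 neutral + 6 sweep loci of 2000 bp, θ_anc = 2, θ_pop = 22 (8 fixed +
14 segregating), θ_acc = 12, θ_dom = 0.1, founder age 12, gene flow 0.4,
escape rates 0.09–0.2 with recombination fraction 0.8, outgroup divergence
40. These are artifact choices — no generative model for the real panel
exists — set to reproduce, at desk scale, the qualitative regime of a
domestication-resequencing study: π_dom/π_wild ≈ 0.2–0.3 genome-wide,
per-contig segregating sites in the tens, sweep loci rare (≈ 6%),
ancestry assignable at ≈ 97% accuracy, neutral palettes moderately
similar and sweep palettes near-identical.

Loci are spaced 2 cM apart, split contiguously over the seven
chromosomes. Wild coordinates are population centers plus uniform jitter
(±0.75°). The fixed-S neutral simulator used for thresholds is exact:
every replicate carries exactly S derived mutations, and the mean SFS is
proportional to 1/i (verified within 3 standard errors, and against
msprime at the tree level).

### What the generator does not emulate

No within-locus recombination or LD decay (the CLR's spatial dimension is
therefore weakly informative here — detection rests on the SFS shape); no
sequencing error, read-level artifacts or genotype-caller bias; no
heterozygosity (inbred panel assumption); no demographic history beyond
the population labels (no growth, no explicit bottleneck timing, no
isolation by distance within populations); missingness is absent by default and is
exercised separately in unit tests. Passing tests therefore establish the
correctness and calibration of the *statistics* under the planted model,
not the power of the scans on any real demographic history.

## Numerical choices

Internal positions 0-based half-open (VCF 1-based at the boundary); float
outputs written at 6 significant digits; all randomness flows from one
seed per run; thresholds record reps and seed. Degenerate inputs signal
(`UndefinedStatistic` or ValueError) rather than returning 0: π with no
callable sites, H_norm on an empty spectrum or n < 3, similarity of two
empty palettes, KS with a class below two longitudes. Ties in LD pruning
resolve to keeping the earlier site; ties in nearest-wild distance use the
relative tolerance above. The α search is bounded (1e−6..1 per bp) to
avoid the flat neutral plateau at large α; the golden-section result is
compared against the best grid point and the better of the two is kept.

## Known limitations

The CLR's absolute scale depends on the background SFS construction and
is not comparable across software. The fixed-S null is conservative for
data whose sites are less correlated than a single genealogy (as in the
hierarchical generator). GTR+Γ distances are accepted at the interface
but deliberately not implemented beyond JC69 (per-pair identifiability);
the `model` argument validates accordingly. The balanced-subsampling
check controls for locus-count confounding only, not for differences in
per-locus SNP counts between classes.
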