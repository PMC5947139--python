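# sweepscape

Selective-sweep scans and mosaic-ancestry reconstruction for resequenced
crop diversity panels.

Crop domestication leaves two complementary signatures in a panel of wild
and domesticated genomes. First, loci under selection during domestication
(*domestication sweeps*) show strongly reduced diversity in the domesticated
subset and a skewed unfolded site frequency spectrum. Second, because
domesticated genomes are mosaics of ancestral blocks inherited from several
wild source populations, the *origin* of each block can be traced by finding
the wild haplotype nearest to each domesticated haplotype, locus by locus.
`sweepscape` implements both analyses end to end for inbred (haploid-coded)
panels such as barley, plus a seeded synthetic-panel generator that emulates
the structure these analyses assume, so every statistical property of the
pipeline can be exercised and verified without access to a real
resequencing data set.

## What it computes

**Sweep scan** (per reference contig = locus, wild vs domesticated subsets):

- nucleotide diversity π, normalized by segregating *plus* callable
  invariant sites, with missing-data handling;
- the diversity reduction index DRI = π_wild / π_dom;
- Fay & Wu's normalized *H* (Zeng et al. 2006):
  H_norm = (θ_π − θ_L) / √Var, strongly negative when high-frequency
  derived alleles are in excess;
- a composite likelihood ratio (CLR) sweep test against the genome-wide
  background SFS, using the per-lineage escape-probability construction
  p_e = 1 − exp(−αd) (Nielsen et al. 2005), maximized over the sweep
  intensity α at two grid points per contig;
- outlier thresholds from standard-neutral coalescent simulations with
  fixed segregating sites (CLR 99th percentile, H_norm 99.9th lower-tail
  percentile) and the empirical 95th percentile for DRI; union and
  "at least two tests" consensus calls; hypergeometric overlap P-values.

**Ancestry reconstruction** (per domesticate × locus):

- JC69 maximum-likelihood distances to every wild haplotype (invariant
  sites count as matches);
- nearest-wild-allele assignment; ties across populations are treated as
  incomplete lineage sorting and left unassigned;
- ancestry palettes (sorted `locus_population` token sets), pairwise
  Jaccard similarity J = |X∩Y| / |X∪Y|, similarity matrices and medians
  per locus class, balanced locus subsampling;
- the monophyletic-locus fraction and a two-sample Kolmogorov–Smirnov
  contrast of carrier-wild longitudes between neutral and sweep loci.

## Worked example

Run the full pipeline (simulate → polarize → filter → scan → ancestry) at
the default study conditions:

```bash
sweepscape all --out run1 --seed 1
```

which prints

```
outliers union=7 consensus=6 median_J(neutral)=0.351 median_J(sweep)=1.000 KS p=2.97e-120
```

Of the 106 simulated loci (100 neutral + 6 planted sweeps), 7 are outliers
in at least one scan and 6 — the planted sweeps — are supported by at least
two scans. Ancestry palettes restricted to sweep loci are identical across
domesticates (median J = 1.0: all domesticates inherited each sweep locus
from the same wild population), whereas neutral-locus palettes are shuffled
by gene flow (median J ≈ 0.35). The longitudes of the wild accessions
carrying the ancestral haplotypes differ sharply between neutral loci
(spread across all population centers) and sweep loci (confined to the
east/west source populations): KS P ≈ 3e−120.

Artifacts are written next to the report (`scan.tsv`, `assignments.tsv`,
`palettes.tsv`, `similarity_*.tsv`, `thresholds.yaml`, `report.json`); every
number in `report.json` can be recomputed from them —
`sweepscape report --dir run1` does exactly that. The stages are also
available individually (`sweepscape simulate | filter | scan | ancestry`),
each reading the VCF and its sidecar TSVs (samples, genetic map,
invariant-site counts) from disk.

The same stages are available as a library:

```python
from sweepscape import SimConfig, simulate_panel, polarize_alleles
from sweepscape import background_sfs, clr_scan, palette_similarity

alignments, metadata, gmap, truth = simulate_panel(SimConfig(seed=1))
```

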