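"""Synthetic diversity panels and the fixed-S neutral coalescent null.

``simulate_panel`` generates a multi-population panel with the structure the
downstream analyses assume: differentiated wild populations with distinct
geographic centers, domesticated genomes that are per-locus mosaics of
population-ancestral blocks, a designated subset of sweep loci whose
domesticated haplotypes descend from a single shared founder, and two
outgroup accessions for ancestral-allele polarization.

The generator uses a hierarchical infinite-sites mutation model rather than a
full structured coalescent: mutations are Poisson-distributed at four nested
levels (ancestral lineage, population, accession, domesticate), each mutation
hits a new site, and population-level mutations are what make alleles
population-specific.  This keeps the population specificity of alleles — the
quantity the ancestry procedure exploits — analytically transparent and
directly tunable.

``simulate_neutral_fixed_s`` is the classic ms-style standard neutral
coalescent conditioned on the number of segregating sites S: a Kingman tree
is drawn for n samples and S mutations are placed multinomially on branches
proportional to branch length.  It provides the null distribution for the
scan thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (
    CHROMOSOMES,
    ContigAlignment,
    GeneticMap,
    SampleMetadata,
)

#: nine wild population labels with (latitude, longitude) centers emulating a
#: west-to-east gradient across the Fertile Crescent: six southern-Levant
#: clusters, a northern-Levant cluster and two Mesopotamian clusters.
DEFAULT_POP_CENTERS: dict[str, tuple[float, float]] = {
    "CG": (32.7, 35.0),
    "GH": (33.0, 35.7),
    "HG": (33.1, 35.5),
    "JJ": (31.8, 35.4),
    "LM": (33.5, 46.0),
    "NL": (36.3, 36.5),
    "NM": (30.6, 34.8),
    "SCJ": (32.2, 34.9),
    "UM": (37.2, 40.5),
}


@dataclass
class SimConfig:
    """Parameters of the synthetic panel.

    ``theta_*`` are expected mutation counts per locus contributed at each
    level of the hierarchy: ``theta_anc`` fixed in the whole ingroup (derived
    relative to the outgroups), ``theta_pop`` private to one wild population,
    ``theta_acc`` private to one accession-level draw, ``theta_dom`` private
    to one domesticated genome.  A fraction ``pop_seg_fraction`` of each
    population's mutations segregate within it (each member carries the
    allele with the mutation's population frequency, drawn uniformly on
    ``seg_freq_range``) rather than being fixed; a haplotype sampled from
    the population carries its own draw of the standing variants, which is
    what a sweep founder drags to high frequency.  Standing variants are
    capped below high frequency because a near-fixed variant is
    indistinguishable from the fixed class that the fixed part of
    ``theta_pop`` already models.  Gene flow follows a two-donor mosaic: each
    neutral locus has a base population and one historical donor population,
    and each domesticate descends from the donor block with probability
    ``gene_flow_prob`` (sweep-locus sources are never re-drawn).  At sweep
    loci, each locus draws an escape rate from ``sweep_escape_range``; an
    escapee domesticate is a hitchhiking recombinant that exchanges a
    fraction ``escape_recomb_fraction`` of the founder's distinctive
    variants (per variant, independently) for a fresh draw from the source
    population.  Escapees place the founder's derived alleles at high but
    sub-fixed frequency in the domesticated sample — the classic post-sweep
    signature of excess high-frequency derived variants plus a few
    low-frequency recombinant alleles.
    """

    n_wild_per_pop: int = 8
    n_pops: int = 9
    n_dom: int = 40
    n_neutral_loci: int = 100
    n_sweep_loci: int = 6
    locus_length: int = 2000
    theta_anc: float = 2.0
    theta_pop: float = 22.0
    pop_seg_fraction: float = 0.636
    seg_freq_range: tuple[float, float] = (0.1, 0.6)
    theta_acc: float = 12.0
    theta_dom: float = 0.1
    founder_age_theta: float = 12.0
    gene_flow_prob: float = 0.4
    sweep_escape_range: tuple[float, float] = (0.09, 0.2)
    escape_recomb_fraction: float = 0.8
    sweep_sources: dict[str, list[str]] = field(
        default_factory=lambda: {"west": ["SCJ"], "east": ["LM"]}
    )
    pop_centers: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_POP_CENTERS)
    )
    coord_jitter: float = 0.75
    outgroup_divergence: float = 40.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_wild_per_pop", "n_pops", "n_dom", "locus_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.n_neutral_loci < 0 or self.n_sweep_loci < 0:
            raise ValueError("locus counts must be >= 0")
        if self.n_neutral_loci + self.n_sweep_loci == 0:
            raise ValueError("at least one locus is required")
        if self.n_sweep_loci >= self.n_neutral_loci + self.n_sweep_loci and (
            self.n_neutral_loci == 0
        ):
            raise ValueError("there must be at least one neutral locus")
        if not 0.0 <= self.gene_flow_prob <= 1.0:
            raise ValueError("gene_flow_prob must be in [0, 1]")
        elo, ehi = self.sweep_escape_range
        if not 0.0 <= elo <= ehi <= 1.0:
            raise ValueError("sweep_escape_range must satisfy 0 <= lo <= hi <= 1")
        if not 0.0 <= self.escape_recomb_fraction <= 1.0:
            raise ValueError("escape_recomb_fraction must be in [0, 1]")
        if not 0.0 <= self.pop_seg_fraction <= 1.0:
            raise ValueError("pop_seg_fraction must be in [0, 1]")
        lo, hi = self.seg_freq_range
        if not 0.0 < lo <= hi < 1.0:
            raise ValueError("seg_freq_range must satisfy 0 < lo <= hi < 1")
        for name in ("theta_anc", "theta_pop", "theta_acc", "theta_dom",
                     "founder_age_theta", "outgroup_divergence"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if len(self.pop_centers) < self.n_pops:
            raise ValueError(
                f"need >= {self.n_pops} population centers, got {len(self.pop_centers)}"
            )
        pops = set(self.populations)
        for side in ("east", "west"):
            for p in self.sweep_sources.get(side, []):
                if p not in pops:
                    raise ValueError(f"sweep source {p!r} not among populations")

    @property
    def populations(self) -> list[str]:
        return sorted(self.pop_centers)[: self.n_pops]


@dataclass
class SyntheticTruth:
    """Generator ground truth for parameter-recovery tests.

    ``locus_source`` maps each neutral locus to a per-domesticate source
    population and each sweep locus to the single source shared by all
    domesticates.
    """

    locus_source: dict[str, dict[str, str] | str]
    sweep_loci: set[str]
    sample_populations: dict[str, str]

    def source_of(self, locus_id: str, dom: str) -> str:
        src = self.locus_source[locus_id]
        return src if isinstance(src, str) else src[dom]


def simulate_panel(
    config: SimConfig,
) -> tuple[list[ContigAlignment], list[SampleMetadata], GeneticMap, SyntheticTruth]:
    """Generate a seeded synthetic panel.

    Returns one :class:`ContigAlignment` per locus (polarization left to
    :func:`sweepscape.io.polarize_alleles` from the two outgroups), sample
    metadata with wild coordinates jittered around population centers, a
    genetic map with loci evenly spaced over the seven chromosomes, and the
    ground truth.
    """
    rng = np.random.default_rng(config.seed)
    pops = config.populations

    wild_ids = [
        f"W_{p}_{j:02d}" for p in pops for j in range(config.n_wild_per_pop)
    ]
    wild_pop = {
        f"W_{p}_{j:02d}": p for p in pops for j in range(config.n_wild_per_pop)
    }
    dom_ids = [f"DOM_{j:03d}" for j in range(config.n_dom)]
    out_ids = ["OUT_1", "OUT_2"]
    all_ids = wild_ids + dom_ids + out_ids

    # metadata: wild coordinates jitter uniformly around the population center
    metadata: list[SampleMetadata] = []
    for w in wild_ids:
        lat0, lon0 = config.pop_centers[wild_pop[w]]
        j = config.coord_jitter
        metadata.append(
            SampleMetadata(
                accession=w,
                status="wild",
                population=wild_pop[w],
                latitude=float(lat0 + rng.uniform(-j, j)),
                longitude=float(lon0 + rng.uniform(-j, j)),
                q_vector=np.eye(len(pops))[pops.index(wild_pop[w])],
            )
        )
    for d in dom_ids:
        metadata.append(SampleMetadata(accession=d, status="domesticated"))
    for o in out_ids:
        metadata.append(SampleMetadata(accession=o, status="outgroup"))

    n_loci = config.n_neutral_loci + config.n_sweep_loci
    locus_ids = [f"locus{i:04d}" for i in range(n_loci)]
    sweep_ids = {
        str(s)
        for s in rng.choice(locus_ids, size=config.n_sweep_loci, replace=False)
    }

    # sweep sources alternate between the west and east lists
    west = config.sweep_sources.get("west", [])
    east = config.sweep_sources.get("east", [])
    if config.n_sweep_loci and not (west or east):
        raise ValueError("sweep loci requested but no sweep sources configured")
    side_cycle = [s for pair in zip(west, east) for s in pair] or (west + east)
    if not side_cycle:
        side_cycle = west + east

    locus_source: dict[str, dict[str, str] | str] = {}
    alignments: list[ContigAlignment] = []
    sweep_counter = 0
    for locus in locus_ids:
        if locus in sweep_ids:
            src = side_cycle[sweep_counter % len(side_cycle)]
            sweep_counter += 1
            locus_source[locus] = src
        else:
            # two-donor mosaic: a base population plus one historical
            # gene-flow donor; each domesticate descends from the donor
            # block with probability gene_flow_prob
            base = pops[rng.integers(len(pops))]
            others = [p for p in pops if p != base]
            donor = others[rng.integers(len(others))] if others else base
            per_dom: dict[str, str] = {}
            for d in dom_ids:
                if rng.random() < config.gene_flow_prob:
                    per_dom[d] = donor
                else:
                    per_dom[d] = base
            locus_source[locus] = per_dom

        aln = _simulate_locus(
            rng, config, locus, all_ids, wild_ids, wild_pop, dom_ids, out_ids,
            pops, locus_source[locus], locus in sweep_ids,
        )
        alignments.append(aln)

    # genetic map: loci evenly spaced in cM, split contiguously over 7 chromosomes
    per_chrom = -(-n_loci // len(CHROMOSOMES))
    entries = {}
    for i, locus in enumerate(locus_ids):
        chrom = CHROMOSOMES[i // per_chrom]
        entries[locus] = (chrom, 2.0 * (i % per_chrom))
    gmap = GeneticMap(entries=entries, version="synthetic")
    for aln in alignments:
        aln.map_position = gmap.position(aln.locus_id)

    truth = SyntheticTruth(
        locus_source=locus_source,
        sweep_loci=set(sweep_ids),
        sample_populations=dict(wild_pop),
    )
    return alignments, metadata, gmap, truth


def _simulate_locus(
    rng: np.random.Generator,
    config: SimConfig,
    locus: str,
    all_ids: list[str],
    wild_ids: list[str],
    wild_pop: dict[str, str],
    dom_ids: list[str],
    out_ids: list[str],
    pops: list[str],
    source,
    is_sweep: bool,
) -> ContigAlignment:
    # mutation sets as lists of abstract ids; positions assigned afterwards
    next_id = 0

    def fresh(expected: float) -> list[int]:
        nonlocal next_id
        k = int(rng.poisson(expected))
        ids = list(range(next_id, next_id + k))
        next_id += k
        return ids

    anc_mut = fresh(config.theta_anc)
    pop_fixed = {p: fresh(config.theta_pop * (1.0 - config.pop_seg_fraction))
                 for p in pops}
    # standing variants: (mutation id, population frequency)
    lo, hi = config.seg_freq_range
    pop_seg: dict[str, list[tuple[int, float]]] = {}
    for p in pops:
        muts = fresh(config.theta_pop * config.pop_seg_fraction)
        pop_seg[p] = [(mid, rng.uniform(lo, hi)) for mid in muts]

    def draw_from_pop(p: str) -> list[int]:
        """One haplotype sampled from population p (no accession privates)."""
        seg = [mid for mid, f in pop_seg[p] if rng.random() < f]
        return anc_mut + pop_fixed[p] + seg

    hap: dict[str, list[int]] = {}
    for w in wild_ids:
        hap[w] = draw_from_pop(wild_pop[w]) + fresh(config.theta_acc)
    if is_sweep:
        # the founder is a wild haplotype sampled at the onset of
        # domestication: besides an accession-level draw it carries the
        # private derived mutations its own lineage accumulated relative to
        # modern wild haplotypes (founder age) — the variants hitchhiking
        # drags to high frequency in the domesticates
        founder_acc = fresh(config.theta_acc + config.founder_age_theta)
        founder_seg = {mid for mid, f in pop_seg[source] if rng.random() < f}
        founder = anc_mut + pop_fixed[source] + sorted(founder_seg) + founder_acc
        r = config.escape_recomb_fraction
        # sweeps differ in age and strength: each locus gets its own
        # escape rate, which also spreads the founder-allele frequency
        # classes across loci
        escape_prob = rng.uniform(*config.sweep_escape_range)
        for d in dom_ids:
            if rng.random() < escape_prob:
                # recombinant escapee: per variant, keep the founder state
                # with prob 1 - r, otherwise re-draw it from the population
                h = list(anc_mut) + list(pop_fixed[source])
                for mid in founder_acc:
                    if rng.random() < 1.0 - r:
                        h.append(mid)
                for mid, f in pop_seg[source]:
                    carried = mid in founder_seg
                    p_keep = (1.0 - r) + r * f if carried else r * f
                    if rng.random() < p_keep:
                        h.append(mid)
                hap[d] = h + fresh(config.theta_dom)
            else:
                hap[d] = founder + fresh(config.theta_dom)
    else:
        # a domesticate is a recent copy of a population haplotype plus its
        # own privates (domestication bottleneck: no deep accession-level
        # divergence within the domesticated lineage)
        for d in dom_ids:
            hap[d] = draw_from_pop(source[d]) + fresh(config.theta_dom)
    for o in out_ids:
        hap[o] = fresh(config.outgroup_divergence)

    n_mut = next_id
    if n_mut > config.locus_length:
        raise ValueError(
            f"{locus}: {n_mut} mutations exceed locus_length={config.locus_length}; "
            "increase locus_length or reduce thetas"
        )
    positions = np.sort(rng.choice(config.locus_length, size=n_mut, replace=False))
    order = rng.permutation(n_mut)  # mutation id -> site column
    col_of = np.empty(n_mut, dtype=np.intp)
    col_of[order] = np.arange(n_mut)

    derived = np.zeros((len(all_ids), n_mut), dtype=np.int8)
    for row, acc in enumerate(all_ids):
        for mid in hap[acc]:
            derived[row, col_of[mid]] = 1

    # random ref/alt labelling: ancestral allele is REF at ~half the sites
    swap = rng.random(n_mut) < 0.5
    alleles = derived.copy()
    alleles[:, swap] = 1 - alleles[:, swap]

    return ContigAlignment(
        locus_id=locus,
        samples=list(all_ids),
        alleles=alleles,
        site_positions=positions,
        n_invariant_sites=config.locus_length - n_mut,
        contig_length=config.locus_length,
    )


def simulate_neutral_fixed_s(
    n: int,
    S: int,
    reps: int,
    seed: int | np.random.Generator = 0,
) -> list[np.ndarray]:
    """Standard neutral coalescent conditioned on S segregating sites.

    For each replicate a Kingman genealogy is drawn (exponential coalescence
    times at rate C(k, 2) while k lineages remain, no recombination) and S
    mutations are placed multinomially on branches with probability
    proportional to branch length.  Returns ``reps`` derived-allele matrices
    of shape ``(n, S)``; a column's derived count equals the number of leaves
    below the mutated branch, so every replicate has exactly S segregating
    sites (when n >= 2 every branch subtends 1..n-1 leaves).
    """
    if n < 2:
        raise ValueError("need at least two samples")
    if S < 0 or reps < 0:
        raise ValueError("S and reps must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    out: list[np.ndarray] = []
    for _ in range(reps):
        # active lineages: (leaf index array, accumulated branch length)
        active: list[tuple[np.ndarray, float]] = [
            (np.array([i]), 0.0) for i in range(n)
        ]
        branches: list[tuple[np.ndarray, float]] = []
        k = n
        while k > 1:
            t = rng.exponential(2.0 / (k * (k - 1)))
            active = [(leaves, length + t) for leaves, length in active]
            i, j = rng.choice(k, size=2, replace=False)
            if i > j:
                i, j = j, i
            li, lj = active[j], active[i]
            branches.append(lj)
            branches.append(li)
            merged = (np.concatenate([lj[0], li[0]]), 0.0)
            del active[j]
            del active[i]
            active.append(merged)
            k -= 1
        lengths = np.array([b[1] for b in branches])
        mat = np.zeros((n, S), dtype=np.int8)
        if S > 0 and lengths.sum() > 0:
            counts = rng.multinomial(S, lengths / lengths.sum())
            col = 0
            for (leaves, _), c in zip(branches, counts):
                for _ in range(c):
                    mat[leaves, col] = 1
                    col += 1
        out.append(mat)
    return out


def sfs_of_matrix(mat: np.ndarray) -> np.ndarray:
    """Unfolded SFS ``xi[1..n-1]`` of a complete derived-allele matrix."""
    n = mat.shape[0]
    counts = mat.sum(axis=0)
    xi = np.bincount(counts[(counts > 0) & (counts < n)], minlength=n)[1:n]
    return xi.astype(np.int64)
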