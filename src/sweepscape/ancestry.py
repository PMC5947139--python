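"""Mosaic-ancestry reconstruction of domesticated genomes.

Per locus, each domesticated haplotype is assigned to the wild population
carrying the phylogenetically nearest allele (smallest pairwise distance).
When the minimal-distance set spans several populations the allele sharing
predates the population splits (incomplete lineage sorting) and the locus is
left unassigned for that domesticate.  The sorted set of
``locus_population`` tokens of one domesticate is its ancestry palette;
palettes are compared with the Jaccard similarity J = |X n Y| / |X u Y|,
whose endpoints are 1 for identical palettes and 0 when no locus originates
from the same population.

Pairwise distances default to the JC69 maximum-likelihood distance
d = -(3/4) ln(1 - 4p/3) computed from the mismatch proportion p over
callable sites (contig invariant sites count as matches).  With two biallelic
SNP haplotypes per comparison, richer substitution models are not
identifiable per pair, and only the ranking of wild candidates matters here.

The east-west contrast pools the longitudes of the carrier wild accessions
per locus class (neutral vs sweep) and applies the two-sample
Kolmogorov-Smirnov test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import ks_2samp

from .core import MISSING, ContigAlignment, SampleMetadata, metadata_index

TIE_EPS = 1e-9


@dataclass
class AncestryAssignment:
    locus_id: str
    dom_accession: str
    population: str  # population label or "unassigned"
    carrier_wilds: list[str] = field(default_factory=list)
    min_distance: float = math.nan


@dataclass
class AncestryPalette:
    """Sorted locus_population token set for one domesticated accession."""

    dom_accession: str
    tokens: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.tokens = sorted(set(self.tokens))

    def token_set(self) -> frozenset[str]:
        return frozenset(self.tokens)

    def restrict(self, loci: Iterable[str]) -> "AncestryPalette":
        loci = set(loci)
        kept = [t for t in self.tokens if t.rsplit("_", 1)[0] in loci]
        return AncestryPalette(dom_accession=self.dom_accession, tokens=kept)


@dataclass
class SimilarityMatrix:
    accessions: list[str]
    values: np.ndarray
    locus_subset: str = "all"  # neutral | sweep | all

    def median_offdiagonal(self) -> float:
        iu = np.triu_indices(len(self.accessions), k=1)
        vals = self.values[iu]
        vals = vals[~np.isnan(vals)]
        if vals.size == 0:
            raise ValueError("no defined pairwise similarities")
        return float(np.median(vals))


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def pairwise_distance(
    aln: ContigAlignment, a: str, b: str, model: str = "JC69"
) -> float:
    """JC69 ML distance (substitutions/site) between two accessions.

    p = mismatches / callable sites, where callable = SNP sites non-missing
    in both accessions plus the contig's invariant sites (counted as
    matches); d = -(3/4) ln(1 - 4p/3), +inf when p >= 3/4.  Raises when the
    two accessions share no callable site.
    """
    ia, ib = aln.sample_index([a, b])
    return float(
        _distance_rows(
            aln.alleles[ia][None, :], aln.alleles[ib][None, :],
            aln.n_invariant_sites, model,
        )[0, 0]
    )


def _distance_rows(
    A: np.ndarray, B: np.ndarray, n_invariant: int, model: str = "JC69"
) -> np.ndarray:
    """Pairwise distance matrix between row haplotypes of A and of B."""
    if model != "JC69":
        raise ValueError(f"unsupported model {model!r}")
    okA = A != MISSING
    okB = B != MISSING
    both = okA[:, None, :] & okB[None, :, :]
    mismatch = (A[:, None, :] != B[None, :, :]) & both
    callable_ = both.sum(axis=2) + n_invariant
    mism = mismatch.sum(axis=2)
    if np.any(callable_ == 0):
        raise ValueError("zero callable overlap between accessions")
    p = mism / callable_
    d = np.full(p.shape, math.inf)
    ok = p < 0.75
    d[ok] = -0.75 * np.log1p(-4.0 * p[ok] / 3.0)
    return d


# ---------------------------------------------------------------------------
# assignment
# ---------------------------------------------------------------------------

def assign_locus_ancestry(
    aln: ContigAlignment,
    dom: str,
    wild_panel: Sequence[str],
    pop_labels: dict[str, str],
    tie_eps: float = TIE_EPS,
    model: str = "JC69",
) -> AncestryAssignment:
    """Nearest-wild-allele ancestry of one domesticate at one locus.

    The minimal-distance wild set is {w : d(dom, w) <= d_min (1 + tie_eps)
    + tie_eps}; if its population labels are a single population the locus is
    assigned to it, otherwise (incomplete lineage sorting) "unassigned".
    Wilds without a population label in ``pop_labels`` force "unassigned"
    when they enter the minimal set.
    """
    if not wild_panel:
        raise ValueError("empty wild panel")
    idx_d = aln.sample_index([dom])
    idx_w = aln.sample_index(list(wild_panel))
    d = _distance_rows(
        aln.alleles[idx_d], aln.alleles[idx_w], aln.n_invariant_sites, model
    )[0]
    d_min = float(np.min(d))
    if not math.isfinite(d_min):
        return AncestryAssignment(aln.locus_id, dom, "unassigned")
    cutoff = d_min * (1.0 + tie_eps) + tie_eps
    carriers = [w for w, dist in zip(wild_panel, d) if dist <= cutoff]
    pops = {pop_labels.get(w) for w in carriers}
    if len(pops) == 1 and None not in pops:
        return AncestryAssignment(
            aln.locus_id, dom, pops.pop(), carriers, d_min
        )
    return AncestryAssignment(aln.locus_id, dom, "unassigned", carriers, d_min)


def assign_panel_ancestry(
    alignments: Sequence[ContigAlignment],
    dom_ids: Sequence[str],
    wild_panel: Sequence[str],
    pop_labels: dict[str, str],
    tie_eps: float = TIE_EPS,
    model: str = "JC69",
) -> list[AncestryAssignment]:
    """All (domesticate, locus) assignments, vectorized per locus."""
    out: list[AncestryAssignment] = []
    wild_panel = list(wild_panel)
    for aln in alignments:
        idx_d = aln.sample_index(list(dom_ids))
        idx_w = aln.sample_index(wild_panel)
        D = _distance_rows(
            aln.alleles[idx_d], aln.alleles[idx_w], aln.n_invariant_sites, model
        )
        for r, dom in enumerate(dom_ids):
            d = D[r]
            d_min = float(np.min(d))
            if not math.isfinite(d_min):
                out.append(AncestryAssignment(aln.locus_id, dom, "unassigned"))
                continue
            cutoff = d_min * (1.0 + tie_eps) + tie_eps
            carriers = [w for w, dist in zip(wild_panel, d) if dist <= cutoff]
            pops = {pop_labels.get(w) for w in carriers}
            if len(pops) == 1 and None not in pops:
                out.append(
                    AncestryAssignment(aln.locus_id, dom, pops.pop(), carriers, d_min)
                )
            else:
                out.append(
                    AncestryAssignment(aln.locus_id, dom, "unassigned", carriers, d_min)
                )
    return out


# ---------------------------------------------------------------------------
# palettes and similarity
# ---------------------------------------------------------------------------

def build_palette(assignments: Iterable[AncestryAssignment]) -> AncestryPalette:
    """Palette of one domesticate: unassigned loci dropped, tokens
    ``locusid_population`` sorted by locus name."""
    assignments = list(assignments)
    doms = {a.dom_accession for a in assignments}
    if len(doms) != 1:
        raise ValueError("assignments must belong to a single domesticate")
    tokens = [
        f"{a.locus_id}_{a.population}"
        for a in assignments
        if a.population != "unassigned"
    ]
    return AncestryPalette(dom_accession=doms.pop(), tokens=tokens)


def palette_similarity(
    x: AncestryPalette, y: AncestryPalette, printed_formula: bool = False
) -> float:
    """Jaccard similarity of two ancestry palettes.

    Default J = |X n Y| / |X u Y| (1 for identical palettes, 0 for
    disjoint).  ``printed_formula=True`` selects the variant
    |X n Y| / (|X| + |Y| + |X n Y|), provided for comparison; note it does
    not reach 1 on identical palettes.  Two empty palettes are undefined.
    """
    X, Y = x.token_set(), y.token_set()
    if not X and not Y:
        raise ValueError("similarity undefined for two empty palettes")
    inter = len(X & Y)
    if printed_formula:
        return inter / (len(X) + len(Y) + inter)
    return inter / len(X | Y)


def similarity_summary(
    palettes: Sequence[AncestryPalette],
    locus_subset: Iterable[str] | None = None,
    subset_label: str = "all",
) -> SimilarityMatrix:
    """All pairwise J restricted to a locus subset; undefined pairs (both
    palettes empty on the subset) are NaN, diagonal is 1 for non-empty
    palettes."""
    if len(palettes) < 2:
        raise ValueError("need >= 2 palettes")
    if locus_subset is not None:
        palettes = [p.restrict(locus_subset) for p in palettes]
    n = len(palettes)
    vals = np.full((n, n), np.nan)
    for i in range(n):
        vals[i, i] = 1.0 if palettes[i].tokens else np.nan
        for j in range(i + 1, n):
            try:
                v = palette_similarity(palettes[i], palettes[j])
            except ValueError:
                v = np.nan
            vals[i, j] = vals[j, i] = v
    return SimilarityMatrix(
        accessions=[p.dom_accession for p in palettes],
        values=vals,
        locus_subset=subset_label,
    )


def balanced_subsample_median(
    palettes: Sequence[AncestryPalette],
    large_subset: Sequence[str],
    target_size: int,
    reps: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Median J distribution under random locus subsamples of the larger
    subset at the smaller subset's size (controls for subset-size
    confounding of the median similarity)."""
    large_subset = list(large_subset)
    if target_size > len(large_subset):
        raise ValueError("target_size exceeds the subset")
    rng = np.random.default_rng(seed)
    medians = np.empty(reps)
    for r in range(reps):
        pick = rng.choice(len(large_subset), size=target_size, replace=False)
        loci = [large_subset[i] for i in pick]
        medians[r] = similarity_summary(palettes, loci).median_offdiagonal()
    return medians


def monophyletic_fraction(assignments: Iterable[AncestryAssignment]) -> float:
    """Fraction of assigned loci descended from a single wild population in
    every domesticate where they were assigned."""
    per_locus: dict[str, set[str]] = {}
    for a in assignments:
        if a.population == "unassigned":
            continue
        per_locus.setdefault(a.locus_id, set()).add(a.population)
    if not per_locus:
        raise ValueError("no assigned loci")
    mono = sum(1 for pops in per_locus.values() if len(pops) == 1)
    return mono / len(per_locus)


def longitudinal_contrast(
    assignments: Iterable[AncestryAssignment],
    metadata: Sequence[SampleMetadata],
    sweep_loci: set[str],
):
    """Two-sample KS test on carrier-wild longitudes, neutral vs sweep loci.

    Each assignment contributes the longitudes of its carrier wild
    accessions, pooled by locus class.  Returns
    ``(D, p_value, neutral_lons, sweep_lons)``.
    """
    meta = metadata_index(metadata)
    neutral, sweep = [], []
    for a in assignments:
        if a.population == "unassigned":
            continue
        lons = [
            meta[w].longitude
            for w in a.carrier_wilds
            if w in meta and meta[w].longitude is not None
        ]
        (sweep if a.locus_id in sweep_loci else neutral).extend(lons)
    if len(neutral) < 2 or len(sweep) < 2:
        raise ValueError("each locus class needs >= 2 carrier longitudes")
    res = ks_2samp(neutral, sweep)
    return float(res.statistic), float(res.pvalue), np.asarray(neutral), np.asarray(sweep)
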