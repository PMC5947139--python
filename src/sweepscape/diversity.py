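"""Per-locus and sliding-window diversity statistics.

Nucleotide diversity pi is the average number of pairwise differences per
callable site.  With missing data each SNP site contributes
``2 j (m - j) / (m (m - 1))`` — the mean pairwise difference over the m
non-missing alleles carrying j alternates — and the denominator L is the sum
of callable invariant sites and the SNP sites with at least two non-missing
alleles.

The unfolded site frequency spectrum (SFS) counts derived alleles at
polarized sites and handles missing data by hypergeometric projection to a
common sample size m, so that Fay & Wu's H and the composite likelihood
ratio see a single n.

Fay & Wu's normalized H follows Zeng et al. (2006): H = theta_pi - theta_L,
standardized by its neutral variance evaluated at Watterson's theta and the
unbiased theta^2 estimator.  Strongly negative values indicate an excess of
high-frequency derived alleles, the footprint of a recent sweep.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import hypergeom

from .core import MISSING, UNPOLARIZED, ContigAlignment, GeneticMap


@dataclass
class SiteFrequencySpectrum:
    """Unfolded SFS for a sample subset.

    ``xi[i]`` holds the (possibly fractional, after projection) count of
    sites whose derived allele appears ``i+1`` times in a sample of ``n``;
    the vector covers frequencies 1..n-1.
    """

    n: int
    xi: np.ndarray
    n_sites_used: int = 0

    def __post_init__(self) -> None:
        self.xi = np.asarray(self.xi, dtype=float)
        if self.xi.size != self.n - 1:
            raise ValueError(f"xi must have length n-1 = {self.n - 1}")
        if np.any(self.xi < 0):
            raise ValueError("xi entries must be >= 0")

    @property
    def total(self) -> float:
        return float(self.xi.sum())

    @property
    def is_empty(self) -> bool:
        return self.total == 0.0


@dataclass
class ScanRecord:
    """Per-locus bundle of scan statistics and outlier flags."""

    locus_id: str
    pi_wild: float | None = None
    pi_dom: float | None = None
    dri: float | None = None
    h_norm_wild: float | None = None
    h_norm_dom: float | None = None
    clr_dom: float | None = None
    clr_wild: float | None = None
    chromosome: str | None = None
    cm: float | None = None
    flags: dict = field(default_factory=dict)


class UndefinedStatistic(ValueError):
    """Raised when a statistic has no defined value on the given input."""


# ---------------------------------------------------------------------------
# nucleotide diversity
# ---------------------------------------------------------------------------

def nucleotide_diversity(
    aln: ContigAlignment, subset: list[str] | None = None
) -> float:
    """Per-site nucleotide diversity pi for a sample subset.

    Sites with fewer than two non-missing alleles are excluded from both the
    numerator and the callable-length denominator.
    """
    mat = aln.alleles if subset is None else aln.alleles[aln.sample_index(subset)]
    nonmiss = mat != MISSING
    m = nonmiss.sum(axis=0)
    j = np.where(nonmiss, mat, 0).sum(axis=0)
    usable = m >= 2
    L = aln.n_invariant_sites + int(usable.sum())
    if L == 0:
        raise UndefinedStatistic(
            f"{aln.locus_id}: no callable sites for pi"
        )
    mu, ju = m[usable].astype(float), j[usable].astype(float)
    num = float(np.sum(2.0 * ju * (mu - ju) / (mu * (mu - 1.0))))
    return num / L


def diversity_reduction_index(pi_wild: float, pi_dom: float) -> float:
    """DRI = pi_wild / pi_dom.

    ``pi_dom = 0`` with ``pi_wild > 0`` maps to +inf (ranked above every
    finite value); ``pi_wild = 0`` yields NaN, marking the locus for
    exclusion from DRI ranking.
    """
    if pi_wild < 0 or pi_dom < 0:
        raise ValueError("pi must be >= 0")
    if pi_wild == 0.0:
        return math.nan
    if pi_dom == 0.0:
        return math.inf
    return pi_wild / pi_dom


# ---------------------------------------------------------------------------
# unfolded SFS
# ---------------------------------------------------------------------------

def completeness_quantile(
    aln: ContigAlignment, subset: list[str] | None = None, q: float = 0.8
) -> int:
    """Default projection size: the q-quantile of per-site non-missing counts."""
    mat = aln.alleles if subset is None else aln.alleles[aln.sample_index(subset)]
    m = (mat != MISSING).sum(axis=0)
    if m.size == 0:
        return 0
    return int(np.quantile(m, 1.0 - q, method="lower"))


def unfolded_sfs(
    aln: ContigAlignment,
    subset: list[str] | None = None,
    project_to: int | None = None,
) -> SiteFrequencySpectrum:
    """Unfolded SFS over polarized SNP sites, projected to ``project_to``.

    Each polarized site with ``m_i >= project_to`` non-missing calls adds the
    hypergeometric weight P(k derived in a draw of project_to | j of m_i) to
    xi_k; classes k = 0 and k = project_to (monomorphic after projection) are
    dropped.  With complete data and ``project_to = n`` this is the raw
    derived-count histogram.
    """
    der = aln.derived_matrix()
    if subset is not None:
        der = der[aln.sample_index(subset)]
    n_sub = der.shape[0]
    m_target = n_sub if project_to is None else int(project_to)
    if m_target < 2:
        raise ValueError("projection size must be >= 2")
    nonmiss = der != MISSING
    m = nonmiss.sum(axis=0)
    j = np.where(nonmiss, der, 0).sum(axis=0)
    xi = np.zeros(m_target - 1, dtype=float)
    # unpolarized columns arrive as all-missing (m = 0) and are skipped;
    # monomorphic-in-subset sites carry no SFS information
    informative = (m >= m_target) & (j > 0) & (j < m)
    exact = informative & (m == m_target)
    xi += np.bincount(j[exact] - 1, minlength=m_target - 1)[: m_target - 1]
    ks = np.arange(1, m_target)
    for mi, ji in zip(m[informative & ~exact], j[informative & ~exact]):
        xi += hypergeom.pmf(ks, mi, ji, m_target)
    used = int(informative.sum())
    return SiteFrequencySpectrum(n=m_target, xi=xi, n_sites_used=used)


# ---------------------------------------------------------------------------
# Fay & Wu's H (normalized)
# ---------------------------------------------------------------------------

def theta_pi(sfs: SiteFrequencySpectrum) -> float:
    n = sfs.n
    i = np.arange(1, n)
    return float(np.sum(2.0 * i * (n - i) * sfs.xi) / (n * (n - 1)))


def theta_l(sfs: SiteFrequencySpectrum) -> float:
    n = sfs.n
    i = np.arange(1, n)
    return float(np.sum(i * sfs.xi) / (n - 1))


def fay_wu_h(sfs: SiteFrequencySpectrum) -> float:
    """Unnormalized H = theta_pi - theta_L (debugging aid)."""
    return theta_pi(sfs) - theta_l(sfs)


def fay_wu_h_norm(sfs: SiteFrequencySpectrum) -> float:
    """Normalized Fay & Wu H (Zeng et al. 2006).

    Var(theta_pi - theta_L) =
        (n - 2) / (6 (n - 1)) * theta
      + [18 n^2 (3 n + 2) b_{n+1} - (88 n^3 + 9 n^2 - 13 n + 6)]
        / (9 n (n - 1)^2) * theta^2

    with a_n = sum_{i<n} 1/i, b_n = sum_{i<n} 1/i^2, theta estimated by
    Watterson's S / a_n and theta^2 by the unbiased S (S - 1) / (a_n^2 + b_n).
    """
    if sfs.n < 3:
        raise UndefinedStatistic("H_norm needs n >= 3")
    if sfs.is_empty:
        raise UndefinedStatistic("H_norm undefined on an empty spectrum")
    n = sfs.n
    S = sfs.total
    a_n = float(np.sum(1.0 / np.arange(1, n)))
    b_n = float(np.sum(1.0 / np.arange(1, n) ** 2))
    b_n1 = b_n + 1.0 / n**2
    theta_w = S / a_n
    theta_sq = S * (S - 1.0) / (a_n**2 + b_n)
    var = (
        (n - 2.0) / (6.0 * (n - 1.0)) * theta_w
        + (
            18.0 * n**2 * (3.0 * n + 2.0) * b_n1
            - (88.0 * n**3 + 9.0 * n**2 - 13.0 * n + 6.0)
        )
        / (9.0 * n * (n - 1.0) ** 2)
        * theta_sq
    )
    if var <= 0:
        raise UndefinedStatistic("non-positive variance estimate")
    return (theta_pi(sfs) - theta_l(sfs)) / math.sqrt(var)


# ---------------------------------------------------------------------------
# sliding windows
# ---------------------------------------------------------------------------

def sliding_window(
    alignments: list[ContigAlignment],
    gmap: GeneticMap,
    subset: list[str] | None = None,
    window: float = 10.0,
    step: float = 1.0,
    stat: str = "pi",
):
    """Recompute a statistic over the pooled sites of loci in half-open
    [w, w + window) cM windows stepped by ``step`` on each chromosome.

    ``stat`` is ``"pi"`` (pooled numerator over pooled callable length) or
    ``"h_norm"`` (H_norm of the summed unprojected SFS, complete data).
    Windows without member loci are emitted with value ``None``; unmapped
    loci are skipped (their count is returned).
    """
    placed: dict[str, list[tuple[float, ContigAlignment]]] = {}
    n_unmapped = 0
    for aln in alignments:
        pos = aln.map_position or gmap.position(aln.locus_id)
        if pos is None:
            n_unmapped += 1
            continue
        chrom, cm = pos
        placed.setdefault(chrom, []).append((cm, aln))

    rows = []
    for chrom in sorted(placed):
        loci = placed[chrom]
        max_cm = max(cm for cm, _ in loci)
        start = 0.0
        while start <= max_cm:
            members = [a for cm, a in loci if start <= cm < start + window]
            value = None
            if members:
                value = _pooled_stat(members, subset, stat)
            rows.append(
                {"chromosome": chrom, "start_cm": start, "value": value,
                 "n_loci": len(members)}
            )
            start += step
    return rows, n_unmapped


def _pooled_stat(members: list[ContigAlignment], subset, stat: str):
    if stat == "pi":
        num = 0.0
        L = 0
        for aln in members:
            mat = (aln.alleles if subset is None
                   else aln.alleles[aln.sample_index(subset)])
            nonmiss = mat != MISSING
            m = nonmiss.sum(axis=0)
            j = np.where(nonmiss, mat, 0).sum(axis=0)
            usable = m >= 2
            mu, ju = m[usable].astype(float), j[usable].astype(float)
            num += float(np.sum(2.0 * ju * (mu - ju) / (mu * (mu - 1.0))))
            L += aln.n_invariant_sites + int(usable.sum())
        return num / L if L else None
    if stat == "h_norm":
        spectra = [unfolded_sfs(a, subset) for a in members]
        ns = {s.n for s in spectra}
        if len(ns) != 1:
            raise ValueError("pooled H_norm needs a common sample size")
        pooled = SiteFrequencySpectrum(
            n=ns.pop(),
            xi=np.sum([s.xi for s in spectra], axis=0),
            n_sites_used=sum(s.n_sites_used for s in spectra),
        )
        try:
            return fay_wu_h_norm(pooled)
        except UndefinedStatistic:
            return None
    raise ValueError(f"unknown statistic {stat!r}")
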