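"""Composite-likelihood-ratio sweep test, neutral thresholds, outlier calls.

The CLR test contrasts, per contig, the composite likelihood of the observed
derived-allele counts under the genome-wide background SFS against a sweep
model in which each lineage escapes the sweep at distance d from the test
position with probability ``p_e = 1 - exp(-alpha * d)``.  Lineages that do
not escape coalesce into a single ancestral lineage carrying the swept
haplotype; the k escapees plus that lineage form an ancestral sample of size
k + 1 whose derived-allele count is drawn from the background spectrum
downsampled hypergeometrically, and the swept class then re-expands to its
n - k present-day copies.  Monomorphic outcomes (derived count 0 or n) are
unobservable and the site distribution is renormalized over 1..n-1.

The likelihood is maximized over the sweep intensity alpha on a log grid
with golden-section refinement; alpha -> large recovers the background
(every lineage escapes), so the model nests neutrality and the reported
log-ratio is non-negative.

Thresholds come from standard neutral fixed-(S, n) coalescent simulations
(CLR 99th percentile, H_norm lower-tail 99.9th percentile); the DRI cutoff
is the 95th percentile of the observed empirical DRI distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import binom, hypergeom

from .core import MISSING, ContigAlignment
from .diversity import (
    SiteFrequencySpectrum,
    UndefinedStatistic,
    fay_wu_h_norm,
    unfolded_sfs,
)
from .simulate import sfs_of_matrix, simulate_neutral_fixed_s

ALPHA_GRID = np.logspace(-6, 0, 40)  # sweep intensity per bp


@dataclass
class ClrFit:
    locus_id: str
    grid_position: float
    alpha: float
    clr: float
    n_snps_used: int

    def __post_init__(self) -> None:
        if self.clr < 0:
            raise ValueError("clr must be >= 0")
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")


@dataclass
class ThresholdSet:
    clr_99: float
    hnorm_999: float  # lower-tail cutoff (negative); flag H_norm below it
    dri_95: float | None = None
    reps: int = 0
    seed: int = 0


# ---------------------------------------------------------------------------
# background SFS
# ---------------------------------------------------------------------------

def background_sfs(
    alignments: list[ContigAlignment],
    subset: list[str] | None = None,
    project_to: int | None = None,
) -> SiteFrequencySpectrum:
    """Genome-wide unfolded SFS pooled over all contigs (unnormalized counts;
    consumers normalize to frequencies as needed)."""
    spectra = []
    for aln in alignments:
        s = unfolded_sfs(aln, subset, project_to)
        spectra.append(s)
    ns = {s.n for s in spectra}
    if len(ns) != 1:
        raise ValueError("background pooling needs one common projection size")
    xi = np.sum([s.xi for s in spectra], axis=0)
    if xi.sum() == 0:
        raise ValueError("no polarized polymorphic sites genome-wide")
    return SiteFrequencySpectrum(
        n=ns.pop(), xi=xi, n_sites_used=sum(s.n_sites_used for s in spectra)
    )


def _background_probs(sfs: SiteFrequencySpectrum) -> np.ndarray:
    p = sfs.xi / sfs.xi.sum()
    # zero classes would make any observation there impossible under the
    # null; floor them at a tiny pseudo-probability and renormalize
    p = np.maximum(p, 1e-12)
    return p / p.sum()


def _site_class_table(p: np.ndarray) -> np.ndarray:
    """T[k, b]: P(derived count b in the present sample | k escapees).

    ``p`` is the background distribution over derived counts 1..n-1 in a
    sample of n.  Rows k = 0..n; columns b = 0..n (0 and n are the
    unobservable monomorphic classes).
    """
    n = p.size + 1
    T = np.zeros((n + 1, n + 1))
    T[n, 1:n] = p  # all escaped: background unchanged
    js = np.arange(1, n)
    for k in range(n):
        H = k + 1
        # downsample background from n to H: q[m], m = 0..H
        ms = np.arange(H + 1)
        q = np.zeros(H + 1)
        for j, pj in zip(js, p):
            q += pj * hypergeom.pmf(ms, n, j, H)
        for m in range(H + 1):
            if q[m] == 0.0:
                continue
            # the non-escaped (swept) ancestral lineage is a carrier with
            # probability m / H; it contributes n - k present-day copies
            pm = q[m]
            if m > 0:
                b = (n - k) + (m - 1)
                T[k, b] += pm * (m / H)
            T[k, m] += pm * (1.0 - m / H)
    return T


def _clr_loglik(
    counts: np.ndarray,
    dists: np.ndarray,
    alpha: float,
    T: np.ndarray,
    n: int,
) -> float:
    """Composite log-likelihood of derived counts at distances ``dists`` from
    the test position under sweep intensity ``alpha``."""
    p_e = 1.0 - np.exp(-alpha * dists)
    ks = np.arange(n + 1)
    # binomial weights per site over number of escapees (binom.pmf handles
    # the p_e -> 0 and p_e -> 1 boundaries exactly)
    W = binom.pmf(ks[None, :], n, p_e[:, None])
    M = W @ T  # (n_sites, n+1) distribution over b = 0..n
    observable = M[:, 1:n].sum(axis=1)
    probs = M[np.arange(counts.size), counts]
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = np.log(probs) - np.log(observable)
    if not np.all(np.isfinite(ll)):
        return -np.inf
    return float(ll.sum())


def clr_scan(
    aln: ContigAlignment,
    background: SiteFrequencySpectrum,
    subset: list[str] | None = None,
    grid: int = 2,
    min_snps: int = 4,
    rng: np.random.Generator | None = None,
) -> ClrFit | None:
    """Best CLR fit over ``grid`` evenly spaced interior test positions.

    Contigs with fewer than ``min_snps`` polarized polymorphic sites at the
    common sample size are skipped (``None``).  Sites with more non-missing
    calls than the background sample size n are downsampled to n
    hypergeometrically (seeded via ``rng``); identity on complete data.
    """
    n = background.n
    p = _background_probs(background)
    der = aln.derived_matrix()
    if subset is not None:
        der = der[aln.sample_index(subset)]
    nonmiss = der != MISSING
    m = nonmiss.sum(axis=0)
    j = np.where(nonmiss, der, 0).sum(axis=0)

    counts, positions = [], []
    rng = rng or np.random.default_rng(0)
    for col in range(der.shape[1]):
        mi, ji = int(m[col]), int(j[col])
        if mi < n or ji == 0 or ji == mi:
            continue
        if mi > n:
            ji = int(hypergeom.rvs(mi, ji, n, random_state=rng))
            if ji == 0 or ji == n:
                continue
        counts.append(ji)
        positions.append(int(aln.site_positions[col]))
    if len(counts) < min_snps:
        return None
    counts = np.array(counts)
    positions = np.array(positions, dtype=float)
    length = float(aln.contig_length or (positions.max() + 1))

    T = _site_class_table(p)
    null_ll = float(np.log(p[counts - 1]).sum())

    best = None
    for g in range(1, grid + 1):
        x = length * g / (grid + 1)
        dists = np.maximum(np.abs(positions - x), 1.0)

        def ll(log_alpha: float) -> float:
            return _clr_loglik(counts, dists, math.exp(log_alpha), T, n)

        grid_ll = np.array([ll(la) for la in np.log(ALPHA_GRID)])
        i_best = int(np.argmax(grid_ll))
        lo = math.log(ALPHA_GRID[max(i_best - 1, 0)])
        hi = math.log(ALPHA_GRID[min(i_best + 1, ALPHA_GRID.size - 1)])
        la_opt, ll_opt = _golden_section(ll, lo, hi)
        if grid_ll[i_best] > ll_opt:
            la_opt, ll_opt = math.log(ALPHA_GRID[i_best]), grid_ll[i_best]
        clr = max(0.0, ll_opt - null_ll)
        fit = ClrFit(
            locus_id=aln.locus_id,
            grid_position=x,
            alpha=math.exp(la_opt),
            clr=clr,
            n_snps_used=counts.size,
        )
        if best is None or fit.clr > best.clr:
            best = fit
    return best


def _golden_section(f, lo: float, hi: float, tol: float = 1e-3, maxit: int = 40):
    """Maximize f on [lo, hi] by golden-section search."""
    invphi = (math.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = f(c), f(d)
    for _ in range(maxit):
        if b - a < tol:
            break
        if fc > fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = f(d)
    return (c, fc) if fc >= fd else (d, fd)


# ---------------------------------------------------------------------------
# neutral thresholds
# ---------------------------------------------------------------------------

def neutral_clr_hnorm(
    n: int,
    S_list,
    reps: int,
    seed: int,
    locus_length: int = 2000,
    grid: int = 2,
    min_snps: int = 4,
) -> tuple[np.ndarray, np.ndarray]:
    """CLR and H_norm values on ``reps`` standard-neutral fixed-S datasets.

    S is drawn per replicate from ``S_list`` (the observed per-contig
    segregating-site counts).  CLR is computed against the pooled SFS of the
    simulated datasets themselves; site positions are uniform on the locus.
    """
    rng = np.random.default_rng(seed)
    S_list = np.asarray(list(S_list), dtype=int)
    S_draws = S_list[rng.integers(S_list.size, size=reps)]
    mats = [
        simulate_neutral_fixed_s(n, int(S), 1, rng)[0] for S in S_draws
    ]
    pooled = np.zeros(n - 1)
    for mat in mats:
        pooled += sfs_of_matrix(mat)
    bg = SiteFrequencySpectrum(n=n, xi=pooled, n_sites_used=int(pooled.sum()))
    p = _background_probs(bg)
    T = _site_class_table(p)

    clrs, hnorms = [], []
    for mat in mats:
        xi = sfs_of_matrix(mat)
        sfs = SiteFrequencySpectrum(n=n, xi=xi, n_sites_used=int(xi.sum()))
        try:
            hnorms.append(fay_wu_h_norm(sfs))
        except UndefinedStatistic:
            hnorms.append(np.nan)
        counts = mat.sum(axis=0)
        keep = (counts > 0) & (counts < n)
        counts = counts[keep]
        if counts.size < min_snps:
            clrs.append(np.nan)
            continue
        positions = np.sort(rng.integers(locus_length, size=counts.size)).astype(float)
        null_ll = float(np.log(p[counts - 1]).sum())
        best = 0.0
        for g in range(1, grid + 1):
            x = locus_length * g / (grid + 1)
            dists = np.maximum(np.abs(positions - x), 1.0)

            def ll(la: float) -> float:
                return _clr_loglik(counts, dists, math.exp(la), T, n)

            grid_ll = np.array([ll(la) for la in np.log(ALPHA_GRID)])
            i_best = int(np.argmax(grid_ll))
            lo = math.log(ALPHA_GRID[max(i_best - 1, 0)])
            hi = math.log(ALPHA_GRID[min(i_best + 1, ALPHA_GRID.size - 1)])
            _, ll_opt = _golden_section(ll, lo, hi)
            ll_opt = max(ll_opt, grid_ll[i_best])
            best = max(best, max(0.0, ll_opt - null_ll))
        clrs.append(best)
    return np.asarray(clrs), np.asarray(hnorms)


def neutral_thresholds(
    n: int,
    S_list,
    reps: int = 1000,
    seed: int = 0,
    dri_values=None,
    locus_length: int = 2000,
) -> ThresholdSet:
    """Percentile cutoffs from the neutral null (and the empirical DRI tail).

    ``clr_99``: 99th percentile of neutral CLR.  ``hnorm_999``: the 99.9th
    percentile of the magnitude of the negative tail, returned as a negative
    cutoff (sweeps generate high-frequency derived alleles, hence the lower
    tail).  ``dri_95``: 95th percentile of the observed finite DRI values
    (loci with pi_wild = 0 excluded beforehand), not simulated.
    """
    if reps < 100:
        raise ValueError("need >= 100 replicates for percentile thresholds")
    clrs, hnorms = neutral_clr_hnorm(n, S_list, reps, seed, locus_length)
    clr_99 = float(np.nanpercentile(clrs, 99.0))
    hnorm_999 = -float(np.nanpercentile(-hnorms, 99.9))
    dri_95 = None
    if dri_values is not None:
        finite = np.asarray(
            [d for d in dri_values if d is not None and np.isfinite(d)], dtype=float
        )
        if finite.size:
            dri_95 = float(np.percentile(finite, 95.0))
    return ThresholdSet(
        clr_99=clr_99, hnorm_999=hnorm_999, dri_95=dri_95, reps=reps, seed=seed
    )


# ---------------------------------------------------------------------------
# outlier calling and overlap significance
# ---------------------------------------------------------------------------

@dataclass
class OutlierCalls:
    clr: set[str] = field(default_factory=set)
    hnorm: set[str] = field(default_factory=set)
    dri: set[str] = field(default_factory=set)
    union: set[str] = field(default_factory=set)
    consensus: set[str] = field(default_factory=set)  # >= 2 tests


def call_outliers(records, thresholds: ThresholdSet) -> OutlierCalls:
    """Flag per-test outliers and the at-least-two-tests consensus.

    CLR: ``clr_dom > clr_99``; H_norm: ``h_norm_dom < hnorm_999`` (lower
    tail); DRI: ``dri >= dri_95`` including +inf (pi_wild = 0 loci carry
    NaN DRI and are never flagged).
    """
    calls = OutlierCalls()
    for rec in records:
        lid = rec.locus_id
        if rec.clr_dom is not None and rec.clr_dom > thresholds.clr_99:
            calls.clr.add(lid)
        if (
            rec.h_norm_dom is not None
            and np.isfinite(rec.h_norm_dom)
            and rec.h_norm_dom < thresholds.hnorm_999
        ):
            calls.hnorm.add(lid)
        if (
            thresholds.dri_95 is not None
            and rec.dri is not None
            and not math.isnan(rec.dri)
            and rec.dri >= thresholds.dri_95
        ):
            calls.dri.add(lid)
    calls.union = calls.clr | calls.hnorm | calls.dri
    calls.consensus = (
        (calls.clr & calls.hnorm)
        | (calls.clr & calls.dri)
        | (calls.hnorm & calls.dri)
    )
    return calls


def overlap_significance(set_a: set, set_b: set, universe_size: int) -> float:
    """Upper-tail hypergeometric P(X >= |A and B|) for the overlap of two
    outlier sets drawn from a universe of ``universe_size`` loci."""
    a, b = len(set_a), len(set_b)
    k = len(set_a & set_b)
    if a > universe_size or b > universe_size:
        raise ValueError("set sizes exceed the universe")
    return float(hypergeom.sf(k - 1, universe_size, a, b))
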