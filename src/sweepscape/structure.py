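"""Variant and sample filters feeding structure-sensitive analyses.

MAF/missingness site filters, greedy windowed LD pruning, genotype PCA, the
admixture-threshold sample filter (accessions must carry >= 95% of a single
population's ancestry component to count as non-admixed), and median-based
population geographic centers.

Admixture proportions are consumed, not estimated: the Q-matrix comes from an
external model-based clustering run (or from the synthetic generator's
truth) and this module only applies the threshold rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import MISSING, SampleMetadata


@dataclass
class FilterConfig:
    maf_min: float = 0.05
    missing_max: float = 0.5
    r2_max: float = 0.99
    q_single_pop_min: float = 0.95
    ld_window: int = 50
    ld_step: int = 5

    def __post_init__(self) -> None:
        for name in ("maf_min", "missing_max", "r2_max", "q_single_pop_min"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {v}")


def filter_variants(
    matrix: np.ndarray, cfg: FilterConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Keep sites with minor-allele frequency > ``maf_min`` and missing-data
    fraction < ``missing_max``.  Returns (filtered matrix, kept-site mask)."""
    cfg = cfg or FilterConfig()
    mat = np.asarray(matrix)
    nonmiss = mat != MISSING
    m = nonmiss.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(m > 0, np.where(nonmiss, mat, 0).sum(axis=0) / m, 0.0)
    maf = np.minimum(freq, 1.0 - freq)
    miss_frac = 1.0 - m / mat.shape[0]
    keep = (maf > cfg.maf_min) & (miss_frac < cfg.missing_max)
    return mat[:, keep], keep


def haplotype_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared haplotype correlation of two biallelic sites on
    pairwise-complete samples; equals D^2 / (p1 q1 p2 q2)."""
    ok = (x != MISSING) & (y != MISSING)
    if ok.sum() < 2:
        return 0.0
    xv, yv = x[ok].astype(float), y[ok].astype(float)
    if xv.std() == 0.0 or yv.std() == 0.0:
        return 0.0
    r = np.corrcoef(xv, yv)[0, 1]
    return float(r * r)


def ld_prune(
    matrix: np.ndarray, r2_max: float = 0.99, window: int = 50, step: int = 5
) -> np.ndarray:
    """Greedy left-to-right LD pruning within a sliding site window.

    For every pair of still-kept sites within a window with haplotype
    r^2 > ``r2_max``, the later site is dropped.  Returns the indices of kept
    sites (into the input column order).
    """
    mat = np.asarray(matrix)
    n_sites = mat.shape[1]
    keep = np.ones(n_sites, dtype=bool)
    start = 0
    while start < n_sites:
        stop = min(start + window, n_sites)
        idx = [i for i in range(start, stop) if keep[i]]
        block = mat[:, idx]
        r2 = None
        if len(idx) > 1 and not np.any(block == MISSING):
            # complete-data fast path: one correlation matrix per window
            with np.errstate(invalid="ignore", divide="ignore"):
                r2 = np.nan_to_num(np.corrcoef(block.T.astype(float))) ** 2
        for a_pos, i in enumerate(idx):
            if not keep[i]:
                continue
            for b_pos in range(a_pos + 1, len(idx)):
                jj = idx[b_pos]
                if not keep[jj]:
                    continue
                r2_ij = (
                    r2[a_pos, b_pos]
                    if r2 is not None
                    else haplotype_r2(mat[:, i], mat[:, jj])
                )
                if r2_ij > r2_max:
                    keep[jj] = False
        if stop == n_sites:
            break
        start += step
    return np.flatnonzero(keep)


def pca(matrix: np.ndarray, n_components: int = 10, scale: bool = True):
    """Genotype PCA: per-site mean imputation of missing calls, centering
    (and unit-variance scaling), then SVD.

    Returns ``(scores, variance_fractions)`` with scores per accession.
    """
    mat = np.asarray(matrix, dtype=float)
    mat[np.asarray(matrix) == MISSING] = np.nan
    col_mean = np.nanmean(mat, axis=0)
    informative = ~np.isnan(col_mean)
    mat = mat[:, informative]
    col_mean = col_mean[informative]
    inds = np.where(np.isnan(mat))
    mat[inds] = np.take(col_mean, inds[1])
    centered = mat - col_mean
    if scale:
        sd = centered.std(axis=0)
        nonconst = sd > 0
        centered = centered[:, nonconst] / sd[nonconst]
    if centered.shape[1] < 2:
        raise ValueError("fewer than 2 informative sites for PCA")
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    var = s**2
    frac = var / var.sum()
    k = min(n_components, s.size)
    return u[:, :k] * s[:k], frac[:k]


def admixture_filter(
    metadata: Sequence[SampleMetadata],
    q_min: float = 0.95,
    strict: bool = False,
) -> list[str]:
    """Accessions whose largest ancestry component is >= ``q_min``.

    Accessions without a q_vector are retained with a warning unless
    ``strict``, in which case they raise.
    """
    import logging

    kept = []
    n_missing = 0
    for m in metadata:
        if m.q_vector is None:
            if strict:
                raise ValueError(f"{m.accession}: missing q_vector in strict mode")
            n_missing += 1
            kept.append(m.accession)
        elif float(np.max(m.q_vector)) >= q_min:
            kept.append(m.accession)
    if n_missing:
        logging.getLogger(__name__).warning(
            "%d accession(s) without q_vector retained unfiltered", n_missing
        )
    return kept


def population_geographic_centers(
    metadata: Sequence[SampleMetadata],
) -> dict[str, tuple[float, float]]:
    """Coordinate-wise median (latitude, longitude) per population; even
    member counts take the midpoint of the central pair.  Populations with no
    geolocated member are omitted."""
    coords: dict[str, list[tuple[float, float]]] = {}
    for m in metadata:
        if m.population is None or m.latitude is None or m.longitude is None:
            continue
        coords.setdefault(m.population, []).append((m.latitude, m.longitude))
    return {
        pop: (
            float(np.median([c[0] for c in pts])),
            float(np.median([c[1] for c in pts])),
        )
        for pop, pts in coords.items()
    }
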