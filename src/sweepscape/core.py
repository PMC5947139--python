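"""Core containers: per-contig alignments, sample metadata, genetic map.

Allele matrices are ``int8`` with codes ``0`` (ref), ``1`` (alt) and ``-1``
(missing).  Each accession contributes a single haplotype: the panels this
package targets are inbred (single-seed descent), so a sample is a haploid
sequence and heterozygous calls are treated as missing upstream.

Site positions are stored 0-based half-open internally; VCF input/output
converts from/to 1-based coordinates at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

MISSING = -1

#: per-site ancestral-state codes
ANC_REF = 0
ANC_ALT = 1
UNPOLARIZED = -1

CHROMOSOMES = tuple(f"{i}H" for i in range(1, 8))


@dataclass
class ContigAlignment:
    """Sample x site allele matrix for one reference contig (locus).

    Parameters
    ----------
    locus_id:
        Contig name; also the locus identifier used in ancestry palettes.
    samples:
        Ordered accession ids, one haplotype each.
    alleles:
        ``(n_samples, n_sites)`` int8 matrix over {0, 1, -1}.
    site_positions:
        0-based positions within the contig, strictly increasing.
    ancestral_state:
        Per-site code: 0 = ref ancestral, 1 = alt ancestral, -1 = unpolarized.
    n_invariant_sites:
        Number of monomorphic callable sites on the contig; enters the
        denominator of per-site diversity and the match count of pairwise
        distances.
    map_position:
        ``(chromosome, cM)`` or ``None`` when the contig is unplaced.
    """

    locus_id: str
    samples: list[str]
    alleles: np.ndarray
    site_positions: np.ndarray
    ancestral_state: np.ndarray | None = None
    n_invariant_sites: int = 0
    map_position: tuple[str, float] | None = None
    contig_length: int | None = None

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        self.site_positions = np.asarray(self.site_positions, dtype=np.int64)
        if self.alleles.ndim != 2:
            raise ValueError("alleles must be a 2-D sample x site matrix")
        if self.alleles.shape[0] != len(self.samples):
            raise ValueError(
                f"{self.locus_id}: {len(self.samples)} samples but "
                f"{self.alleles.shape[0]} matrix rows"
            )
        if self.alleles.shape[1] != self.site_positions.size:
            raise ValueError(f"{self.locus_id}: site count mismatch")
        if self.site_positions.size > 1 and not np.all(
            np.diff(self.site_positions) > 0
        ):
            raise ValueError(f"{self.locus_id}: positions must strictly increase")
        if self.n_invariant_sites < 0:
            raise ValueError("n_invariant_sites must be >= 0")
        if self.ancestral_state is None:
            self.ancestral_state = np.full(self.n_sites, UNPOLARIZED, dtype=np.int8)
        else:
            self.ancestral_state = np.asarray(self.ancestral_state, dtype=np.int8)
            if self.ancestral_state.size != self.n_sites:
                raise ValueError(f"{self.locus_id}: ancestral_state size mismatch")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]

    def sample_index(self, accessions: Sequence[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.array([lookup[a] for a in accessions], dtype=np.intp)
        except KeyError as exc:  # pragma: no cover - message only
            raise KeyError(f"accession {exc} not in alignment {self.locus_id}")

    def subset(self, accessions: Sequence[str]) -> "ContigAlignment":
        """Row-subset of the matrix for the given accessions (same sites)."""
        idx = self.sample_index(accessions)
        return ContigAlignment(
            locus_id=self.locus_id,
            samples=list(accessions),
            alleles=self.alleles[idx],
            site_positions=self.site_positions.copy(),
            ancestral_state=self.ancestral_state.copy(),
            n_invariant_sites=self.n_invariant_sites,
            map_position=self.map_position,
            contig_length=self.contig_length,
        )

    def derived_matrix(self) -> np.ndarray:
        """Matrix recoded as 0 = ancestral, 1 = derived, -1 = missing/unpolarized.

        Columns without an assigned ancestral state are entirely -1; downstream
        unfolded-SFS statistics skip them.
        """
        out = np.full_like(self.alleles, MISSING)
        anc = self.ancestral_state
        pol = anc != UNPOLARIZED
        if not np.any(pol):
            return out
        obs = self.alleles[:, pol]
        der = np.where(obs == MISSING, MISSING, (obs != anc[pol][None, :]).astype(np.int8))
        out[:, pol] = der
        return out


@dataclass
class SampleMetadata:
    """One accession of the diversity panel."""

    accession: str
    status: str  # wild | domesticated | outgroup
    population: str | None = None
    latitude: float | None = None
    longitude: float | None = None
    q_vector: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.status not in ("wild", "domesticated", "outgroup"):
            raise ValueError(f"unknown status {self.status!r}")
        if self.q_vector is not None:
            self.q_vector = np.asarray(self.q_vector, dtype=float)
            if abs(float(self.q_vector.sum()) - 1.0) > 1e-6:
                raise ValueError(
                    f"{self.accession}: q_vector must sum to 1 "
                    f"(got {self.q_vector.sum():.6f})"
                )


def samples_by_status(metadata: Sequence[SampleMetadata], status: str) -> list[str]:
    return [m.accession for m in metadata if m.status == status]


def metadata_index(metadata: Sequence[SampleMetadata]) -> dict[str, SampleMetadata]:
    return {m.accession: m for m in metadata}


@dataclass
class GeneticMap:
    """Locus -> (chromosome, cM) lookup for one map dialect.

    Two map versions of the reference exist historically; all analyses run on
    a single chosen version, identified by ``version``.
    """

    entries: Mapping[str, tuple[str, float]] = field(default_factory=dict)
    version: str = "default"

    def __post_init__(self) -> None:
        for locus, (chrom, cm) in self.entries.items():
            if chrom not in CHROMOSOMES:
                raise ValueError(f"{locus}: chromosome {chrom!r} not in {CHROMOSOMES}")
            if cm < 0:
                raise ValueError(f"{locus}: negative cM position")

    def position(self, locus_id: str) -> tuple[str, float] | None:
        return self.entries.get(locus_id)

    def __len__(self) -> int:
        return len(self.entries)
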