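"""Reading and writing of the standard formats.

VCF input is parsed with :mod:`cyvcf2`.  The panel is inbred, so samples are
haploid: haploid genotypes are taken as-is, homozygous diploid calls are
collapsed to one allele, and heterozygous diploid calls are set to missing
rather than resolved to a random allele.  Multi-allelic sites are skipped
with a warning.

VCF lacks the count of callable invariant sites per contig, which the
per-site diversity normalization and pairwise distances require; it is
supplied through a sidecar TSV (``contig<TAB>n_callable_invariant``), which
the simulator writes alongside the VCF.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .core import (
    ANC_ALT,
    ANC_REF,
    MISSING,
    UNPOLARIZED,
    ContigAlignment,
    GeneticMap,
    SampleMetadata,
)

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.6g"


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def write_vcf(
    alignments: Iterable[ContigAlignment],
    path: str | Path,
) -> None:
    """Write haploid biallelic genotypes as a VCF 4.2 text file.

    Internal 0-based site positions become 1-based POS; ref/alt codes map to
    arbitrary but fixed bases (A/G).
    """
    path = Path(path)
    alignments = list(alignments)
    if not alignments:
        raise ValueError("no alignments to write")
    samples = alignments[0].samples
    gt_str = {0: "0", 1: "1", MISSING: "."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=sweepscape\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for aln in alignments:
            length = aln.contig_length or (int(aln.site_positions[-1]) + 1
                                           if aln.n_sites else 1)
            fh.write(f"##contig=<ID={aln.locus_id},length={length}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples) + "\n"
        )
        for aln in alignments:
            if aln.samples != samples:
                raise ValueError("all alignments must share the sample order")
            for col in range(aln.n_sites):
                pos = int(aln.site_positions[col]) + 1
                gts = "\t".join(gt_str[int(g)] for g in aln.alleles[:, col])
                fh.write(
                    f"{aln.locus_id}\t{pos}\t.\tA\tG\t.\tPASS\t.\tGT\t{gts}\n"
                )


def read_genotypes(
    vcf_path: str | Path,
    metadata: Sequence[SampleMetadata] | None = None,
    invariant_sites: dict[str, int] | None = None,
    genetic_map: GeneticMap | None = None,
) -> list[ContigAlignment]:
    """Build one :class:`ContigAlignment` per contig from a VCF.

    ``invariant_sites`` maps contig -> number of callable monomorphic sites
    (see :func:`read_invariant_sites`); contigs absent from it get 0.
    """
    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    if metadata is not None:
        known = {m.accession for m in metadata}
        unknown = [s for s in samples if s not in known]
        if unknown:
            raise ValueError(f"VCF samples not in metadata: {unknown}")
    invariant_sites = invariant_sites or {}

    per_contig: dict[str, list[tuple[int, np.ndarray]]] = {}
    order: list[str] = []
    for var in vcf:
        if len(var.ALT) != 1:
            logger.warning(
                "skipping multi-allelic site %s:%d", var.CHROM, var.POS
            )
            continue
        row = np.empty(len(samples), dtype=np.int8)
        for i, g in enumerate(var.genotypes):
            calls = g[:-1]  # trailing element is the phase flag
            if any(c < 0 for c in calls):
                row[i] = MISSING
            elif len(set(calls)) == 1:
                row[i] = calls[0]
            else:
                row[i] = MISSING  # heterozygous: inbred panel convention
        per_contig.setdefault(var.CHROM, [])
        if var.CHROM not in order:
            order.append(var.CHROM)
        per_contig[var.CHROM].append((var.POS - 1, row))

    alignments = []
    for contig in order:
        sites = sorted(per_contig[contig], key=lambda t: t[0])
        positions = np.array([p for p, _ in sites], dtype=np.int64)
        mat = np.column_stack([r for _, r in sites]).astype(np.int8)
        aln = ContigAlignment(
            locus_id=contig,
            samples=samples,
            alleles=mat,
            site_positions=positions,
            n_invariant_sites=int(invariant_sites.get(contig, 0)),
            map_position=genetic_map.position(contig) if genetic_map else None,
        )
        alignments.append(aln)
    return alignments


# ---------------------------------------------------------------------------
# polarization
# ---------------------------------------------------------------------------

def polarize_alleles(
    aln: ContigAlignment, outgroup_ids: Sequence[str]
) -> ContigAlignment:
    """Assign per-site ancestral states from two outgroup accessions.

    A site's ancestral allele is the allele carried identically by both
    outgroups (and matching ref or alt, which biallelic coding guarantees);
    any disagreement or missing outgroup call leaves the site unpolarized.
    Already-assigned states are never flipped (idempotent).
    """
    if len(outgroup_ids) != 2:
        raise ValueError("exactly two outgroup accessions are required")
    idx = aln.sample_index(outgroup_ids)
    o1, o2 = aln.alleles[idx[0]], aln.alleles[idx[1]]
    anc = np.where(
        (o1 == o2) & (o1 != MISSING), o1, UNPOLARIZED
    ).astype(np.int8)
    prev = aln.ancestral_state
    keep = prev != UNPOLARIZED
    anc[keep] = prev[keep]
    out = ContigAlignment(
        locus_id=aln.locus_id,
        samples=list(aln.samples),
        alleles=aln.alleles.copy(),
        site_positions=aln.site_positions.copy(),
        ancestral_state=anc,
        n_invariant_sites=aln.n_invariant_sites,
        map_position=aln.map_position,
        contig_length=aln.contig_length,
    )
    return out


# ---------------------------------------------------------------------------
# TSV sidecars
# ---------------------------------------------------------------------------

def write_samples_tsv(metadata: Sequence[SampleMetadata], path: str | Path) -> None:
    rows = []
    for m in metadata:
        row = {
            "accession": m.accession,
            "status": m.status,
            "population": m.population if m.population is not None else "NA",
            "lat": "NA" if m.latitude is None else f"{m.latitude:.6f}",
            "lon": "NA" if m.longitude is None else f"{m.longitude:.6f}",
        }
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_samples_tsv(path: str | Path) -> list[SampleMetadata]:
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=["NA"])
    out = []
    for _, r in df.iterrows():
        out.append(
            SampleMetadata(
                accession=r["accession"],
                status=r["status"],
                population=None if pd.isna(r["population"]) else r["population"],
                latitude=None if pd.isna(r["lat"]) else float(r["lat"]),
                longitude=None if pd.isna(r["lon"]) else float(r["lon"]),
            )
        )
    return out


def write_map_tsv(gmap: GeneticMap, path: str | Path) -> None:
    rows = [
        {"contig": locus, "chromosome": chrom, "cM": f"{cm:.4f}"}
        for locus, (chrom, cm) in sorted(gmap.entries.items())
    ]
    pd.DataFrame(rows, columns=["contig", "chromosome", "cM"]).to_csv(
        path, sep="\t", index=False
    )


def read_map_tsv(path: str | Path, version: str = "default") -> GeneticMap:
    df = pd.read_csv(path, sep="\t", dtype={"contig": str, "chromosome": str})
    entries = {
        r["contig"]: (r["chromosome"], float(r["cM"])) for _, r in df.iterrows()
    }
    return GeneticMap(entries=entries, version=version)


def write_invariant_sites(counts: dict[str, int], path: str | Path) -> None:
    pd.DataFrame(
        [{"contig": c, "n_callable_invariant": n} for c, n in sorted(counts.items())]
    ).to_csv(path, sep="\t", index=False)


def read_invariant_sites(path: str | Path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", dtype={"contig": str})
    return {r["contig"]: int(r["n_callable_invariant"]) for _, r in df.iterrows()}


def write_truth_tsv(truth, path: str | Path) -> None:
    """Flat per-(locus, domesticate) truth table; sweep loci repeat their
    shared source for every domesticate with dom = '*'. """
    rows = []
    for locus, src in sorted(truth.locus_source.items()):
        sweep = int(locus in truth.sweep_loci)
        if isinstance(src, str):
            rows.append({"locus": locus, "dom": "*", "source": src, "sweep": sweep})
        else:
            for dom, s in sorted(src.items()):
                rows.append({"locus": locus, "dom": dom, "source": s, "sweep": sweep})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_truth_tsv(path: str | Path):
    from .simulate import SyntheticTruth

    df = pd.read_csv(path, sep="\t", dtype=str)
    locus_source: dict[str, dict[str, str] | str] = {}
    sweep_loci: set[str] = set()
    for locus, grp in df.groupby("locus"):
        if int(grp["sweep"].iloc[0]):
            sweep_loci.add(locus)
        if (grp["dom"] == "*").all():
            locus_source[locus] = grp["source"].iloc[0]
        else:
            locus_source[locus] = dict(zip(grp["dom"], grp["source"]))
    return SyntheticTruth(
        locus_source=locus_source, sweep_loci=sweep_loci, sample_populations={}
    )


def write_qmatrix_tsv(
    metadata: Sequence[SampleMetadata], populations: Sequence[str], path: str | Path
) -> None:
    rows = []
    for m in metadata:
        if m.q_vector is None:
            continue
        row = {"accession": m.accession}
        row.update({p: f"{q:.6f}" for p, q in zip(populations, m.q_vector)})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_qmatrix_tsv(path: str | Path) -> dict[str, np.ndarray]:
    df = pd.read_csv(path, sep="\t")
    return {
        str(r["accession"]): r.drop("accession").to_numpy(dtype=float)
        for _, r in df.iterrows()
    }


# ---------------------------------------------------------------------------
# result tables
# ---------------------------------------------------------------------------

def write_results(records: pd.DataFrame | list, path: str | Path,
                  columns: Sequence[str] | None = None) -> None:
    """Write a result table with deterministic column order and fixed float
    precision; an empty record list yields a header-only file."""
    if not isinstance(records, pd.DataFrame):
        records = pd.DataFrame(list(records), columns=columns)
    elif columns is not None:
        records = records[list(columns)]
    records.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
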