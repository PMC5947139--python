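"""Config-driven end-to-end runs: simulate -> filter -> scan -> ancestry.

Each stage is a function over in-memory panels that writes its tables to
the run directory, so stages can run standalone from files (via the CLI
subcommands) or composed in :func:`run_pipeline`; every number in the
final report can be recomputed from the artifacts on disk.  All randomness
flows from the single seed in the configuration.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import ancestry as anc
from . import io as sio
from . import structure as st
from . import sweep as sw
from .core import ContigAlignment, SampleMetadata, samples_by_status
from .diversity import (
    ScanRecord,
    UndefinedStatistic,
    diversity_reduction_index,
    fay_wu_h_norm,
    nucleotide_diversity,
    unfolded_sfs,
)
from .simulate import SimConfig, simulate_panel

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    out_dir: str = "run"
    seed: int = 0
    sim: dict = field(default_factory=dict)
    scan_reps: int = 300
    scan_grid: int = 2
    scan_min_snps: int = 4
    tie_eps: float = anc.TIE_EPS
    distance_model: str = "JC69"
    filters: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        try:
            return cls(**data)
        except TypeError as exc:
            raise ValueError(f"invalid pipeline config: {exc}") from exc

    def filter_config(self) -> st.FilterConfig:
        try:
            return st.FilterConfig(**self.filters) if self.filters else st.FilterConfig()
        except TypeError as exc:
            raise ValueError(f"invalid filter config: {exc}") from exc


@dataclass
class RunReport:
    seed: int
    n_loci: int = 0
    n_samples: int = 0
    n_scan_records: int = 0
    outliers: dict = field(default_factory=dict)
    overlap_pvalues: dict = field(default_factory=dict)
    n_assigned: int = 0
    n_unassigned: int = 0
    ancestry_accuracy: float | None = None
    monophyletic_fraction: float | None = None
    median_j: dict = field(default_factory=dict)
    ks: dict = field(default_factory=dict)
    thresholds: dict = field(default_factory=dict)
    stage_seconds: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------

def load_panel(
    vcf: str | Path,
    samples: str | Path,
    invariant: str | Path | None = None,
    map_tsv: str | Path | None = None,
    polarize: bool = True,
) -> tuple[list[ContigAlignment], list[SampleMetadata]]:
    """Read a panel from files and polarize against the outgroups."""
    metadata = sio.read_samples_tsv(samples)
    inv = sio.read_invariant_sites(invariant) if invariant else None
    gmap = sio.read_map_tsv(map_tsv) if map_tsv else None
    alignments = sio.read_genotypes(vcf, metadata, inv, gmap)
    if polarize:
        out_ids = samples_by_status(metadata, "outgroup")
        if len(out_ids) == 2:
            alignments = [sio.polarize_alleles(a, out_ids) for a in alignments]
        else:
            logger.warning(
                "%d outgroup accessions found; skipping polarization",
                len(out_ids),
            )
    return alignments, metadata


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(config: PipelineConfig, out: Path):
    try:
        sim_cfg = SimConfig(**{**config.sim, "seed": config.seed})
        alignments, metadata, gmap, truth = simulate_panel(sim_cfg)
    except (TypeError, ValueError) as exc:
        raise StageError("simulate", str(exc)) from exc
    sio.write_vcf(alignments, out / "panel.vcf")
    sio.write_samples_tsv(metadata, out / "samples.tsv")
    sio.write_map_tsv(gmap, out / "map.tsv")
    sio.write_invariant_sites(
        {a.locus_id: a.n_invariant_sites for a in alignments},
        out / "invariant_sites.tsv",
    )
    sio.write_truth_tsv(truth, out / "truth.tsv")
    return alignments, metadata, gmap, truth


def stage_filter(alignments, metadata, config: PipelineConfig, out: Path) -> dict:
    """Structure-sensitive filtering: MAF/missingness, LD pruning, PCA and
    the admixture threshold on wild accessions.  Writes kept-site and PCA
    tables plus a JSON report of counts at each step."""
    fcfg = config.filter_config()
    matrix = np.concatenate([a.alleles for a in alignments], axis=1)
    filtered, keep = st.filter_variants(matrix, fcfg)
    kept_idx = np.flatnonzero(keep)
    pruned_local = st.ld_prune(
        filtered, fcfg.r2_max, fcfg.ld_window, fcfg.ld_step
    )
    pruned_idx = kept_idx[pruned_local]
    wild_meta = [m for m in metadata if m.status == "wild"]
    kept_wild = st.admixture_filter(wild_meta, fcfg.q_single_pop_min)
    report = {
        "n_sites": int(matrix.shape[1]),
        "n_sites_maf_missing": int(keep.sum()),
        "n_sites_ld_pruned": int(pruned_idx.size),
        "n_wild": len(wild_meta),
        "n_wild_non_admixed": len(kept_wild),
    }
    pd.DataFrame({"site_index": pruned_idx}).to_csv(
        out / "kept_sites.tsv", sep="\t", index=False
    )
    try:
        scores, frac = st.pca(filtered[:, pruned_local])
        pca_df = pd.DataFrame(
            scores, columns=[f"PC{i + 1}" for i in range(scores.shape[1])]
        )
        pca_df.insert(0, "accession", [m.accession for m in metadata])
        sio.write_results(pca_df, out / "pca_scores.tsv")
        report["pca_variance_fractions"] = [float(f) for f in frac[:5]]
    except ValueError as exc:
        logger.warning("PCA skipped: %s", exc)
    with open(out / "filter_report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    return report


def stage_scan(alignments, metadata, config: PipelineConfig, out: Path):
    wild_ids = samples_by_status(metadata, "wild")
    dom_ids = samples_by_status(metadata, "domesticated")
    fcfg = config.filter_config()
    wild_meta = [m for m in metadata if m.status == "wild"]
    kept_wild = set(st.admixture_filter(wild_meta, fcfg.q_single_pop_min))
    wild_ids = [w for w in wild_ids if w in kept_wild]
    try:
        bg = sw.background_sfs(alignments, dom_ids)
    except ValueError as exc:
        raise StageError("scan", str(exc)) from exc
    records = scan_records(
        alignments, wild_ids, dom_ids, bg,
        min_snps=config.scan_min_snps, grid=config.scan_grid, seed=config.seed,
    )
    S_list = [int(unfolded_sfs(a, dom_ids).total) for a in alignments]
    S_list = [s for s in S_list if s > 0] or [1]
    thresholds = sw.neutral_thresholds(
        n=len(dom_ids),
        S_list=S_list,
        reps=max(100, config.scan_reps),
        seed=config.seed + 1,
        dri_values=[r.dri for r in records],
        locus_length=int(np.median([a.contig_length or 2000 for a in alignments])),
    )
    calls = sw.call_outliers(records, thresholds)
    scan_df = pd.DataFrame(
        [
            {
                "locus": r.locus_id,
                "chrom": r.chromosome,
                "cM": r.cm,
                "pi_wild": r.pi_wild,
                "pi_dom": r.pi_dom,
                "dri": r.dri,
                "h_norm_wild": r.h_norm_wild,
                "h_norm_dom": r.h_norm_dom,
                "clr_dom": r.clr_dom,
                "outlier_clr": r.locus_id in calls.clr,
                "outlier_hnorm": r.locus_id in calls.hnorm,
                "outlier_dri": r.locus_id in calls.dri,
                "consensus": r.locus_id in calls.consensus,
            }
            for r in records
        ]
    )
    sio.write_results(scan_df, out / "scan.tsv")
    th_dict = {
        "clr_99": thresholds.clr_99,
        "hnorm_999": thresholds.hnorm_999,
        "dri_95": thresholds.dri_95,
        "reps": thresholds.reps,
        "seed": thresholds.seed,
    }
    with open(out / "thresholds.yaml", "w") as fh:
        yaml.safe_dump(th_dict, fh)
    return records, thresholds, calls


def scan_records(
    alignments: list[ContigAlignment],
    wild_ids: list[str],
    dom_ids: list[str],
    background,
    min_snps: int = 4,
    grid: int = 2,
    seed: int = 0,
) -> list[ScanRecord]:
    """Per-locus pi (wild/dom), DRI, H_norm and CLR (domesticated)."""
    rng = np.random.default_rng(seed)
    records = []
    for aln in alignments:
        rec = ScanRecord(locus_id=aln.locus_id)
        if aln.map_position:
            rec.chromosome, rec.cm = aln.map_position
        try:
            rec.pi_wild = nucleotide_diversity(aln, wild_ids)
            rec.pi_dom = nucleotide_diversity(aln, dom_ids)
            rec.dri = diversity_reduction_index(rec.pi_wild, rec.pi_dom)
        except UndefinedStatistic:
            pass
        try:
            rec.h_norm_dom = fay_wu_h_norm(unfolded_sfs(aln, dom_ids))
        except (UndefinedStatistic, ValueError):
            rec.h_norm_dom = None
        try:
            rec.h_norm_wild = fay_wu_h_norm(unfolded_sfs(aln, wild_ids))
        except (UndefinedStatistic, ValueError):
            rec.h_norm_wild = None
        fit = sw.clr_scan(
            aln, background, dom_ids, grid=grid, min_snps=min_snps, rng=rng
        )
        rec.clr_dom = fit.clr if fit else None
        if fit is None:
            rec.flags["clr_skipped"] = True
        records.append(rec)
    return records


def stage_ancestry(
    alignments, metadata, sweep_loci: set[str], config: PipelineConfig,
    out: Path, truth=None,
):
    wild_ids = samples_by_status(metadata, "wild")
    dom_ids = samples_by_status(metadata, "domesticated")
    fcfg = config.filter_config()
    wild_meta = [m for m in metadata if m.status == "wild"]
    kept_wild = set(st.admixture_filter(wild_meta, fcfg.q_single_pop_min))
    wild_ids = [w for w in wild_ids if w in kept_wild]
    pop_labels = {
        m.accession: m.population for m in metadata if m.status == "wild"
    }
    try:
        assignments = anc.assign_panel_ancestry(
            alignments, dom_ids, wild_ids, pop_labels,
            tie_eps=config.tie_eps, model=config.distance_model,
        )
    except ValueError as exc:
        raise StageError("ancestry", str(exc)) from exc

    palettes = [
        anc.build_palette([a for a in assignments if a.dom_accession == d])
        for d in dom_ids
    ]
    neutral_loci = {a.locus_id for a in alignments} - sweep_loci
    median_j = {}
    for label, loci in (
        ("neutral", neutral_loci), ("sweep", sweep_loci), ("all", None)
    ):
        if loci is not None and not loci:
            continue
        sm = anc.similarity_summary(palettes, loci, subset_label=label)
        median_j[label] = sm.median_offdiagonal()
        sio.write_results(
            pd.DataFrame(sm.values, index=sm.accessions, columns=sm.accessions)
            .reset_index()
            .rename(columns={"index": "accession"}),
            out / f"similarity_{label}.tsv",
        )
    ks = None
    if sweep_loci:
        try:
            D, pval, lon_n, lon_s = anc.longitudinal_contrast(
                assignments, metadata, sweep_loci
            )
            ks = {"D": D, "p_value": pval,
                  "n_neutral": int(lon_n.size), "n_sweep": int(lon_s.size)}
            with open(out / "ks_report.json", "w") as fh:
                json.dump(ks, fh, indent=2)
        except ValueError as exc:
            logger.warning("KS contrast skipped: %s", exc)
    sio.write_results(
        pd.DataFrame(
            [{"dom": p.dom_accession, "tokens": ",".join(p.tokens)}
             for p in palettes]
        ),
        out / "palettes.tsv",
    )
    sio.write_results(
        pd.DataFrame(
            [
                {
                    "locus": a.locus_id,
                    "dom": a.dom_accession,
                    "population": a.population,
                    "min_distance": a.min_distance,
                    "carriers": ",".join(a.carrier_wilds),
                }
                for a in assignments
            ]
        ),
        out / "assignments.tsv",
    )
    return assignments, palettes, median_j, ks


def recompute_report(out_dir: str | Path) -> dict:
    """Re-derive the headline counts of a finished run from its tables
    (no report-only state)."""
    out = Path(out_dir)
    summary: dict = {}
    scan = pd.read_csv(out / "scan.tsv", sep="\t")
    summary["n_scan_records"] = int(len(scan))
    summary["outliers"] = {
        "clr": int(scan["outlier_clr"].sum()),
        "hnorm": int(scan["outlier_hnorm"].sum()),
        "dri": int(scan["outlier_dri"].sum()),
        "union": int(
            (scan[["outlier_clr", "outlier_hnorm", "outlier_dri"]].sum(axis=1) > 0).sum()
        ),
        "consensus": int(scan["consensus"].sum()),
    }
    assignments = pd.read_csv(out / "assignments.tsv", sep="\t")
    assigned = assignments[assignments["population"] != "unassigned"]
    summary["n_assigned"] = int(len(assigned))
    summary["n_unassigned"] = int(len(assignments) - len(assigned))
    per_locus = assigned.groupby("locus")["population"].nunique()
    summary["monophyletic_fraction"] = float((per_locus == 1).mean())
    truth_path = out / "truth.tsv"
    if truth_path.exists():
        truth = sio.read_truth_tsv(truth_path)
        hits = sum(
            row["population"] == truth.source_of(row["locus"], row["dom"])
            for _, row in assigned.iterrows()
        )
        summary["ancestry_accuracy"] = hits / max(len(assigned), 1)
    return summary


def run_pipeline(config: PipelineConfig) -> RunReport:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(seed=config.seed)

    t0 = time.time()
    alignments, metadata, gmap, truth = stage_simulate(config, out)
    report.stage_seconds["simulate"] = round(time.time() - t0, 3)

    t0 = time.time()
    out_ids = samples_by_status(metadata, "outgroup")
    alignments = [sio.polarize_alleles(a, out_ids) for a in alignments]
    report.n_loci = len(alignments)
    report.n_samples = len(metadata)
    stage_filter(alignments, metadata, config, out)
    report.stage_seconds["filter"] = round(time.time() - t0, 3)

    t0 = time.time()
    records, thresholds, calls = stage_scan(alignments, metadata, config, out)
    report.n_scan_records = len(records)
    universe = len(records)
    report.outliers = {
        "clr": len(calls.clr),
        "hnorm": len(calls.hnorm),
        "dri": len(calls.dri),
        "union": len(calls.union),
        "consensus": len(calls.consensus),
    }
    report.overlap_pvalues = {
        "clr_hnorm": sw.overlap_significance(calls.clr, calls.hnorm, universe),
        "clr_dri": sw.overlap_significance(calls.clr, calls.dri, universe),
        "hnorm_dri": sw.overlap_significance(calls.hnorm, calls.dri, universe),
    }
    report.thresholds = {
        "clr_99": thresholds.clr_99,
        "hnorm_999": thresholds.hnorm_999,
        "dri_95": thresholds.dri_95,
        "reps": thresholds.reps,
        "seed": thresholds.seed,
    }
    report.stage_seconds["scan"] = round(time.time() - t0, 3)

    t0 = time.time()
    assignments, palettes, median_j, ks = stage_ancestry(
        alignments, metadata, truth.sweep_loci, config, out, truth=truth
    )
    assigned = [a for a in assignments if a.population != "unassigned"]
    report.n_assigned = len(assigned)
    report.n_unassigned = len(assignments) - len(assigned)
    if assigned:
        hits = sum(
            1 for a in assigned
            if a.population == truth.source_of(a.locus_id, a.dom_accession)
        )
        report.ancestry_accuracy = hits / len(assigned)
    report.monophyletic_fraction = anc.monophyletic_fraction(assignments)
    report.median_j = median_j
    report.ks = ks or {}
    report.stage_seconds["ancestry"] = round(time.time() - t0, 3)

    report.to_json(out / "report.json")
    return report
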