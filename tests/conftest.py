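import numpy as np
import pytest

from sweepscape.core import ContigAlignment, SampleMetadata
from sweepscape.io import polarize_alleles
from sweepscape.simulate import SimConfig, simulate_panel


def make_alignment(
    alleles,
    locus_id="locusA",
    samples=None,
    positions=None,
    n_invariant=10,
    ancestral=None,
    contig_length=None,
):
    alleles = np.asarray(alleles, dtype=np.int8)
    n, s = alleles.shape
    return ContigAlignment(
        locus_id=locus_id,
        samples=samples or [f"s{i}" for i in range(n)],
        alleles=alleles,
        site_positions=positions if positions is not None else np.arange(s) * 10,
        ancestral_state=ancestral,
        n_invariant_sites=n_invariant,
        contig_length=contig_length,
    )


@pytest.fixture(scope="session")
def small_config():
    """Down-scaled panel used where full defaults would be wasteful."""
    return SimConfig(
        n_wild_per_pop=4,
        n_dom=12,
        n_neutral_loci=12,
        n_sweep_loci=2,
        seed=17,
    )


@pytest.fixture(scope="session")
def small_panel(small_config):
    return simulate_panel(small_config)


@pytest.fixture(scope="session")
def default_panel():
    """One panel at the study-condition defaults, polarized."""
    alignments, metadata, gmap, truth = simulate_panel(SimConfig(seed=101))
    outgroups = [m.accession for m in metadata if m.status == "outgroup"]
    alignments = [polarize_alleles(a, outgroups) for a in alignments]
    return alignments, metadata, gmap, truth


def subset_ids(metadata, status):
    return [m.accession for m in metadata if m.status == status]
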