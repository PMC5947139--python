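"""Diversity statistics: pi, unfolded SFS, Fay & Wu's H, DRI, windows."""

import itertools

import numpy as np
import pytest
from scipy.stats import hypergeom

from sweepscape.core import ANC_REF, MISSING, GeneticMap
from sweepscape.diversity import (
    SiteFrequencySpectrum,
    UndefinedStatistic,
    completeness_quantile,
    diversity_reduction_index,
    fay_wu_h,
    fay_wu_h_norm,
    nucleotide_diversity,
    sliding_window,
    theta_l,
    theta_pi,
    unfolded_sfs,
)

from conftest import make_alignment


def brute_force_pi(alleles, n_invariant):
    """Mean pairwise difference per callable site, averaged over available
    pairs at each site (independent oracle)."""
    alleles = np.asarray(alleles)
    total = 0.0
    L = n_invariant
    for col in alleles.T:
        obs = col[col != MISSING]
        if obs.size < 2:
            continue
        L += 1
        diffs = sum(a != b for a, b in itertools.combinations(obs, 2))
        total += diffs / (obs.size * (obs.size - 1) / 2)
    if L == 0:
        raise ZeroDivisionError
    return total / L


class TestPi:
    def test_monomorphic_contig_zero(self):
        aln = make_alignment(np.zeros((4, 3)), n_invariant=10)
        assert nucleotide_diversity(aln) == 0.0

    def test_hand_case_complete(self):
        # one SNP with derived count 2 among 4, plus 9 invariant sites: the
        # contig has L = 10 callable sites
        mat = np.zeros((4, 1), dtype=np.int8)
        mat[:2, 0] = 1
        aln = make_alignment(mat, n_invariant=9)
        assert nucleotide_diversity(aln) == pytest.approx((2 * 2 * 2 / 12) / 10)

    def test_hand_case_one_genotype_masked(self):
        mat = np.zeros((4, 1), dtype=np.int8)
        mat[:2, 0] = 1
        mat[3, 0] = MISSING  # m=3, j=2
        aln = make_alignment(mat, n_invariant=9)
        assert nucleotide_diversity(aln) == pytest.approx((2 * 2 * 1 / 6) / 10)

    def test_matches_brute_force_on_random_matrices(self):
        rng = np.random.default_rng(0)
        for _ in range(60):
            n = rng.integers(2, 8)
            s = rng.integers(1, 10)
            mat = rng.integers(0, 2, size=(n, s)).astype(np.int8)
            mat[rng.random(size=mat.shape) < 0.25] = MISSING
            inv = int(rng.integers(0, 20))
            aln = make_alignment(mat, n_invariant=inv)
            try:
                expected = brute_force_pi(mat, inv)
            except ZeroDivisionError:
                with pytest.raises(UndefinedStatistic):
                    nucleotide_diversity(aln)
                continue
            assert nucleotide_diversity(aln) == pytest.approx(expected)

    def test_invariant_to_sample_order_and_label_swap(self):
        rng = np.random.default_rng(1)
        mat = rng.integers(0, 2, size=(6, 8)).astype(np.int8)
        mat[rng.random(size=mat.shape) < 0.2] = MISSING
        aln = make_alignment(mat, n_invariant=5)
        base = nucleotide_diversity(aln)
        perm = rng.permutation(6)
        assert nucleotide_diversity(make_alignment(mat[perm], n_invariant=5)) == (
            pytest.approx(base)
        )
        swapped = np.where(mat == MISSING, MISSING, 1 - mat)
        assert nucleotide_diversity(make_alignment(swapped, n_invariant=5)) == (
            pytest.approx(base)
        )

    def test_no_callable_sites_signals(self):
        aln = make_alignment(np.full((3, 2), MISSING), n_invariant=0)
        with pytest.raises(UndefinedStatistic):
            nucleotide_diversity(aln)


class TestDri:
    def test_equal_diversity_gives_one(self):
        assert diversity_reduction_index(0.01, 0.01) == 1.0

    def test_arithmetic(self):
        assert diversity_reduction_index(0.01, 0.0005) == pytest.approx(20.0)

    def test_zero_dom_diversity_infinite(self):
        assert diversity_reduction_index(0.01, 0.0) == np.inf

    def test_zero_wild_diversity_excluded_as_nan(self):
        assert np.isnan(diversity_reduction_index(0.0, 0.01))


class TestUnfoldedSfs:
    def _polarized(self, mat):
        mat = np.asarray(mat, dtype=np.int8)
        return make_alignment(
            mat, ancestral=np.full(mat.shape[1], ANC_REF, dtype=np.int8)
        )

    def test_complete_data_counts_raw_derived(self):
        mat = [[1, 1, 0], [1, 0, 0], [0, 0, 1], [0, 0, 1]]
        sfs = unfolded_sfs(self._polarized(mat))
        assert np.allclose(sfs.xi, [1, 2, 0])  # one singleton, two doubletons
        assert sfs.n_sites_used == 3

    def test_projection_matches_hypergeometric_table(self):
        # one site with j=2 of m_i=4, projected to m=2: weights from exact
        # enumeration P(k | 2 of 4, draw 2)
        mat = np.array([[1], [1], [0], [0]], dtype=np.int8)
        sfs = unfolded_sfs(self._polarized(mat), project_to=2)
        expected_k1 = hypergeom.pmf(1, 4, 2, 2)  # 4/6
        assert sfs.n == 2
        assert sfs.xi[0] == pytest.approx(expected_k1)

    def test_unpolarized_sites_skipped(self):
        mat = np.array([[1, 1], [0, 1], [0, 0]], dtype=np.int8)
        aln = make_alignment(mat)  # no ancestral states at all
        sfs = unfolded_sfs(aln)
        assert sfs.is_empty

    def test_sites_below_projection_size_skipped(self):
        mat = np.array([[1], [0], [MISSING], [0]], dtype=np.int8)
        sfs = unfolded_sfs(self._polarized(mat), project_to=4)
        assert sfs.is_empty

    def test_completeness_quantile(self):
        mat = np.array([[1, 1], [0, MISSING], [0, MISSING], [0, 0]], dtype=np.int8)
        aln = make_alignment(mat)
        assert completeness_quantile(aln, q=1.0) == 2


class TestFayWuH:
    def test_singleton_spectrum_positive_numerator(self):
        sfs = SiteFrequencySpectrum(n=4, xi=[1, 0, 0], n_sites_used=1)
        assert theta_pi(sfs) == pytest.approx(0.5)
        assert theta_l(sfs) == pytest.approx(1 / 3)
        assert fay_wu_h(sfs) == pytest.approx(1 / 6)
        assert fay_wu_h_norm(sfs) > 0

    def test_high_frequency_spectrum_negative_numerator(self):
        sfs = SiteFrequencySpectrum(n=4, xi=[0, 0, 1], n_sites_used=1)
        assert theta_pi(sfs) == pytest.approx(0.5)
        assert theta_l(sfs) == pytest.approx(1.0)
        assert fay_wu_h(sfs) == pytest.approx(-0.5)
        assert fay_wu_h_norm(sfs) < 0

    def test_numerator_antisymmetric_under_spectrum_mirror(self):
        rng = np.random.default_rng(2)
        for n in (5, 9, 14):
            xi = rng.integers(0, 6, size=n - 1).astype(float)
            mirrored = xi[::-1].copy()
            h1 = fay_wu_h(SiteFrequencySpectrum(n=n, xi=xi))
            # theta_pi is mirror-symmetric while theta_L flips around
            # theta_W; the numerator obeys H(xi) + H(mirror) =
            # 2*theta_pi - (theta_L + theta_L_mirror) with
            # theta_L + theta_L_mirror = n/(n-1) * S... verify exactly:
            h2 = fay_wu_h(SiteFrequencySpectrum(n=n, xi=mirrored))
            S = xi.sum()
            tp = theta_pi(SiteFrequencySpectrum(n=n, xi=xi))
            assert h1 + h2 == pytest.approx(2 * tp - S * n / (n - 1))

    def test_empty_spectrum_signals(self):
        with pytest.raises(UndefinedStatistic):
            fay_wu_h_norm(SiteFrequencySpectrum(n=5, xi=np.zeros(4)))

    def test_needs_three_samples(self):
        with pytest.raises(UndefinedStatistic):
            fay_wu_h_norm(SiteFrequencySpectrum(n=2, xi=[3.0]))


class TestSlidingWindow:
    def _gmap(self, entries):
        return GeneticMap(entries=entries)

    def test_single_locus_in_expected_windows(self):
        aln = make_alignment(np.zeros((3, 1)), locus_id="l1", n_invariant=5)
        gmap = self._gmap({"l1": ("1H", 5.0)})
        rows, _ = sliding_window([aln], gmap)
        hit = [r["start_cm"] for r in rows if r["n_loci"] > 0]
        assert hit == [0.0, 1.0, 2.0, 3.0, 4.0, 5.0]

    def test_window_pi_equals_pooled_sites(self):
        rng = np.random.default_rng(3)
        m1 = rng.integers(0, 2, size=(4, 5)).astype(np.int8)
        m2 = rng.integers(0, 2, size=(4, 3)).astype(np.int8)
        a1 = make_alignment(m1, locus_id="l1", n_invariant=7)
        a2 = make_alignment(m2, locus_id="l2", n_invariant=4)
        gmap = self._gmap({"l1": ("2H", 1.0), "l2": ("2H", 2.0)})
        rows, _ = sliding_window([a1, a2], gmap)
        both = [r for r in rows if r["n_loci"] == 2]
        pooled = make_alignment(
            np.concatenate([m1, m2], axis=1),
            positions=np.arange(8),
            n_invariant=11,
        )
        assert both
        assert both[0]["value"] == pytest.approx(nucleotide_diversity(pooled))

    def test_unmapped_loci_counted(self):
        aln = make_alignment(np.zeros((3, 1)), locus_id="nowhere")
        rows, n_unmapped = sliding_window([aln], self._gmap({}))
        assert rows == []
        assert n_unmapped == 1
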