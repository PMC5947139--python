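"""Mosaic-ancestry reconstruction: distances, assignment, palettes, J,
monophyly, and the east-west longitudinal contrast."""

import itertools
import math

import numpy as np
import pytest

from sweepscape.ancestry import (
    AncestryAssignment,
    AncestryPalette,
    assign_locus_ancestry,
    assign_panel_ancestry,
    balanced_subsample_median,
    build_palette,
    longitudinal_contrast,
    monophyletic_fraction,
    pairwise_distance,
    palette_similarity,
    similarity_summary,
)
from sweepscape.core import MISSING, SampleMetadata, samples_by_status
from sweepscape.simulate import SimConfig, simulate_panel

from conftest import make_alignment


class TestPairwiseDistance:
    def test_identical_sequences_zero(self):
        mat = np.array([[0, 1, 0], [0, 1, 0]], dtype=np.int8)
        aln = make_alignment(mat, samples=["a", "b"], n_invariant=10)
        assert pairwise_distance(aln, "a", "b") == 0.0

    def test_jc69_closed_form(self):
        # p = 3 mismatches / 10 callable -> d = -(3/4) ln(1 - 4*0.3/3)
        mat = np.zeros((2, 3), dtype=np.int8)
        mat[1] = 1
        aln = make_alignment(mat, samples=["a", "b"], n_invariant=7)
        assert pairwise_distance(aln, "a", "b") == pytest.approx(
            -0.75 * math.log(0.6), rel=1e-12
        )

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        mat = rng.integers(0, 2, size=(2, 12)).astype(np.int8)
        mat[rng.random(mat.shape) < 0.2] = MISSING
        aln = make_alignment(mat, samples=["a", "b"], n_invariant=30)
        assert pairwise_distance(aln, "a", "b") == pairwise_distance(aln, "b", "a")

    def test_saturation_infinite(self):
        mat = np.zeros((2, 9), dtype=np.int8)
        mat[1] = 1  # p = 9/10 > 3/4
        aln = make_alignment(mat, samples=["a", "b"], n_invariant=1)
        assert pairwise_distance(aln, "a", "b") == math.inf

    def test_zero_callable_overlap_raises(self):
        mat = np.array([[0, MISSING], [MISSING, 1]], dtype=np.int8)
        aln = make_alignment(mat, samples=["a", "b"], n_invariant=0)
        with pytest.raises(ValueError):
            pairwise_distance(aln, "a", "b")


class TestAssignment:
    def _panel_aln(self):
        # dom identical to wild w_a (pop A); w_b1/w_b2 of pop B differ
        mat = np.array(
            [
                [0, 1, 0, 0],  # dom
                [0, 1, 0, 0],  # w_a  (pop A)
                [1, 0, 1, 0],  # w_b1 (pop B)
                [1, 0, 0, 1],  # w_b2 (pop B)
            ],
            dtype=np.int8,
        )
        return make_alignment(
            mat, samples=["dom", "w_a", "w_b1", "w_b2"], n_invariant=20
        )

    def test_unique_minimum_assigned(self):
        aln = self._panel_aln()
        res = assign_locus_ancestry(
            aln, "dom", ["w_a", "w_b1", "w_b2"],
            {"w_a": "A", "w_b1": "B", "w_b2": "B"},
        )
        assert res.population == "A"
        assert res.carrier_wilds == ["w_a"]
        assert res.min_distance == 0.0

    def test_tie_across_populations_unassigned(self):
        mat = np.array(
            [[0, 0], [0, 0], [0, 0], [1, 1]], dtype=np.int8
        )
        aln = make_alignment(
            mat, samples=["dom", "wA", "wB", "far"], n_invariant=10
        )
        res = assign_locus_ancestry(
            aln, "dom", ["wA", "wB", "far"], {"wA": "A", "wB": "B", "far": "B"}
        )
        assert res.population == "unassigned"
        assert set(res.carrier_wilds) == {"wA", "wB"}

    def test_tie_within_population_assigned(self):
        mat = np.array([[0], [0], [0], [1]], dtype=np.int8)
        aln = make_alignment(
            mat, samples=["dom", "w1", "w2", "far"], n_invariant=10
        )
        res = assign_locus_ancestry(
            aln, "dom", ["w1", "w2", "far"], {"w1": "A", "w2": "A", "far": "B"}
        )
        assert res.population == "A"

    def test_unlabeled_wild_in_minimal_set_unassigns(self):
        mat = np.array([[0], [0], [1]], dtype=np.int8)
        aln = make_alignment(mat, samples=["dom", "w1", "w2"], n_invariant=5)
        res = assign_locus_ancestry(aln, "dom", ["w1", "w2"], {"w2": "B"})
        assert res.population == "unassigned"

    def test_empty_wild_panel_raises(self):
        aln = self._panel_aln()
        with pytest.raises(ValueError):
            assign_locus_ancestry(aln, "dom", [], {})

    def test_invariant_to_wild_panel_order(self):
        aln = self._panel_aln()
        labels = {"w_a": "A", "w_b1": "B", "w_b2": "B"}
        r1 = assign_locus_ancestry(aln, "dom", ["w_a", "w_b1", "w_b2"], labels)
        r2 = assign_locus_ancestry(aln, "dom", ["w_b2", "w_a", "w_b1"], labels)
        assert r1.population == r2.population
        assert set(r1.carrier_wilds) == set(r2.carrier_wilds)


class TestPalettes:
    def _assignments(self):
        return [
            AncestryAssignment("locus2", "d1", "pop1"),
            AncestryAssignment("locus1", "d1", "pop1"),
            AncestryAssignment("locus3", "d1", "unassigned"),
        ]

    def test_tokens_sorted_by_locus_and_formatted(self):
        pal = build_palette(self._assignments())
        assert pal.tokens == ["locus1_pop1", "locus2_pop1"]

    def test_all_unassigned_empty(self):
        pal = build_palette(
            [AncestryAssignment("locus1", "d1", "unassigned")]
        )
        assert pal.tokens == []

    def test_mixed_accessions_rejected(self):
        with pytest.raises(ValueError):
            build_palette(
                [
                    AncestryAssignment("l", "d1", "p"),
                    AncestryAssignment("l", "d2", "p"),
                ]
            )


class TestJaccard:
    def test_identical_palettes_one(self):
        x = AncestryPalette("d1", ["locus1_pop1", "locus2_pop3"])
        y = AncestryPalette("d2", ["locus1_pop1", "locus2_pop3"])
        assert palette_similarity(x, y) == 1.0

    def test_disjoint_palettes_zero(self):
        x = AncestryPalette("d1", ["locus1_pop1", "locus2_pop1"])
        y = AncestryPalette("d2", ["locus1_pop2", "locus2_pop3"])
        assert palette_similarity(x, y) == 0.0

    def test_partial_overlap(self):
        x = AncestryPalette("d1", ["a_1", "b_1"])
        y = AncestryPalette("d2", ["a_1", "b_2"])
        assert palette_similarity(x, y) == pytest.approx(1 / 3)

    def test_printed_variant_denominator(self):
        x = AncestryPalette("d1", ["a_1", "b_1"])
        y = AncestryPalette("d2", ["a_1", "b_1"])
        assert palette_similarity(x, y, printed_formula=True) == pytest.approx(
            2 / (2 + 2 + 2)
        )

    def test_both_empty_undefined(self):
        with pytest.raises(ValueError):
            palette_similarity(AncestryPalette("d1"), AncestryPalette("d2"))

    def test_one_minus_j_triangle_inequality(self):
        rng = np.random.default_rng(1)
        loci = [f"l{i}" for i in range(8)]
        pals = [
            AncestryPalette(
                f"d{k}",
                [f"{l}_p{rng.integers(3)}" for l in loci if rng.random() < 0.8],
            )
            for k in range(12)
        ]
        for a, b, c in itertools.combinations(range(12), 3):
            try:
                dab = 1 - palette_similarity(pals[a], pals[b])
                dbc = 1 - palette_similarity(pals[b], pals[c])
                dac = 1 - palette_similarity(pals[a], pals[c])
            except ValueError:
                continue
            assert dac <= dab + dbc + 1e-12


class TestSimilaritySummary:
    def _pals(self):
        return [
            AncestryPalette("d1", ["a_1", "b_1", "c_2"]),
            AncestryPalette("d2", ["a_1", "b_1", "c_2"]),
            AncestryPalette("d3", ["a_2", "b_1", "c_1"]),
        ]

    def test_symmetric_unit_diagonal(self):
        sm = similarity_summary(self._pals())
        assert np.allclose(sm.values, sm.values.T)
        assert np.allclose(np.diag(sm.values), 1.0)

    def test_identical_palettes_median_one(self):
        pals = self._pals()[:2] + [AncestryPalette("d3", ["a_1", "b_1", "c_2"])]
        assert similarity_summary(pals).median_offdiagonal() == 1.0

    def test_locus_restriction(self):
        sm = similarity_summary(self._pals(), locus_subset=["b"])
        off = sm.values[0, 2]
        assert off == 1.0  # all share b_1

    def test_needs_two_palettes(self):
        with pytest.raises(ValueError):
            similarity_summary(self._pals()[:1])


class TestBalancedSubsample:
    def test_full_size_reproduces_median(self):
        pals = [
            AncestryPalette("d1", ["a_1", "b_1"]),
            AncestryPalette("d2", ["a_1", "b_2"]),
            AncestryPalette("d3", ["a_2", "b_2"]),
        ]
        full = similarity_summary(pals, ["a", "b"]).median_offdiagonal()
        med = balanced_subsample_median(pals, ["a", "b"], 2, reps=10, seed=0)
        assert np.allclose(med, full)

    def test_seed_reproducible(self):
        pals = [
            AncestryPalette("d1", [f"l{i}_1" for i in range(6)]),
            AncestryPalette("d2", [f"l{i}_{1 + i % 2}" for i in range(6)]),
            AncestryPalette("d3", [f"l{i}_2" for i in range(6)]),
        ]
        loci = [f"l{i}" for i in range(6)]
        m1 = balanced_subsample_median(pals, loci, 3, reps=20, seed=9)
        m2 = balanced_subsample_median(pals, loci, 3, reps=20, seed=9)
        assert np.array_equal(m1, m2)


class TestMonophyly:
    def test_all_single_source(self):
        a = [
            AncestryAssignment("l1", "d1", "A"),
            AncestryAssignment("l1", "d2", "A"),
            AncestryAssignment("l2", "d1", "B"),
        ]
        assert monophyletic_fraction(a) == 1.0

    def test_split_locus_halves_fraction(self):
        a = [
            AncestryAssignment("l1", "d1", "A"),
            AncestryAssignment("l1", "d2", "B"),
            AncestryAssignment("l2", "d1", "A"),
            AncestryAssignment("l2", "d2", "A"),
        ]
        assert monophyletic_fraction(a) == 0.5

    def test_no_assignments_raises(self):
        with pytest.raises(ValueError):
            monophyletic_fraction(
                [AncestryAssignment("l1", "d1", "unassigned")]
            )


class TestLongitudinalContrast:
    def _meta(self, lons):
        return [
            SampleMetadata(f"w{i}", "wild", population="P",
                           latitude=30.0, longitude=lon)
            for i, lon in enumerate(lons)
        ]

    def _assign(self, locus, wilds):
        return AncestryAssignment(locus, "d1", "P", carrier_wilds=wilds)

    def test_identical_samples_null(self):
        meta = self._meta([34.0, 35.0, 36.0])
        a = [
            self._assign("neutral1", ["w0", "w1", "w2"]),
            self._assign("sweep1", ["w0", "w1", "w2"]),
        ]
        D, p, *_ = longitudinal_contrast(a, meta, {"sweep1"})
        assert D == 0.0
        assert p == pytest.approx(1.0)

    def test_disjoint_supports_maximal_d(self):
        meta = self._meta([34.0, 34.5, 44.0, 44.5])
        a = [
            self._assign("neutral1", ["w0", "w1"]),
            self._assign("sweep1", ["w2", "w3"]),
        ]
        D, p, *_ = longitudinal_contrast(a, meta, {"sweep1"})
        assert D == 1.0

    def test_single_longitude_class_signals(self):
        meta = self._meta([34.0, 35.0])
        a = [self._assign("neutral1", ["w0", "w1"])]
        with pytest.raises(ValueError):
            longitudinal_contrast(a, meta, {"sweepX"})


class TestRecoveryTrend:
    def test_recovery_degrades_as_population_signal_vanishes(self):
        """Shrinking population-level divergence erodes assignability:
        the unassigned/incorrect fraction rises monotonically."""
        scores = []
        for theta_pop in (18.0, 4.0, 0.5):
            cfg = SimConfig(
                n_wild_per_pop=4, n_dom=10, n_neutral_loci=10, n_sweep_loci=2,
                theta_pop=theta_pop, seed=23,
            )
            alignments, metadata, _, truth = simulate_panel(cfg)
            doms = samples_by_status(metadata, "domesticated")
            wilds = samples_by_status(metadata, "wild")
            labels = {m.accession: m.population for m in metadata
                      if m.status == "wild"}
            assignments = assign_panel_ancestry(alignments, doms, wilds, labels)
            correct = sum(
                a.population != "unassigned"
                and a.population == truth.source_of(a.locus_id, a.dom_accession)
                for a in assignments
            )
            scores.append(correct / len(assignments))
        assert scores[0] > scores[1] > scores[2]
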