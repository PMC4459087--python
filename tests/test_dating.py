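"""Distance dating engine: heights, rate fitting, CIs, fossil consistency."""

import numpy as np
import pytest

import satclock as sc
from satclock.calibrations import CalibrationPrior
from satclock.dating import (
    calibrate_rate,
    check_fossil_consistency,
    date_tree,
    node_heights,
    resolve_calibration,
)
from satclock.distances import DistanceMatrix
from satclock.simulate import simulate_stylized_distances
from satclock.trees import Chronogram, NODE_CLADES


def _cal(label, clade, min_age, **kw):
    return CalibrationPrior(label, frozenset(clade), min_age, **kw)


class TestNodeHeights:
    def test_perfect_clock_three_taxa(self):
        tree = Chronogram.from_newick("((A:1,B:1):1,C:2);")
        d = DistanceMatrix(
            ("A", "B", "C"),
            np.array([[0, 4.0, 10.0], [4.0, 0, 10.0], [10.0, 10.0, 0]]),
        )
        h = node_heights(tree, d)
        assert h.heights[frozenset({"A", "B"})] == pytest.approx(2.0)
        assert h.heights[frozenset({"A", "B", "C"})] == pytest.approx(5.0)
        assert not h.clamped

    def test_stylized_fixture_deep_node(self, reference_tree, exact_stylized_distances):
        h = node_heights(reference_tree, exact_stylized_distances)
        clade = NODE_CLADES["divergence_Sphenisciformes_Procellariiformes"]
        assert h.heights[clade] == pytest.approx(29.4375 / 2, rel=1e-12)

    def test_identical_sequences_give_zero_heights(self, reference_tree):
        n = len(reference_tree.taxa)
        d = DistanceMatrix(tuple(reference_tree.taxa), np.zeros((n, n)))
        h = node_heights(reference_tree, d)
        assert all(v == 0.0 for v in h.heights.values())

    def test_missing_taxa_rejected(self, reference_tree):
        d = DistanceMatrix(("A", "B"), np.zeros((2, 2)))
        with pytest.raises(KeyError):
            node_heights(reference_tree, d)

    def test_non_monotone_heights_clamped_and_flagged(self):
        tree = Chronogram.from_newick("((A:1,B:1):1,C:2);")
        # AB pair farther apart than either is from C: child exceeds parent
        d = DistanceMatrix(
            ("A", "B", "C"),
            np.array([[0, 8.0, 4.0], [8.0, 0, 4.0], [4.0, 4.0, 0]]),
        )
        h = node_heights(tree, d)
        ab = frozenset({"A", "B"})
        assert ab in h.clamped
        assert h.heights[ab] == h.heights[frozenset({"A", "B", "C"})]


class TestCalibrateRate:
    def test_single_exact_calibration_recovers_rate(self):
        tree = Chronogram.from_newick("((A:10,B:10):5,C:15);")
        d = simulate_stylized_distances(tree, sc.SaturationModel(onset=1000.0))
        h = node_heights(tree, d)
        rate, _, _ = calibrate_rate(h, tree, [_cal("ab", ["A", "B"], 10.0)])
        assert rate == pytest.approx(1.0)

    def test_through_origin_fit_of_two_calibrations(self):
        tree = Chronogram.from_newick("((A:10,B:10):50.001,(C:60,D:60):0.001);")
        d = simulate_stylized_distances(tree)
        h = node_heights(tree, d)
        rate, _, _ = calibrate_rate(
            h, tree, [_cal("ab", ["A", "B"], 10.0), _cal("cd", ["C", "D"], 60.0)]
        )
        assert rate == pytest.approx((10 * 10 + 60 * 29.375) / 3700.0, rel=1e-9)

    def test_uniform_priors_with_huge_maxima_keep_point_min_rate(self):
        tree = Chronogram.from_newick("((A:10,B:10):5,C:15);")
        d = simulate_stylized_distances(tree, sc.SaturationModel(onset=1000.0))
        h = node_heights(tree, d)
        point, _, _ = calibrate_rate(h, tree, [_cal("ab", ["A", "B"], 10.0)])
        soft, _, _ = calibrate_rate(
            h,
            tree,
            [_cal("ab", ["A", "B"], 10.0, shape="uniform", soft_max=1e4)],
            mode="soft",
        )
        assert soft == point

    def test_empty_calibrations_rejected(self, reference_tree, exact_stylized_distances):
        h = node_heights(reference_tree, exact_stylized_distances)
        with pytest.raises(ValueError):
            calibrate_rate(h, reference_tree, [])

    def test_stem_attachment_for_single_survivor(self, reference_tree):
        pruned = reference_tree.prune_to(
            [t for t in reference_tree.taxa
             if t not in ("Anhinga_melanogaster", "Phalacrocorax_auritus")]
        )
        cal = _cal("stem_Sulidae", NODE_CLADES["stem_Sulidae"], 33.0)
        clade, note = resolve_calibration(pruned, cal)
        assert clade is not None and "Sula_leucogaster" in clade
        assert "stem" in note

    def test_unresolvable_calibration_skipped(self, reference_tree, exact_stylized_distances):
        h = node_heights(reference_tree, exact_stylized_distances)
        ghost = _cal("ghost", ["Nonexistent_taxon"], 10.0)
        with pytest.raises(ValueError):
            calibrate_rate(h, reference_tree, [ghost])


class TestDateTree:
    def test_scale_equivariance(self, reference_tree, exact_stylized_distances):
        """Multiplying all minima by c multiplies all ages by c."""
        cals = [_cal(c.label, c.clade, c.min_age) for c in sc.STANDARD_SIX]
        cals_x2 = [_cal(c.label, c.clade, 2 * c.min_age) for c in sc.STANDARD_SIX]
        a = date_tree(reference_tree, exact_stylized_distances, cals, bootstrap_reps=0)
        b = date_tree(reference_tree, exact_stylized_distances, cals_x2, bootstrap_reps=0)
        assert b.rate == pytest.approx(a.rate / 2)
        for ea, eb in zip(a.estimates, b.estimates):
            assert eb.point_age == pytest.approx(2 * ea.point_age, rel=1e-9)

    def test_zero_bootstrap_collapses_ci(self, reference_tree, exact_stylized_distances):
        res = date_tree(
            reference_tree, exact_stylized_distances, sc.STANDARD_SIX, bootstrap_reps=0
        )
        for e in res.estimates:
            assert e.ci_low == e.point_age == e.ci_high
            assert e.relative_ci == 0.0

    def test_young_calibration_compresses_deep_node(self, reference_tree):
        """With only unsaturated-zone calibrations the 62-MY node dates to ~29.4."""
        d = simulate_stylized_distances(reference_tree)
        young = [_cal("grebes", NODE_CLADES["crown_Podicipedidae"], 8.7)]
        res = date_tree(reference_tree, d, young, bootstrap_reps=0)
        old = res.by_label()["divergence_Sphenisciformes_Procellariiformes"]
        assert old.point_age == pytest.approx(29.4375, rel=1e-9)

    def test_saturation_sign_pattern_end_to_end(self, reference_tree):
        """Deep calibration inflates young nodes; young-only compresses old ones."""
        d = simulate_stylized_distances(reference_tree)
        deep = [_cal("penguin", NODE_CLADES["divergence_Sphenisciformes_Procellariiformes"], 62.0)]
        young = [_cal("grebes", NODE_CLADES["crown_Podicipedidae"], 8.7)]
        res_deep = date_tree(reference_tree, d, deep, bootstrap_reps=0)
        res_young = date_tree(reference_tree, d, young, bootstrap_reps=0)
        for label in ("jamesi_andinus", "crown_Phoenicopteridae", "crown_Podicipedidae"):
            truth = reference_tree.age_of(NODE_CLADES[label])
            assert res_deep.by_label()[label].point_age > truth
        for label in ("stem_Fregatidae", "crown_Aequornithes"):
            truth = reference_tree.age_of(NODE_CLADES[label])
            assert res_young.by_label()[label].point_age < truth

    def test_minimum_age_floor_applies_to_used_calibrations(self, reference_tree):
        d = simulate_stylized_distances(reference_tree)
        res = date_tree(reference_tree, d, sc.STANDARD_SIX, bootstrap_reps=0)
        for cal in sc.STANDARD_SIX:
            est = res.by_label()[cal.label]
            assert est.point_age >= cal.min_age - 1e-9
        floored = [e for e in res.estimates if e.floored]
        assert floored  # saturation forces at least the deepest nodes onto their minima

    def test_monotone_ages_after_flooring(self, reference_tree, exact_stylized_distances):
        res = date_tree(
            reference_tree, exact_stylized_distances, sc.STANDARD_SIX, bootstrap_reps=0
        )
        ages = {e.clade: e.point_age for e in res.estimates}
        for clade, _age, node in reference_tree.internal_nodes():
            parent = node.parent_node
            if parent is not None:
                assert ages[clade] <= ages[parent.clade] + 1e-9

    def test_bootstrap_deterministic_given_seed(self, reference_tree, nuclear_alignments):
        kw = dict(bootstrap_reps=20, seed=42)
        a = date_tree(reference_tree, nuclear_alignments[:2], sc.STANDARD_SIX, **kw)
        b = date_tree(reference_tree, nuclear_alignments[:2], sc.STANDARD_SIX, **kw)
        for ea, eb in zip(a.estimates, b.estimates):
            assert (ea.ci_low, ea.ci_high) == (eb.ci_low, eb.ci_high)

    def test_distance_input_with_bootstrap_warns_and_collapses(
        self, reference_tree, exact_stylized_distances
    ):
        res = date_tree(
            reference_tree, exact_stylized_distances, sc.STANDARD_SIX, bootstrap_reps=50
        )
        assert any("bootstrap" in w for w in res.warnings)
        assert all(e.ci_low == e.ci_high for e in res.estimates)

    def test_no_calibrations_rejected(self, reference_tree, exact_stylized_distances):
        with pytest.raises(ValueError):
            date_tree(reference_tree, exact_stylized_distances, [])

    def test_jc_correction_reduces_depth_bias(self):
        """On mechanistic data the optional correction moves deep nodes toward truth."""
        tree = Chronogram.from_newick("((A:10,B:10):40.001,(C:50,D:50):0.001);")
        locus = sc.LocusProfile("nuc", "nDNA", 30000, 1.0)
        aln = sc.simulate_alignment(tree, locus, seed=9)
        cal = [_cal("ab", ["A", "B"], 10.0)]
        raw = date_tree(tree, aln, cal, bootstrap_reps=0)
        corr = date_tree(tree, aln, cal, bootstrap_reps=0, correction="jc")
        root = frozenset("ABCD")
        assert abs(corr.by_clade()[root].point_age - 50.0) < abs(
            raw.by_clade()[root].point_age - 50.0
        )


class TestFossilConsistency:
    def test_young_only_calibration_rejects_deep_fossils(self, reference_tree):
        d = simulate_stylized_distances(reference_tree)
        res = date_tree(reference_tree, d, sc.YOUNGEST_TWO, bootstrap_reps=0)
        violations = check_fossil_consistency(
            res.estimates, sc.DEFAULT_CALIBRATIONS, reference_tree
        )
        assert {v.min_age for v in violations} == {33.0, 51.8, 60.5}

    def test_all_calibrations_consistent(self, reference_tree):
        d = simulate_stylized_distances(reference_tree)
        res = date_tree(reference_tree, d, sc.STANDARD_SIX, bootstrap_reps=0)
        assert (
            check_fossil_consistency(res.estimates, sc.DEFAULT_CALIBRATIONS, reference_tree)
            == []
        )

    def test_empty_fossil_table(self, reference_tree):
        d = simulate_stylized_distances(reference_tree)
        res = date_tree(reference_tree, d, sc.YOUNGEST_TWO, bootstrap_reps=0)
        assert check_fossil_consistency(res.estimates, [], reference_tree) == []
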