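"""Fixture chronogram, sequence simulator and the 45-run grid."""

import numpy as np
import pytest
from scipy.linalg import expm

import satclock as sc
from satclock.calibrations import DEFAULT_CALIBRATIONS, STANDARD_SIX, YOUNGEST_TWO
from satclock.grid import make_run_grid
from satclock.simulate import (
    DEFAULT_LOCI,
    DEFAULT_MTDNA_LOCUS,
    LocusProfile,
    simulate_alignment,
    simulate_stylized_distances,
)
from satclock.trees import (
    ALL_TAXA,
    Chronogram,
    NODE_CLADES,
    make_reference_chronogram,
)


class TestReferenceChronogram:
    def test_anchored_ages(self, reference_tree):
        t = reference_tree
        assert t.age_of(NODE_CLADES["divergence_Sphenisciformes_Procellariiformes"]) == 62.0
        assert t.age_of(NODE_CLADES["jamesi_andinus"]) == pytest.approx(0.5)
        assert t.age_of(NODE_CLADES["crown_Phoenicopteridae"]) == pytest.approx(4.4)
        assert t.age_of(NODE_CLADES["crown_Mirandornithes"]) == pytest.approx(32.6)

    def test_all_calibrated_clades_monophyletic(self, reference_tree):
        for cal in DEFAULT_CALIBRATIONS:
            assert reference_tree.is_monophyletic(cal.clade), cal.label

    def test_parent_older_than_child_everywhere(self, reference_tree):
        for _clade, age, node in reference_tree.internal_nodes():
            for child in node.child_nodes():
                child_age = child.age
                assert age > child_age

    def test_taxon_panel(self, reference_tree):
        assert sorted(reference_tree.taxa) == sorted(ALL_TAXA)
        assert len(ALL_TAXA) == 17

    def test_determinism(self):
        assert make_reference_chronogram(0).newick() == make_reference_chronogram(0).newick()

    def test_non_ultrametric_rejected(self):
        with pytest.raises(ValueError, match="ultrametric"):
            Chronogram.from_newick("((A:1,B:2):1,C:3);")

    def test_scaling(self, reference_tree):
        half = reference_tree.scaled(0.5)
        assert half.root_age == pytest.approx(32.0)
        with pytest.raises(ValueError):
            reference_tree.scaled(0.0)


def _k2p_expected_p(subs, kappa):
    """Independent oracle: matrix exponential of the K2P generator."""
    beta = 1.0 / (kappa + 2.0)
    alpha = kappa * beta
    # states A,G,C,T; A<->G and C<->T are transitions
    Q = np.full((4, 4), beta)
    Q[0, 1] = Q[1, 0] = Q[2, 3] = Q[3, 2] = alpha
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    P = expm(Q * subs)
    return 1.0 - P[0, 0]  # symmetric: same off-diagonal mass from any state


class TestMechanisticSimulation:
    def test_zero_rate_gives_identical_sequences(self, reference_tree):
        locus = LocusProfile("test", "nDNA", 500, 1.0)
        aln = simulate_alignment(reference_tree, locus, seed=1, base_rate=0.0)
        assert (aln.data == aln.data[0]).all()

    def test_negative_rate_rejected(self, reference_tree):
        locus = LocusProfile("test", "nDNA", 500, 1.0)
        with pytest.raises(ValueError):
            simulate_alignment(reference_tree, locus, base_rate=-1.0)

    def test_locus_validation(self):
        with pytest.raises(ValueError):
            LocusProfile("bad", "nDNA", 0, 1.0)
        with pytest.raises(ValueError):
            LocusProfile("bad", "nDNA", 100, -1.0)
        with pytest.raises(ValueError):
            LocusProfile("bad", "plastid", 100, 1.0)

    def test_same_seed_identical_output(self, reference_tree):
        locus = DEFAULT_LOCI[0]
        a = simulate_alignment(reference_tree, locus, seed=7)
        b = simulate_alignment(reference_tree, locus, seed=7)
        assert (a.data == b.data).all()
        assert (a.data != simulate_alignment(reference_tree, locus, seed=8).data).any()

    @pytest.mark.parametrize("depth_my", [10.0, 60.0])
    def test_two_tip_p_distance_matches_markov_expectation(self, depth_my):
        """Mean p-distance sits within binomial noise of the K2P closed form."""
        tree = Chronogram.from_newick(f"(A:{depth_my},B:{depth_my});")
        locus = LocusProfile("test", "nDNA", 20000, 1.0, kappa=2.0)
        pair_subs = 2 * depth_my * 1.0 / 200.0  # base rate 1 %/MY pairwise
        expected = _k2p_expected_p(pair_subs, 2.0)
        aln = simulate_alignment(tree, locus, seed=3)
        observed = aln.p_distance_matrix().get("A", "B") / 100.0
        sd = np.sqrt(expected * (1 - expected) / locus.length)
        assert abs(observed - expected) < 3 * sd

    def test_saturation_sublinearity_at_depth(self):
        """60 MY of divergence yields far less than 6x the 10-MY distance."""
        d = {}
        for depth in (10.0, 60.0):
            tree = Chronogram.from_newick(f"(A:{depth},B:{depth});")
            locus = LocusProfile("mt", "mtDNA", 20000, 5.0, kappa=4.0)
            aln = simulate_alignment(tree, locus, seed=5)
            d[depth] = aln.p_distance_matrix().get("A", "B")
        assert d[60.0] < 6 * d[10.0]

    def test_p_distance_concave_and_bounded(self):
        """Observed distance vs depth is concave, below the stationary mismatch."""
        depths = [5.0, 20.0, 40.0, 80.0]
        vals = []
        for depth in depths:
            tree = Chronogram.from_newick(f"(A:{depth},B:{depth});")
            aln = simulate_alignment(
                tree, LocusProfile("mt", "mtDNA", 30000, 5.0), seed=11
            )
            vals.append(aln.p_distance_matrix().get("A", "B"))
        increments = np.diff(vals) / np.diff(depths)
        assert np.all(np.diff(increments) < 0)
        assert max(vals) < 75.0  # stationary mismatch probability of K2P


class TestStylizedSimulation:
    def test_exact_mode_matches_model(self, reference_tree, model):
        dist = simulate_stylized_distances(reference_tree)
        age = reference_tree.age_of(["Spheniscus_humboldti", "Procellaria_aequinoctialis"])
        assert dist.get("Spheniscus_humboldti", "Procellaria_aequinoctialis") == (
            pytest.approx(sc.expected_distance(model, age))
        )

    def test_finite_length_noise_converges(self, reference_tree, model):
        """Binomial noise around the model mean, shrinking with length."""
        pair = ("Podiceps_cristatus", "Tachybaptus_ruficollis")
        age = reference_tree.age_of(pair)
        target = sc.expected_distance(model, age)
        obs = [
            simulate_stylized_distances(reference_tree, length=50000, seed=s).get(*pair)
            for s in range(5)
        ]
        assert np.mean(obs) == pytest.approx(target, abs=0.5)

    def test_seed_determinism(self, reference_tree):
        a = simulate_stylized_distances(reference_tree, length=500, seed=2)
        b = simulate_stylized_distances(reference_tree, length=500, seed=2)
        assert np.array_equal(a.values, b.values)


class TestRunGrid:
    def test_grid_shape_and_reference_row(self):
        grid = make_run_grid()
        assert len(grid) == 45
        ref = next(r for r in grid if r.run_id == 3)
        assert len(ref.loci) == 7
        assert ref.n_outgroups == 8
        assert len(ref.calibrations) == 6

    def test_mtdna_only_row(self):
        grid = make_run_grid()
        row5 = next(r for r in grid if r.run_id == 5)
        assert row5.loci == (DEFAULT_MTDNA_LOCUS.name,)

    def test_counts_match_declared_numbers(self):
        for r in make_run_grid():
            assert len(set(r.taxa)) == len(r.flamingos) + r.n_outgroups
            assert len(r.calibrations) == len(set(r.calibrations))

    def test_youngest_two_are_grebe_and_mirandornithes(self):
        labels = {c.label for c in YOUNGEST_TWO}
        assert labels == {"crown_Podicipedidae", "crown_Mirandornithes"}
        assert {c.min_age for c in YOUNGEST_TWO} == {8.7, 32.6}

    def test_standard_six_minima(self):
        assert sorted(c.min_age for c in STANDARD_SIX) == [
            8.7, 28.3, 32.6, 33.0, 51.8, 60.5,
        ]

    def test_every_dated_run_resolves_its_calibrations(self, reference_tree):
        from satclock.dating import resolve_calibration

        for r in make_run_grid():
            if not r.dated:
                continue
            sub = reference_tree.prune_to(r.taxa)
            for cal in r.calibration_priors():
                clade, _ = resolve_calibration(sub, cal)
                assert clade is not None, (r.run_id, cal.label)
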