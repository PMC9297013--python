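"""Faith PD, MPD and patristic distances against hand values and oracles."""

import numpy as np
import pytest

import phyloshift as ps
from phyloshift.tree import TreeValidationError

from conftest import brute_force_mpd, brute_force_pd


class TestPatristicMatrix:
    @pytest.mark.parametrize(
        "pair,expected",
        [(("A", "B"), 2.0), (("C", "D"), 3.0), (("A", "C"), 4.0), (("B", "D"), 4.0)],
    )
    def test_hand_path_enumeration(self, toy_dist, pair, expected):
        assert toy_dist.distance(*pair) == pytest.approx(expected, abs=1e-12)

    def test_zero_diagonal_and_symmetry(self, yule64_dist):
        v = yule64_dist.values
        assert np.allclose(np.diag(v), 0.0)
        assert np.allclose(v, v.T)
        assert (v >= 0).all()

    def test_two_tip_tree_single_path(self):
        tree = ps.PhyloTree.from_newick("(A:2,B:3);")
        assert ps.patristic_matrix(tree).distance("A", "B") == pytest.approx(5.0)

    def test_agrees_with_dendropy_distances(self, yule64, yule64_dist):
        pdm = yule64.dendropy_tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in yule64.dendropy_tree.taxon_namespace}
        rng = np.random.default_rng(0)
        labels = list(yule64.tip_labels)
        for _ in range(25):
            a, b = rng.choice(labels, size=2, replace=False)
            assert yule64_dist.distance(a, b) == pytest.approx(
                pdm.patristic_distance(taxa[a], taxa[b]), abs=1e-9
            )


class TestFaithPD:
    def test_full_set_is_total_branch_length(self, toy_tree):
        assert ps.faith_pd(toy_tree, toy_tree.tip_labels).value == pytest.approx(6.5)

    def test_subset_union_of_root_paths(self, toy_tree):
        assert ps.faith_pd(toy_tree, {"A", "B"}).value == pytest.approx(3.0)

    def test_single_species_root_path(self, toy_tree):
        assert ps.faith_pd(toy_tree, {"A"}).value == pytest.approx(2.0)

    def test_empty_set_convention(self, toy_tree):
        mv = ps.faith_pd(toy_tree, set())
        assert mv.defined and mv.value == 0.0

    def test_unknown_label_listed(self, toy_tree):
        with pytest.raises(KeyError, match="Z"):
            ps.faith_pd(toy_tree, {"A", "Z"})

    def test_total_branch_length_exact(self, yule64):
        full = ps.faith_pd(yule64, yule64.tip_labels).value
        assert full == yule64.total_branch_length

    def test_monotone_under_species_addition(self, yule64):
        rng = np.random.default_rng(3)
        labels = list(yule64.tip_labels)
        for _ in range(20):
            rng.shuffle(labels)
            subset = set(labels[:5])
            pd_before = ps.faith_pd(yule64, subset).value
            for add in labels[5:15]:
                subset.add(add)
                pd_after = ps.faith_pd(yule64, subset).value
                assert pd_after >= pd_before - 1e-12
                pd_before = pd_after


class TestMPD:
    def test_pair_equals_patristic_distance(self, toy_tree, toy_dist):
        assert ps.mpd(toy_dist, {"A", "B"}).value == pytest.approx(2.0)

    def test_hand_mean_over_three_pairs(self, toy_dist):
        assert ps.mpd(toy_dist, {"A", "B", "C"}).value == pytest.approx(10.0 / 3.0)

    def test_single_species_undefined(self, toy_dist):
        mv = ps.mpd(toy_dist, {"A"})
        assert not mv.defined and mv.value is None

    def test_bounded_by_min_max_pairwise(self, yule64_dist):
        rng = np.random.default_rng(4)
        labels = list(yule64_dist.labels)
        for _ in range(20):
            k = rng.integers(2, 20)
            subset = list(rng.choice(labels, size=k, replace=False))
            val = ps.mpd(yule64_dist, subset).value
            pair_d = [
                yule64_dist.distance(a, b)
                for i, a in enumerate(subset)
                for b in subset[i + 1 :]
            ]
            assert min(pair_d) - 1e-12 <= val <= max(pair_d) + 1e-12


class TestOracleEquivalence:
    def test_random_subsets_match_brute_force(self, yule64, yule64_dist):
        rng = np.random.default_rng(12)
        labels = list(yule64.tip_labels)
        for _ in range(25):
            k = int(rng.integers(1, 64))
            subset = set(rng.choice(labels, size=k, replace=False))
            assert ps.faith_pd(yule64, subset).value == pytest.approx(
                brute_force_pd(yule64, subset), abs=1e-9
            )
            if k >= 2:
                assert ps.mpd(yule64_dist, subset).value == pytest.approx(
                    brute_force_mpd(yule64_dist, subset), abs=1e-9
                )

    def test_against_scikit_bio(self, yule64):
        skbio = pytest.importorskip("skbio")
        sk_tree = skbio.TreeNode.read([yule64.as_newick()])
        labels = list(yule64.tip_labels)
        rng = np.random.default_rng(8)
        for _ in range(10):
            k = int(rng.integers(1, 64))
            subset = sorted(rng.choice(labels, size=k, replace=False))
            counts = [1] * len(subset)
            expected = skbio.diversity.alpha.faith_pd(
                counts, taxa=subset, tree=sk_tree
            )
            assert ps.faith_pd(yule64, subset).value == pytest.approx(
                float(expected), abs=1e-9
            )


class TestValidation:
    def test_missing_branch_length(self):
        with pytest.raises(TreeValidationError, match="branch length"):
            ps.PhyloTree.from_newick("((A:1,B):1,C:2);")

    def test_duplicate_tips_named(self):
        with pytest.raises(TreeValidationError, match="A"):
            ps.PhyloTree.from_newick("((A:1,A:1):1,C:2);")

    def test_too_few_tips(self):
        with pytest.raises(TreeValidationError, match="2 tips"):
            ps.PhyloTree.from_newick("(A:1);")

    def test_multifurcation_and_zero_lengths_accepted(self):
        tree = ps.PhyloTree.from_newick("(A:1,B:0,C:2,D:1);")
        assert tree.n_tips == 4
        assert ps.faith_pd(tree, {"A", "B"}).value == pytest.approx(1.0)


class TestBatchHelpers:
    def test_batch_pd_matches_scalar(self, yule64):
        from phyloshift.tree import pd_over_masks

        rng = np.random.default_rng(21)
        labels = np.array(yule64.tip_labels)
        pool = rng.choice(64, size=20, replace=False)
        masks = rng.random((50, 20)) < 0.4
        idx = yule64.indices_of(labels[pool])
        batch = pd_over_masks(yule64, idx, masks)
        for r in range(50):
            subset = set(labels[pool[masks[r]]])
            assert batch[r] == pytest.approx(
                ps.faith_pd(yule64, subset).value, abs=1e-9
            )

    def test_batch_mpd_matches_scalar(self, yule64_dist):
        from phyloshift.tree import mpd_over_masks

        rng = np.random.default_rng(22)
        labels = np.array(yule64_dist.labels)
        pool = rng.choice(64, size=15, replace=False)
        sub = yule64_dist.submatrix(yule64_dist.indices_of(labels[pool]))
        masks = rng.random((40, 15)) < 0.5
        batch = mpd_over_masks(sub, masks)
        for r in range(40):
            subset = set(labels[pool[masks[r]]])
            if len(subset) < 2:
                assert np.isnan(batch[r])
            else:
                assert batch[r] == pytest.approx(
                    ps.mpd(yule64_dist, subset).value, abs=1e-9
                )
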