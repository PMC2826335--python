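"""Nei-Li distance, neighbor joining, bootstrap and concordance."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ssrwild import (
    Accession,
    DistanceMatrix,
    Taxonomy,
    ValidationError,
    bootstrap_support,
    distance_matrix,
    nei_li_distance,
    neighbor_joining,
    tree_taxon_concordance,
)

from conftest import build_matrix


class TestNeiLiDistance:
    def test_identical_profiles_distance_zero(self):
        assert nei_li_distance([1, 0, 1], [1, 0, 1]) == 0.0

    def test_disjoint_profiles_distance_one(self):
        assert nei_li_distance([1, 1, 0, 0], [0, 0, 1, 1]) == 1.0

    def test_hand_worked_dice_complement(self):
        # a=3 shared, b=1 unique to x, c=2 unique to y -> 1 - 6/9
        x = [1, 1, 1, 1, 0, 0]
        y = [1, 1, 1, 0, 1, 1]
        assert nei_li_distance(x, y) == pytest.approx(1 - 6 / 9, abs=1e-12)

    def test_both_all_absent_is_undefined(self):
        with pytest.raises(ValidationError, match="all-absent"):
            nei_li_distance([0, 0], [0, 0])

    @given(
        st.lists(st.tuples(st.booleans(), st.booleans()), min_size=1,
                 max_size=60),
    )
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_properties(self, pairs):
        x = np.array([p[0] for p in pairs])
        y = np.array([p[1] for p in pairs])
        if not (x.any() or y.any()):
            return
        d = nei_li_distance(x, y)
        assert 0.0 <= d <= 1.0
        assert d == nei_li_distance(y, x)  # symmetry
        assert (d == 0.0) == bool((x == y).all())  # identity of indiscernibles
        # jointly-absent characters never contribute
        x2 = np.concatenate([x, [False] * 7])
        y2 = np.concatenate([y, [False] * 7])
        assert nei_li_distance(x2, y2) == d


class TestDistanceMatrix:
    def test_identical_accessions_zero_off_diagonal(self):
        mat = build_matrix(
            {"X": {"M": {1, 2}}, "Y": {"M": {1, 2}}}, ["X", "Y"]
        )
        D = distance_matrix(mat)
        assert D.get("X", "Y") == 0.0

    def test_matches_pairwise_calls(self):
        mat = build_matrix(
            {"X": {"M": {1, 2, 3}}, "Y": {"M": {2, 3, 4}}, "Z": {"M": {5}}},
            ["X", "Y", "Z"],
        )
        D = distance_matrix(mat)
        for a in "XYZ":
            for b in "XYZ":
                if a != b:
                    want = nei_li_distance(mat.profile(a), mat.profile(b))
                    assert D.get(a, b) == pytest.approx(want, abs=1e-15)
        assert np.array_equal(D.values, D.values.T)

    def test_section_grouping_is_mean_of_cross_pairs(self):
        tax = Taxonomy(
            [
                Accession("A1", "sp1", "Arachis", "A", 20),
                Accession("A2", "sp1", "Arachis", "A", 20),
                Accession("C1", "sp2", "Caulorrhizae", "unassigned", 20),
                Accession("C2", "sp2", "Caulorrhizae", "unassigned", 20),
            ]
        )
        mat = build_matrix(
            {
                "A1": {"M": {1, 2}}, "A2": {"M": {1, 3}},
                "C1": {"M": {4, 5}}, "C2": {"M": {1, 4}},
            },
            tax.ids(),
        )
        D = distance_matrix(mat, grouping="section", taxonomy=tax)
        # brute-force average over the four cross-section accession pairs
        acc = distance_matrix(mat)
        want = np.mean(
            [acc.get(a, c) for a in ("A1", "A2") for c in ("C1", "C2")]
        )
        assert D.get("Arachis", "Caulorrhizae") == pytest.approx(want, abs=1e-15)

    def test_all_absent_accession_names_pair(self):
        import numpy as np
        from ssrwild import Allele, AlleleMatrix

        cells = np.array([[True, False]])
        mat = AlleleMatrix([Allele("M", 100)], ["X", "Y"], cells)
        with pytest.raises(ValidationError, match="Y"):
            distance_matrix(mat)


def _additive_matrix():
    # path distances of the unrooted quartet A:1, B:2 | 1 | C:3, D:4
    labels = ["A", "B", "C", "D"]
    vals = np.array(
        [
            [0, 3, 5, 6],
            [3, 0, 6, 7],
            [5, 6, 0, 7],
            [6, 7, 7, 0],
        ],
        dtype=float,
    )
    return DistanceMatrix(labels, vals / 10.0)  # scale into [0, 1]


class TestNeighborJoining:
    def test_three_leaves_closed_form(self):
        D = DistanceMatrix(
            ["A", "B", "C"],
            np.array([[0, 0.3, 0.5], [0.3, 0, 0.6], [0.5, 0.6, 0]]),
        )
        tree = neighbor_joining(D)
        dist = tree.path_distances()
        assert dist[("A", "B")] == pytest.approx(0.3, abs=1e-12)
        assert dist[("A", "C")] == pytest.approx(0.5, abs=1e-12)
        assert dist[("B", "C")] == pytest.approx(0.6, abs=1e-12)

    def test_recovers_additive_quartet_exactly(self):
        tree = neighbor_joining(_additive_matrix())
        assert tree.has_split({"A", "B"})
        dist = tree.path_distances()
        D = _additive_matrix()
        for (a, b), got in dist.items():
            assert got == pytest.approx(D.get(a, b), abs=1e-12)

    def test_equidistant_matrix_deterministic_with_zero_internal_edge(self):
        D = DistanceMatrix(["A", "B", "C", "D"],
                           np.ones((4, 4)) - np.eye(4))
        t1 = neighbor_joining(D)
        t2 = neighbor_joining(D)
        assert t1.to_newick() == t2.to_newick()
        # tie-break joins the smallest (row, column) pair first
        assert t1.has_split({"A", "B"})
        (edge,) = [
            w for u, v, w in t1.edges()
            if u not in t1.leaf_names and v not in t1.leaf_names
        ]
        assert edge == 0.0

    def test_too_few_labels_rejected(self):
        D = DistanceMatrix(["A", "B"], np.array([[0, 0.5], [0.5, 0]]))
        with pytest.raises(ValidationError, match=">= 3"):
            neighbor_joining(D)

    def test_column_order_never_affects_topology(self):
        rng = np.random.default_rng(7)
        geno = {
            f"S{i}": {"M": set(map(int, 1 + rng.choice(40, size=12, replace=False)))}
            for i in range(8)
        }
        order = list(geno)
        mat = build_matrix(geno, order)
        shuffled = list(order)
        rng.shuffle(shuffled)
        mat2 = mat.subset_accessions(shuffled, drop_empty_alleles=False)
        t1 = neighbor_joining(distance_matrix(mat))
        t2 = neighbor_joining(distance_matrix(mat2))
        assert set(t1.splits()) == set(t2.splits())


from ssrwild.tree import random_additive_tree  # noqa: E402  (oracle helper)


class TestNJAdditiveConsistency:
    def test_random_additive_trees_recovered(self):
        rng = np.random.default_rng(2024)
        for _ in range(10):
            n = int(rng.integers(6, 11))
            true = random_additive_tree(rng, n)
            dists = true.path_distances()
            labels = true.leaves()
            scale = max(dists.values()) * 1.01
            vals = np.zeros((n, n))
            for i, a in enumerate(labels):
                for j, b in enumerate(labels):
                    if i < j:
                        vals[i, j] = vals[j, i] = dists[(a, b)] / scale
            got = neighbor_joining(DistanceMatrix(labels, vals))
            for pair, want in dists.items():
                assert got.path_distances()[pair] * scale == pytest.approx(
                    want, abs=1e-9
                )
            assert set(got.splits()) == set(true.splits())


class TestBootstrap:
    def test_identical_profiles_form_certain_cherry(self):
        geno = {
            "X1": {"M": {1, 2, 3}},
            "X2": {"M": {1, 2, 3}},
            "Y": {"M": {4, 5, 6}},
            "Z": {"M": {1, 7, 8}},
            "W": {"M": {2, 7, 9}},
        }
        mat = build_matrix(geno, list(geno))
        tree = bootstrap_support(mat, n_reps=50, seed=3)
        assert tree.support_of({"X1", "X2"}) == 100.0

    def test_same_seed_reproduces_supports(self):
        rng = np.random.default_rng(5)
        geno = {
            f"S{i}": {"M": set(map(int, 1 + rng.choice(30, size=10, replace=False)))}
            for i in range(6)
        }
        mat = build_matrix(geno, list(geno))
        t1 = bootstrap_support(mat, n_reps=40, seed=11)
        t2 = bootstrap_support(mat, n_reps=40, seed=11)
        assert t1.supports == t2.supports
        assert all(0.0 <= s <= 100.0 for s in t1.supports.values())

    def test_marker_unit_resamples_whole_loci(self):
        geno = {
            "X1": {"M1": {1, 2}, "M2": {10}},
            "X2": {"M1": {1, 2}, "M2": {10}},
            "Y": {"M1": {3}, "M2": {11, 12}},
            "Z": {"M1": {1, 4}, "M2": {13}},
        }
        mat = build_matrix(geno, list(geno))
        tree = bootstrap_support(mat, n_reps=20, seed=2, unit="marker")
        assert tree.support_of({"X1", "X2"}) == 100.0


class TestConcordance:
    def _tax(self, pairs):
        return Taxonomy(
            [Accession(a, sp, "Arachis", "A", 20) for a, sp in pairs]
        )

    def test_perfect_grouping_scores_one(self):
        tax = self._tax(
            [("A1", "sp1"), ("A2", "sp1"), ("B1", "sp2"), ("B2", "sp2")]
        )
        mat = build_matrix(
            {
                "A1": {"M": {1, 2}}, "A2": {"M": {1, 2, 3}},
                "B1": {"M": {8, 9}}, "B2": {"M": {8, 9, 10}},
            },
            tax.ids(),
        )
        tree = neighbor_joining(distance_matrix(mat))
        assert tree_taxon_concordance(tree, tax, "species") == 1.0

    def test_interleaved_species_scores_zero(self):
        tax = self._tax(
            [("A1", "sp1"), ("B1", "sp2"), ("A2", "sp1"), ("B2", "sp2")]
        )
        # A1 pairs with B1 and A2 with B2: neither species is a split side
        mat = build_matrix(
            {
                "A1": {"M": {1, 2}}, "B1": {"M": {1, 2, 3}},
                "A2": {"M": {8, 9}}, "B2": {"M": {8, 9, 10}},
            },
            tax.ids(),
        )
        tree = neighbor_joining(distance_matrix(mat))
        assert tree_taxon_concordance(tree, tax, "species") == 0.0

    def test_simulated_sections_mostly_concordant(self, default_dataset):
        _, taxonomy, _, mat, _, _ = default_dataset
        tree = neighbor_joining(distance_matrix(mat))
        assert tree_taxon_concordance(tree, taxonomy, "section") >= 0.8
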