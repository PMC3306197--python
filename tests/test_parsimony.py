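"""Wagner parsimony: lengths, diagnostics, searches, rooting, consensus."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from foldphylo.census import EncodedMatrix
from foldphylo.parsimony import (SearchParams, attach_support,
                                 bootstrap_support, char_diagnostics,
                                 enumerate_topologies, exhaustive_search,
                                 g1_signal, heuristic_search, is_informative,
                                 lundberg_root, majority_consensus,
                                 matrix_length, n_unrooted_topologies,
                                 random_topology, robinson_foulds, tree_stats,
                                 wagner_length)
from foldphylo.trees import PhyloTree, TreeError

from conftest import brute_force_steps, brute_force_star_max, splits_compatible


def _random_matrix(rng, n_taxa, n_chars, ancestral=23):
    return EncodedMatrix(rng.integers(0, 24, size=(n_taxa, n_chars)),
                         [f"T{i}" for i in range(n_taxa)],
                         [f"c{j}" for j in range(n_chars)], ancestral)


class TestWagnerLength:
    def test_quartet_examples(self, quartet):
        assert wagner_length(quartet, {"A": 0, "B": 0, "C": 1, "D": 1}) == 1
        assert wagner_length(quartet, {"A": 5, "B": 5, "C": 5, "D": 5}) == 0
        ac_bd = PhyloTree.from_newick("((A,C),(B,D));")
        assert wagner_length(ac_bd, {"A": 0, "C": 3, "B": 0, "D": 3}) == 6

    def test_matches_brute_force(self):
        rng = np.random.default_rng(2)
        for _ in range(30):
            n = int(rng.integers(4, 7))
            t = random_topology([f"T{i}" for i in range(n)], rng)
            char = {f"T{i}": int(rng.integers(0, 24)) for i in range(n)}
            assert wagner_length(t, char) == brute_force_steps(t, char)

    def test_rerooting_invariance(self):
        rng = np.random.default_rng(3)
        t = random_topology(list("ABCDEF"), rng)
        char = {lab: int(rng.integers(0, 24)) for lab in "ABCDEF"}
        L = wagner_length(t, char)
        for u, v in t.edges():
            assert wagner_length(t.root_on_edge(u, v), char) == L

    def test_missing_leaf_state(self, quartet):
        with pytest.raises(TreeError, match="D"):
            wagner_length(quartet, {"A": 0, "B": 1, "C": 2})

    @given(st.data())
    @settings(max_examples=40, deadline=None)
    def test_leaf_permutation_invariance(self, data):
        rng = np.random.default_rng(data.draw(st.integers(0, 10**6)))
        labels = list("ABCDE")
        t = random_topology(labels, rng)
        states = [int(rng.integers(0, 24)) for _ in labels]
        base = wagner_length(t, dict(zip(labels, states)))
        perm = data.draw(st.permutations(states))
        # permuting states over leaves changes the character, not the bound
        m = max(states) - min(states)
        assert wagner_length(t, dict(zip(labels, perm))) >= m
        assert base >= m


class TestMatrixLength:
    def test_single_character_equals_wagner(self, quartet):
        e = EncodedMatrix(np.array([[0], [0], [1], [1]]), list("ABCD"),
                          ["c1"], 23)
        assert matrix_length(quartet, e) == wagner_length(
            quartet, {"A": 0, "B": 0, "C": 1, "D": 1})

    def test_duplicated_column_doubles(self, quartet):
        col = np.array([[0], [3], [7], [23]])
        e1 = EncodedMatrix(col, list("ABCD"), ["c1"], 23)
        e2 = EncodedMatrix(np.hstack([col, col]), list("ABCD"),
                           ["c1", "c2"], 23)
        assert matrix_length(quartet, e2) == 2 * matrix_length(quartet, e1)

    def test_equals_per_character_brute_force(self):
        rng = np.random.default_rng(7)
        e = _random_matrix(rng, 6, 5)
        t = random_topology(e.taxa, rng)
        expected = sum(brute_force_steps(t, e.column(j))
                       for j in range(e.n_characters))
        assert matrix_length(t, e) == expected

    def test_taxa_mismatch(self, quartet):
        e = EncodedMatrix(np.zeros((3, 1), dtype=int), list("ABC"),
                          ["c1"], 23)
        with pytest.raises(TreeError):
            matrix_length(quartet, e)


class TestCharDiagnostics:
    def test_examples(self, quartet):
        d = char_diagnostics(quartet, {"A": 0, "B": 0, "C": 1, "D": 1})
        assert (d.s, d.m, d.g, d.ri) == (1, 1, 2, 1.0)
        d2 = char_diagnostics(quartet, {"A": 0, "B": 3, "C": 1, "D": 2})
        assert (d2.m, d2.g) == (3, 4)
        d3 = char_diagnostics(quartet, {"A": 5, "B": 5, "C": 5, "D": 5})
        assert (d3.s, d3.m, d3.g, d3.ci, d3.ri) == (0, 0, 0, 1.0, None)

    def test_m_le_s_le_g_on_random_instances(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            n = int(rng.integers(4, 8))
            t = random_topology([f"T{i}" for i in range(n)], rng)
            char = {f"T{i}": int(rng.integers(0, 24)) for i in range(n)}
            d = char_diagnostics(t, char)
            assert d.m <= d.s <= d.g

    def test_ensemble_stats_identities(self, quartet):
        e = EncodedMatrix(np.array([[0, 0], [0, 3], [1, 7], [1, 23]]),
                          list("ABCD"), ["c1", "c2"], 23)
        st_ = tree_stats(quartet, e)
        per = st_.per_character
        assert st_.length == sum(d.s for d in per)
        assert st_.ci == pytest.approx(sum(d.m for d in per)
                                       / sum(d.s for d in per))

    def test_perfect_characters_give_ci_ri_one(self, quartet):
        e = EncodedMatrix(np.array([[0], [0], [9], [9]]), list("ABCD"),
                          ["c1"], 23)
        st_ = tree_stats(quartet, e)
        assert st_.ci == 1.0 and st_.ri == 1.0


class TestInformativeness:
    @pytest.mark.parametrize("states,expected", [
        ((0, 0, 1, 1), True),
        ((0, 0, 0, 1), False),
        ((0, 1, 2, 3), True),
        ((5, 5, 5, 5), False),
    ])
    def test_quartet_examples(self, states, expected):
        char = dict(zip("ABCD", states))
        assert is_informative(char) is expected

    def test_surrogate_agrees_with_enumeration_on_small_inputs(self):
        rng = np.random.default_rng(13)
        from foldphylo import parsimony

        for _ in range(25):
            n = int(rng.integers(4, 7))
            char = {f"T{i}": int(rng.integers(0, 4)) for i in range(n)}
            exact = is_informative(char)
            counts: dict[int, int] = {}
            for v in char.values():
                counts[v] = counts.get(v, 0) + 1
            surrogate = (len(counts) >= 3
                         or sum(1 for c in counts.values() if c >= 2) >= 2)
            # the surrogate may only overcall, never undercall, on the
            # degenerate two-state patterns it was designed for
            if len(counts) <= 2:
                assert surrogate == exact


class TestSearches:
    def test_exhaustive_three_and_four_taxa(self):
        e = EncodedMatrix(np.array([[0], [5], [23]]), list("ABC"), ["c"], 23)
        assert len(exhaustive_search(e)) == 1
        e4 = EncodedMatrix(np.array([[0, 0], [0, 0], [9, 9], [9, 9]]),
                           list("ABCD"), ["c1", "c2"], 23)
        best = exhaustive_search(e4)
        assert len(best) == 1
        assert frozenset({"C", "D"}) in best[0].bipartitions()

    def test_refuses_too_many_taxa(self):
        rng = np.random.default_rng(0)
        e = _random_matrix(rng, 10, 2)
        with pytest.raises(TreeError, match="topologies"):
            exhaustive_search(e)

    def test_heuristic_deterministic(self):
        rng = np.random.default_rng(21)
        e = _random_matrix(rng, 7, 6)
        t1 = heuristic_search(e, n_replicates=4, seed=99)
        t2 = heuristic_search(e, n_replicates=4, seed=99)
        assert [t.bipartitions() for t in t1] == [t.bipartitions() for t in t2]

    @pytest.mark.parametrize("swap", ["NNI", "SPR", "TBR"])
    def test_swap_modes_reach_exhaustive_optimum(self, swap):
        rng = np.random.default_rng(5)
        e = _random_matrix(rng, 6, 5)
        Lx = matrix_length(exhaustive_search(e)[0], e)
        trees = heuristic_search(e, n_replicates=4, seed=1, swap=swap)
        assert matrix_length(trees[0], e) == Lx

    def test_recovers_clean_clade_structure(self):
        # two blocks of taxa with opposite state profiles
        states = np.array([[0, 0, 0]] * 3 + [[20, 20, 20]] * 3)
        e = EncodedMatrix(states, [f"L{i}" for i in range(3)]
                          + [f"R{i}" for i in range(3)],
                          ["c1", "c2", "c3"], 23)
        trees = heuristic_search(e, n_replicates=3, seed=0)
        split = frozenset({"R0", "R1", "R2"})
        assert all(split in t.bipartitions() for t in trees)


class TestLundberg:
    def test_single_character_roots_on_extreme_taxon(self):
        e = EncodedMatrix(np.array([[3], [2], [1], [0]]), list("ABCD"),
                          ["c"], 23)
        tree = exhaustive_search(e)[0]
        rooted = lundberg_root(tree, e)
        kids = [rooted.labels.get(k) for k in rooted.neighbors(rooted.root)]
        assert "A" in kids  # highest state sits next to the ancestral root

    def test_constant_matrix_all_edges_tie(self):
        e = EncodedMatrix(np.full((4, 2), 7), list("ABCD"),
                          ["c1", "c2"], 23)
        tree = exhaustive_search(e)[0]
        rooted = lundberg_root(tree, e)
        assert rooted.metadata["lundberg_ties"] == len(tree.edges())

    def test_age_ranked_matrix_roots_oldest_basal(self):
        # abundance decreasing with age rank in every proteome
        rng = np.random.default_rng(17)
        base = np.array([23, 18, 12, 6, 2, 0])
        states = np.clip(base[:, None] + rng.integers(-1, 2, size=(6, 5)),
                         0, 23)
        states[0] = 23
        e = EncodedMatrix(states, [f"F{i}" for i in range(6)],
                          [f"p{j}" for j in range(5)], 23)
        tree = exhaustive_search(e)[0]
        rooted = lundberg_root(tree, e)
        from foldphylo.timeline import node_distance
        nd = node_distance(rooted)
        assert nd["F0"] == min(nd.values())

    def test_rooting_never_decreases_length_and_is_bounded(self):
        rng = np.random.default_rng(23)
        from foldphylo.parsimony import (_attachment_scores, _leaf_cost,
                                         _minplus, _states_dict)
        for _ in range(20):
            e = _random_matrix(rng, int(rng.integers(4, 7)),
                               int(rng.integers(1, 5)))
            t = exhaustive_search(e)[0]
            L = matrix_length(t, e)
            anc = np.array([int(np.median(e.states[:, j]))
                            for j in range(e.n_characters)])
            extra = _minplus(_leaf_cost(anc))
            Lr = min(s for s, _ in
                     _attachment_scores(t, _states_dict(e), extra, None))
            star_cost = sum(
                brute_force_star_max(np.append(e.states[:, j], anc[j]))
                for j in range(e.n_characters))
            assert 0 <= Lr - L <= star_cost


class TestBootstrapConsensus:
    def test_congruent_characters_full_support(self):
        states = np.array([[0, 0], [0, 0], [0, 0], [23, 23], [23, 23],
                           [23, 23]])
        states = np.hstack([states] * 8)
        e = EncodedMatrix(states, [f"L{i}" for i in range(3)]
                          + [f"R{i}" for i in range(3)],
                          [f"c{j}" for j in range(16)], 23)
        sup = bootstrap_support(e, n_reps=20, seed=4,
                                search=SearchParams(replicates=1))
        assert sup[frozenset({"R0", "R1", "R2"})] == 100.0
        assert all(0 <= v <= 100 for v in sup.values())

    def test_majority_splits_are_pairwise_compatible(self):
        rng = np.random.default_rng(31)
        e = _random_matrix(rng, 6, 4)
        sup = bootstrap_support(e, n_reps=25, seed=0,
                                search=SearchParams(replicates=1))
        universe = frozenset(e.taxa)
        heavy = [s for s, v in sup.items() if v > 50]
        for i, a in enumerate(heavy):
            for b in heavy[i + 1:]:
                assert splits_compatible(a, b, universe)

    def test_consensus_of_identical_trees(self):
        rng = np.random.default_rng(6)
        t = random_topology(list("ABCDEF"), rng)
        cons = majority_consensus([t.copy() for _ in range(3)])
        assert cons.bipartitions() == t.bipartitions()

    def test_consensus_majority_rule(self):
        # splits are canonicalized as the side not containing leaf "A"
        t1 = PhyloTree.from_newick("((A,B),(C,D),E);")
        t2 = PhyloTree.from_newick("((A,B),(C,E),D);")
        t3 = PhyloTree.from_newick("((A,B),(C,E),D);")
        cons = majority_consensus([t1, t2, t3])
        assert frozenset({"C", "D", "E"}) in cons.bipartitions()  # AB| 3/3
        assert frozenset({"C", "E"}) in cons.bipartitions()       # 2/3
        assert frozenset({"C", "D"}) not in cons.bipartitions()   # 1/3

    def test_consensus_splits_compatible_on_random_sets(self):
        rng = np.random.default_rng(41)
        labels = list("ABCDEFG")
        universe = frozenset(labels)
        trees = [random_topology(labels, rng) for _ in range(7)]
        cons = majority_consensus(trees, cutoff=0.3)
        splits = list(cons.bipartitions())
        for i, a in enumerate(splits):
            for b in splits[i + 1:]:
                assert splits_compatible(a, b, universe)

    def test_consensus_leafset_mismatch(self):
        t1 = PhyloTree.from_newick("((A,B),(C,D));")
        t2 = PhyloTree.from_newick("((A,B),(C,E));")
        with pytest.raises(TreeError):
            majority_consensus([t1, t2])

    def test_attach_support(self):
        t = PhyloTree.from_newick("((A,B),(C,D),E);")
        sup = {frozenset({"C", "D"}): 87.0}
        t2 = attach_support(t, sup)
        assert 87.0 in t2.support.values()
        assert "87" in t2.to_newick(with_support=True)


class TestG1:
    def test_hand_value(self):
        from scipy import stats
        assert stats.skew([0, 0, 0, 1], bias=False) == pytest.approx(2.0)

    def test_symmetric_lengths_give_near_zero(self):
        # 2x(0,0,1,1) + 1x(0,1,0,1): quartet lengths 4, 5, 6 equally spaced
        e = EncodedMatrix(np.array([[0, 0, 0], [0, 0, 1], [1, 1, 0],
                                    [1, 1, 1]]), list("ABCD"),
                          ["c1", "c2", "c3"], 23)
        assert abs(g1_signal(e, n_random_trees=4000, seed=1)) < 0.05

    def test_structured_matrix_negative(self):
        rng = np.random.default_rng(8)
        states = np.vstack([np.zeros((4, 6), dtype=int),
                            np.full((4, 6), 20)])
        states += rng.integers(0, 3, size=states.shape)
        e = EncodedMatrix(np.clip(states, 0, 23),
                          [f"T{i}" for i in range(8)],
                          [f"c{j}" for j in range(6)], 23)
        assert g1_signal(e, n_random_trees=2000, seed=2) < 0

    def test_zero_variance_is_nan(self):
        e = EncodedMatrix(np.full((4, 2), 9), list("ABCD"), ["c1", "c2"], 23)
        assert np.isnan(g1_signal(e, n_random_trees=200, seed=0))


class TestTopologyCounts:
    def test_enumeration_count_matches_formula(self):
        for n in (4, 5, 6):
            labels = [f"T{i}" for i in range(n)]
            assert sum(1 for _ in enumerate_topologies(labels)) \
                == n_unrooted_topologies(n)

    def test_random_topology_is_valid(self):
        rng = np.random.default_rng(9)
        t = random_topology([f"T{i}" for i in range(9)], rng)
        assert sorted(t.labels.values()) == [f"T{i}" for i in range(9)]
        assert all(t.degree(n) == 3 for n in t.nodes()
                   if n not in t.labels)


def test_robinson_foulds_identity_and_symmetry():
    rng = np.random.default_rng(10)
    t1 = random_topology(list("ABCDEF"), rng)
    t2 = random_topology(list("ABCDEF"), rng)
    assert robinson_foulds(t1, t1.copy()) == 0
    assert robinson_foulds(t1, t2) == robinson_foulds(t2, t1)


def test_robinson_foulds_agrees_with_dendropy():
    import dendropy
    rng = np.random.default_rng(12)
    for _ in range(5):
        t1 = random_topology(list("ABCDEFG"), rng)
        t2 = random_topology(list("ABCDEFG"), rng)
        tns = dendropy.TaxonNamespace()
        d1 = dendropy.Tree.get(data=t1.to_newick(), schema="newick",
                               taxon_namespace=tns)
        d2 = dendropy.Tree.get(data=t2.to_newick(), schema="newick",
                               taxon_namespace=tns)
        d1.encode_bipartitions()
        d2.encode_bipartitions()
        expected = dendropy.calculate.treecompare.symmetric_difference(d1, d2)
        assert robinson_foulds(t1, t2) == expected


def test_majority_consensus_agrees_with_dendropy():
    import dendropy
    rng = np.random.default_rng(14)
    labels = list("ABCDEF")
    trees = [random_topology(labels, rng) for _ in range(5)]
    cons = majority_consensus(trees)
    tns = dendropy.TaxonNamespace()
    dlist = dendropy.TreeList(
        [dendropy.Tree.get(data=t.to_newick(), schema="newick",
                           taxon_namespace=tns) for t in trees])
    dcons = dlist.consensus(min_freq=0.5)
    from foldphylo.trees import PhyloTree as PT
    ours = cons.bipartitions()
    theirs = PT.from_newick(dcons.as_string(schema="newick")).bipartitions()
    assert ours == theirs
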