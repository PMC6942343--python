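import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from traction import tree_core as tc
from traction.fixtures import random_binary_tree

from conftest import all_binary_topologies, bfs_edit_distance, \
    contract_random_edges


def nwk(text, **kw):
    return tc.parse_newick(text, **kw)


class TestBipartition:
    def test_canonical_orientation(self):
        p = tc.Bipartition({"d", "e"}, {"a", "b", "c"})
        q = tc.Bipartition({"a", "b", "c"}, {"d", "e"})
        assert p == q
        assert hash(p) == hash(q)
        assert p.a == frozenset("abc")

    def test_validation(self):
        with pytest.raises(tc.TreeError):
            tc.Bipartition(set(), {"a"})
        with pytest.raises(tc.TreeError):
            tc.Bipartition({"a"}, {"a", "b"})

    def test_trivial(self):
        assert tc.Bipartition({"a"}, {"b", "c"}).is_trivial
        assert not tc.Bipartition({"a", "b"}, {"c", "d"}).is_trivial

    def test_restrict(self):
        p = tc.Bipartition({"a", "b"}, {"c", "d", "e"})
        assert p.restrict({"a", "c", "d"}) == tc.Bipartition({"a"}, {"c", "d"})
        assert p.restrict({"a", "b"}) is None

    def test_pairwise_compatibility(self):
        p = tc.Bipartition({"a", "b"}, {"c", "d", "e"})
        q = tc.Bipartition({"d", "e"}, {"a", "b", "c"})
        r = tc.Bipartition({"a", "c"}, {"b", "d", "e"})
        assert p.is_compatible_with(q)
        assert not p.is_compatible_with(r)


class TestNewick:
    def test_support_dialect(self):
        t = nwk("((a,b)90:0.1,c,(d,e)75);")
        bips = {repr(p) for p in tc.bipartitions(t)}
        assert bips == {"a,b|c,d,e", "a,b,c|d,e"}
        ab = tc.Bipartition({"a", "b"}, {"c", "d", "e"})
        sups = edge_supports(t)
        assert sups[ab] == 90
        assert sups[tc.Bipartition({"d", "e"}, {"a", "b", "c"})] == 75

    def test_two_leaf_tree(self):
        t = nwk("(a,b);")
        assert t.leaf_set == frozenset("ab")
        assert t.internal_edges() == []
        assert tc.write_newick(t) == "(a,b);"

    def test_single_leaf(self):
        t = nwk("a;")
        assert t.leaf_set == frozenset("a")
        assert tc.write_newick(t) == "a;"

    def test_quoted_labels(self):
        t = nwk("('taxon one','taxon two');")
        assert t.leaf_set == {"taxon one", "taxon two"}
        assert tc.parse_newick(tc.write_newick(t)).leaf_set == t.leaf_set

    def test_branch_lengths_preserved(self):
        t = nwk("((a:1,b:2):0.5,c:3,(d,e):0.25);")
        out = tc.write_newick(t)
        assert ":0.5" in out and ":3" in out

    def test_malformed_reports_position(self):
        with pytest.raises(tc.NewickParseError) as exc:
            nwk("((a,b),c;")
        assert exc.value.position is not None
        with pytest.raises(tc.NewickParseError):
            nwk("(a,b)")  # missing semicolon
        with pytest.raises(tc.NewickParseError):
            nwk("(a,,b);")

    def test_duplicate_labels_need_mul_flag(self):
        with pytest.raises(tc.MulTreeError):
            nwk("((a,a),b,c);")
        t = nwk("((a,a),b,c);", mul=True)
        assert t.is_mul
        assert t.leaf_multiset["a"] == 2

    def test_rooted_input_is_unrooted(self):
        rooted = nwk("((a,b),(c,(d,e)));")
        unrooted = nwk("((a,b),c,(d,e));")
        assert tc.trees_isomorphic(rooted, unrooted)
        same = nwk("(a,(b,(c,(d,e))));")
        caterpillar = nwk("((a,b),c,(d,e));")
        assert tc.bipartitions(same) == {
            tc.Bipartition({"d", "e"}, {"a", "b", "c"}),
            tc.Bipartition({"c", "d", "e"}, {"a", "b"}),
        }
        assert tc.trees_isomorphic(same, caterpillar)

    def test_anchor_invariance(self):
        # same unrooted tree written from three different rooted newicks
        forms = [
            "((a,b),(c,(d,e)));",
            "(a,(b,((d,e),c)));",
            "(((a,b),c),(d,e));",
        ]
        outs = {tc.write_newick(nwk(f)) for f in forms}
        assert len(outs) == 1

    @settings(max_examples=40, deadline=None)
    @given(st.integers(0, 10_000), st.integers(4, 20))
    def test_roundtrip_isomorphism(self, seed, n):
        t = random_binary_tree(n, seed)
        back = tc.parse_newick(tc.write_newick(t))
        assert tc.trees_isomorphic(t, back)

    @settings(max_examples=40, deadline=None)
    @given(st.integers(0, 10_000), st.integers(4, 15))
    def test_write_parse_idempotent(self, seed, n):
        rng = random.Random(seed)
        t = contract_random_edges(random_binary_tree(n, seed), rng.randint(0, 3),
                                  rng)
        s1 = tc.write_newick(t)
        s2 = tc.write_newick(tc.parse_newick(s1))
        assert s1 == s2

    def test_support_emitted_as_internal_label(self):
        t = nwk("((a,b)90,c,(d,e));")
        assert ")90" in tc.write_newick(t)


def edge_supports(tree):
    """Bipartition -> support map for a singly-labeled tree."""
    out = {}
    root = min(tree._adj)
    below, parent = tree._below_leafsets(root)
    all_l = tree.leaf_set
    for v, p in parent.items():
        if p is None:
            continue
        s = tree.support(v, p)
        if s is None:
            continue
        side = below[v]
        if 0 < len(side) < len(all_l):
            out[tc.Bipartition(side, all_l - side)] = s
    return out


class TestBipartitions:
    def test_hand_enumeration(self):
        t = nwk("((a,b),c,(d,e));")
        assert tc.bipartitions(t) == {
            tc.Bipartition({"a", "b"}, {"c", "d", "e"}),
            tc.Bipartition({"d", "e"}, {"a", "b", "c"}),
        }

    def test_star_has_none(self):
        assert tc.bipartitions(nwk("(a,b,c,d,e);")) == set()

    @pytest.mark.parametrize("n", [4, 6, 9, 13])
    def test_binary_count_identity(self, n):
        t = random_binary_tree(n, seed=n)
        assert len(tc.bipartitions(t)) == n - 3

    def test_mul_tree_rejected(self):
        t = nwk("((a,a),b,c);", mul=True)
        with pytest.raises(tc.MulTreeError):
            tc.bipartitions(t)


class TestRestrict:
    def test_suppresses_degree_two(self):
        t = nwk("((a,b),x,(c,d));")
        r = tc.restrict(t, {"a", "b", "c", "d"})
        assert tc.bipartitions(r) == {tc.Bipartition({"a", "b"}, {"c", "d"})}

    def test_identity(self):
        t = nwk("((a,b),c,(d,e));")
        assert tc.trees_isomorphic(tc.restrict(t, t.leaf_set), t)

    def test_three_leaves_is_star(self):
        t = nwk("((a,b),c,(d,e));")
        r = tc.restrict(t, {"a", "c", "e"})
        assert r.leaf_set == {"a", "c", "e"}
        assert r.internal_edges() == []

    def test_errors(self):
        t = nwk("((a,b),c,(d,e));")
        with pytest.raises(tc.TreeError):
            tc.restrict(t, {"a", "z"})
        with pytest.raises(tc.TreeError):
            tc.restrict(t, {"a"})

    @pytest.mark.parametrize("seed", range(25))
    def test_commutes_with_bipartitions(self, seed):
        rng = random.Random(seed)
        n = rng.randint(5, 12)
        t = contract_random_edges(random_binary_tree(n, seed),
                                  rng.randint(0, 3), rng)
        labels = sorted(t.leaf_set)
        sub = frozenset(rng.sample(labels, rng.randint(4, n - 1)))
        expected = set()
        for pi in tc.bipartitions(t):
            r = pi.restrict(sub)
            if r is not None and not r.is_trivial:
                expected.add(r)
        assert tc.bipartitions(tc.restrict(t, sub)) == expected


class TestCompatibility:
    def test_examples(self):
        t = nwk("(a,b,(c,d,e));")
        assert tc.is_compatible(tc.Bipartition("de", "abc"), t)
        t2 = nwk("((a,c),b,d,e);")
        assert not tc.is_compatible(tc.Bipartition("ab", "cde"), t2)

    def test_self_compatibility(self):
        t = nwk("((a,b),c,(d,e));")
        for pi in tc.bipartitions(t):
            assert tc.is_compatible(pi, t)

    def test_leafset_mismatch(self):
        t = nwk("((a,b),c,(d,e));")
        with pytest.raises(tc.LeafSetMismatchError):
            tc.is_compatible(tc.Bipartition("ab", "cd"), t)

    @pytest.mark.parametrize("seed", range(15))
    def test_matches_pairwise_rule(self, seed):
        # tree-traversal implementation agrees with the four-intersection
        # rule applied against every displayed split
        rng = random.Random(seed)
        n = rng.randint(5, 9)
        t = contract_random_edges(random_binary_tree(n, seed),
                                  rng.randint(1, 3), rng)
        from conftest import all_nontrivial_splits
        bips = tc.bipartitions(t)
        for pi in all_nontrivial_splits(t.leaf_set):
            expected = all(pi.is_compatible_with(q) for q in bips)
            assert tc.is_compatible(pi, t) == expected


class TestAddBipartition:
    def test_insertion(self):
        t = nwk("(a,b,(c,d,e));")
        out = tc.add_bipartition(t, tc.Bipartition("de", "abc"))
        assert tc.bipartitions(out) == {
            tc.Bipartition("ab", "cde"), tc.Bipartition("de", "abc")}

    def test_existing_is_noop(self):
        t = nwk("((a,b),c,(d,e));")
        out = tc.add_bipartition(t, tc.Bipartition("ab", "cde"))
        assert tc.trees_isomorphic(out, t)

    def test_incompatible_raises(self):
        t = nwk("((a,c),b,d,e);")
        with pytest.raises(tc.IncompatibleBipartitionError):
            tc.add_bipartition(t, tc.Bipartition("ab", "cde"))

    @pytest.mark.parametrize("seed", range(10))
    def test_rebuild_binary_from_star(self, seed):
        b = random_binary_tree(8, seed)
        star = tc.UnrootedTree.star(sorted(b.leaf_set))
        rebuilt = star
        for pi in tc.bipartitions(b):
            rebuilt = tc.add_bipartition(rebuilt, pi)
        assert tc.trees_isomorphic(rebuilt, b)

    @pytest.mark.parametrize("seed", range(20))
    def test_insertion_order_independent(self, seed):
        rng = random.Random(seed)
        b = random_binary_tree(9, seed)
        target = sorted(tc.bipartitions(b), key=tc.Bipartition.sort_key)
        star = tc.UnrootedTree.star(sorted(b.leaf_set))
        results = set()
        for _ in range(5):
            perm = target[:]
            rng.shuffle(perm)
            t = star
            for pi in perm:
                t = tc.add_bipartition(t, pi)
            results.add(frozenset(tc.bipartitions(t)))
        assert len(results) == 1


class TestRF:
    def test_identity(self):
        t = nwk("((a,b),c,(d,e));")
        assert tc.rf_distance(t, t.copy()) == 0

    def test_symmetric_difference(self):
        t1 = nwk("((a,b),c,(d,e));")
        t2 = nwk("((a,c),b,(d,e));")
        assert tc.rf_distance(t1, t2) == 2
        assert tc.rf_distance(t2, t1) == 2

    @pytest.mark.parametrize("n", [5, 7, 10])
    def test_star_vs_binary(self, n):
        b = random_binary_tree(n, seed=n)
        star = tc.UnrootedTree.star(sorted(b.leaf_set))
        assert tc.rf_distance(b, star) == n - 3

    def test_leafset_mismatch(self):
        with pytest.raises(tc.LeafSetMismatchError):
            tc.rf_distance(nwk("((a,b),c,(d,e));"), nwk("((a,b),c,(d,f));"))

    def test_metric_axioms_all_pairs_n5(self):
        trees = all_binary_topologies(list("abcde"))
        assert len(trees) == 15
        ds = [[tc.rf_distance(x, y) for y in trees] for x in trees]
        for i, x in enumerate(trees):
            assert ds[i][i] == 0
            for j in range(len(trees)):
                assert ds[i][j] == ds[j][i]
                assert (ds[i][j] == 0) == tc.trees_isomorphic(x, trees[j])
                for k in range(len(trees)):
                    assert ds[i][k] <= ds[i][j] + ds[j][k]

    @pytest.mark.parametrize("seed", range(30))
    def test_triangle_inequality_random_triples(self, seed):
        rng = random.Random(seed)
        n = rng.randint(5, 8)
        a, b, c = (random_binary_tree(n, 3 * seed + i) for i in range(3))
        assert tc.rf_distance(a, c) <= tc.rf_distance(a, b) + tc.rf_distance(b, c)

    @pytest.mark.parametrize("seed", range(6))
    def test_equals_bfs_edit_distance(self, seed):
        rng = random.Random(seed)
        n = rng.randint(4, 6)
        t1 = contract_random_edges(random_binary_tree(n, seed),
                                   rng.randint(0, 2), rng)
        t2 = contract_random_edges(random_binary_tree(n, seed + 100),
                                   rng.randint(0, 2), rng)
        assert tc.rf_distance(t1, t2) == bfs_edit_distance(t1, t2)


class TestNormalizedRF:
    def test_zero(self):
        t = nwk("((a,b),c,(d,e));")
        assert tc.normalized_rf(t, t.copy()) == 0.0

    def test_maximal(self):
        t1 = nwk("((a,b),c,(d,e));")
        t2 = nwk("((a,d),c,(b,e));")
        assert tc.rf_distance(t1, t2) == 4
        assert tc.normalized_rf(t1, t2) == 1.0

    def test_half(self):
        t1 = nwk("((a,b),c,(d,e));")
        t2 = nwk("((a,c),b,(d,e));")
        assert tc.normalized_rf(t1, t2) == 0.5

    def test_small_n_errors(self):
        t = nwk("(a,b,c);")
        with pytest.raises(tc.TreeError):
            tc.normalized_rf(t, t.copy())


class TestCollapse:
    def test_threshold_example(self):
        t = nwk("((a,b)90,(c,d)60,e);")
        out = tc.collapse_low_support(t, 75)
        assert tc.bipartitions(out) == {tc.Bipartition("ab", "cde")}

    def test_strict_comparison(self):
        t = nwk("((a,b)75,(c,d)75,e);")
        out = tc.collapse_low_support(t, 75)  # 75 is not < 75
        assert len(tc.bipartitions(out)) == 2

    def test_threshold_zero_noop(self):
        t = nwk("((a,b)90,(c,d)60,e);")
        out = tc.collapse_low_support(t, 0)
        assert tc.bipartitions(out) == tc.bipartitions(t)

    def test_huge_threshold_gives_star(self):
        t = nwk("((a,b)90,(c,d)60,e);")
        out = tc.collapse_low_support(t, 1000)
        assert tc.bipartitions(out) == set()

    def test_unannotated_edges_retained(self):
        t = nwk("((a,b),(c,d)60,e);")
        out = tc.collapse_low_support(t, 75)
        assert tc.bipartitions(out) == {tc.Bipartition("ab", "cde")}


class TestRandomResolution:
    def test_binary_unchanged(self):
        t = nwk("((a,b),c,(d,e));")
        out = tc.random_binary_resolution(t, seed=3)
        assert tc.trees_isomorphic(out, t)

    @pytest.mark.parametrize("seed", range(50))
    def test_refines_input(self, seed):
        rng = random.Random(seed)
        n = rng.randint(5, 12)
        t = contract_random_edges(random_binary_tree(n, seed),
                                  rng.randint(1, 4), rng)
        out = tc.random_binary_resolution(t, seed)
        assert out.is_binary
        assert tc.bipartitions(t) <= tc.bipartitions(out)
        assert len(tc.bipartitions(out)) == n - 3

    def test_deterministic(self):
        t = nwk("(a,b,c,d,e,f);")
        a = tc.write_newick(tc.random_binary_resolution(t, 42))
        b = tc.write_newick(tc.random_binary_resolution(t, 42))
        assert a == b

    def test_uniform_at_degree_four(self):
        t = nwk("(a,b,c,d);")
        counts = {}
        for seed in range(10_000):
            out = tc.random_binary_resolution(t, seed)
            (pi,) = tc.bipartitions(out)
            counts[pi] = counts.get(pi, 0) + 1
        assert len(counts) == 3
        for c in counts.values():
            assert abs(c / 10_000 - 1 / 3) < 0.02
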