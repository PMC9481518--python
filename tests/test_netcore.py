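import pytest

from hybnum.constructions import beaded_tree, build_B
from hybnum.netcore import (
    NetworkError,
    PhyloNetwork,
    PloidyProfile,
    network_hybrid_number,
    path_count_vector,
    realizes,
    unfold_leaf_multiset,
    validate,
)

from conftest import assert_consistent, profile


class TestPloidyProfile:
    def test_sorts_descending(self):
        p = PloidyProfile.from_pairs([("a", 2), ("b", 9), ("c", 2)])
        assert p.multiplicities == (9, 2, 2)
        assert p.labels == ("b", "a", "c")

    def test_rejects_duplicates_and_nonpositive(self):
        with pytest.raises(ValueError):
            PloidyProfile.from_pairs([("a", 2), ("a", 1)])
        with pytest.raises(ValueError):
            PloidyProfile.from_pairs([("a", 0)])

    def test_simple_flags(self):
        assert profile(5, 1, 1).is_simple
        assert not profile(5, 2).is_simple
        assert profile(7).is_strictly_simple
        assert profile(1, 1).is_simple


class TestValidate:
    def test_bead_is_valid(self, bead):
        assert validate(bead) == []

    def test_degree_one_one_vertex_is_flagged(self, bead):
        # manually splice a (1,1) vertex without using subdivide's contract
        arc = bead.leaf_in_arc("x1")
        mid = bead.subdivide_arc(arc)
        # subdivision vertices are legal only transiently; validate flags them
        problems = bead.validate()
        assert any(mid in p for p in problems)

    def test_two_roots_flagged(self):
        net = PhyloNetwork()
        r1, r2 = net.new_vertex(), net.new_vertex()
        a = net.new_vertex(label="x1")
        b = net.new_vertex(label="x2")
        net.add_arc(r1, a)
        net.add_arc(r1, b)
        net.add_arc(r2, a)
        problems = net.validate()
        assert any("multiple roots" in p for p in problems)

    def test_loop_rejected(self):
        net = PhyloNetwork()
        v = net.new_vertex()
        with pytest.raises(NetworkError):
            net.add_arc(v, v)

    def test_single_vertex_network(self):
        net = PhyloNetwork()
        net.new_vertex(label="x1")
        assert net.validate() == []
        assert net.path_count_vector() == {"x1": 1}
        assert net.hybrid_number() == 0


class TestIsBinary:
    def test_bead_is_binary(self, bead):
        assert bead.is_binary()

    def test_indegree_three_hybrid(self):
        net = PhyloNetwork()
        root = net.new_vertex()
        t = net.new_vertex()
        h = net.new_vertex()
        leaf = net.new_vertex(label="x1")
        net.add_arc(root, t)
        net.add_arc(root, h)
        net.add_arc(t, h)
        net.add_arc(t, h)
        net.add_arc(h, leaf)
        assert net.validate() == []
        assert not net.is_binary()
        assert net.hybrid_number() == 2  # indeg 3 counts twice


class TestPathCounts:
    def test_three_bead_chain(self):
        net = beaded_tree(3)
        assert net.path_count_vector() == {"x1": 8}
        # independent route: explicit path enumeration
        assert dict(net.unfold_leaf_multiset()) == {"x1": 8}

    def test_tree_counts_are_one(self, cherry_tree):
        assert path_count_vector(cherry_tree) == {"x1": 1, "x2": 1}
        assert network_hybrid_number(cherry_tree) == 0

    def test_traceback_network_counts(self):
        from hybnum.traceback import build_N_auto

        net = build_N_auto(profile(12, 6, 6, 5)).network
        assert net.path_count_vector() == {"x1": 12, "x2": 6, "x3": 6, "x4": 5}
        assert net.hybrid_number() == 5

    def test_bead_hybrid_number(self, bead):
        assert bead.hybrid_number() == 1


class TestRealizes:
    def test_bead(self, bead):
        assert realizes(bead, profile(2, labels=["x1"]))
        assert not realizes(bead, profile(3, labels=["x1"]))

    def test_label_mismatch_errors(self, bead):
        with pytest.raises(NetworkError):
            bead.realizes(profile(2, labels=["y1"]))

    def test_B9(self):
        b = build_B(profile(9))
        assert b.realizes(profile(9, labels=["x1"]))
        assert dict(unfold_leaf_multiset(b)) == {"x1": 9}


class TestSubdivideArc:
    def test_preserves_counts(self, bead):
        bead.subdivide_arc(bead.leaf_in_arc("x1"))
        assert bead.path_count_vector() == {"x1": 2}

    def test_two_subdivisions_chain_in_order(self, bead):
        arc = bead.leaf_in_arc("x1")
        s1 = bead.subdivide_arc(arc)
        s2 = bead.subdivide_arc(bead.leaf_in_arc("x1"))
        # s2 sits below s1, directly above the leaf
        assert [a[1] for a in bead.out_arcs(s1)] == [s2]

    def test_parallel_arc_subdivision_destroys_bead_keeps_counts(self, bead):
        root = bead.root
        arc = bead.out_arcs(root)[0]
        bead.subdivide_arc(arc)
        assert bead.path_count_vector() == {"x1": 2}

    def test_missing_arc_errors(self, bead):
        with pytest.raises(NetworkError):
            bead.subdivide_arc(("nope", "nowhere", 0))


class TestExpandCherry:
    def test_counts_inherited(self, bead):
        before = bead.num_vertices()
        bead.expand_cherry("x1", "x2")
        assert bead.path_count_vector() == {"x1": 2, "x2": 2}
        assert bead.num_vertices() == before + 2

    def test_on_tree_stays_tree(self, cherry_tree):
        cherry_tree.expand_cherry("x2", "x3")
        assert cherry_tree.hybrid_number() == 0
        assert cherry_tree.validate() == []

    def test_duplicate_label_errors(self, bead):
        bead.expand_cherry("x1", "x2")
        with pytest.raises(NetworkError):
            bead.expand_cherry("x1", "x2")


class TestHybridize:
    def test_51_to_65(self):
        # the count-5 leaf donates into the count-1 leaf, yielding (6, 5)
        net = build_B(profile(5, 1))
        assert net.path_count_vector() == {"x1": 5, "x2": 1}
        net.hybridize(donor_label="x1", receiver_label="x2")
        assert net.path_count_vector() == {"x1": 5, "x2": 6}
        assert net.realizes(PloidyProfile.from_pairs([("x2", 6), ("x1", 5)]))

    def test_on_cherry(self, cherry_tree):
        h_before = cherry_tree.hybrid_number()
        cherry_tree.hybridize(donor_label="x2", receiver_label="x1")
        assert cherry_tree.path_count_vector() == {"x1": 2, "x2": 1}
        assert cherry_tree.hybrid_number() == h_before + 1
        assert cherry_tree.is_binary()

    def test_same_label_rejected(self, cherry_tree):
        with pytest.raises(NetworkError):
            cherry_tree.hybridize(donor_label="x1", receiver_label="x1")

    def test_adds_exactly_two_vertices(self, cherry_tree):
        before = cherry_tree.num_vertices()
        cherry_tree.hybridize(donor_label="x2", receiver_label="x1")
        assert cherry_tree.num_vertices() == before + 2


class TestAddPendantLeaf:
    def test_on_root_arc_count_one(self, bead):
        arc = bead.out_arcs(bead.root)[0]
        before = bead.num_vertices()
        bead.add_pendant_leaf(arc, "x2")
        assert bead.path_count_vector() == {"x1": 2, "x2": 1}
        assert bead.num_vertices() == before + 2

    def test_below_three_bead_chain(self):
        net = beaded_tree(3)
        net.add_pendant_leaf(net.leaf_in_arc("x1"), "x2")
        assert net.path_count_vector() == {"x1": 8, "x2": 8}

    def test_duplicate_label_errors(self, bead):
        with pytest.raises(NetworkError):
            bead.add_pendant_leaf(bead.leaf_in_arc("x1"), "x1")


class TestInvariants:
    def test_bead_chain_attains_power_ceiling(self):
        for q in range(5):
            net = beaded_tree(q)
            counts = assert_consistent(net)
            assert counts == {"x1": 2**q}
            assert net.hybrid_number() == q

    def test_surgeries_recount(self, bead):
        """Chained surgeries keep the DP and enumeration routes in lockstep."""
        bead.expand_cherry("x1", "x2")
        assert_consistent(bead)
        bead.hybridize(donor_label="x2", receiver_label="x1")
        assert_consistent(bead)
        arc = bead.out_arcs(bead.root)[0]
        bead.add_pendant_leaf(arc, "x3")
        counts = assert_consistent(bead)
        assert counts == {"x1": 4, "x2": 2, "x3": 1}
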