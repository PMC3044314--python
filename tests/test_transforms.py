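import itertools

import numpy as np
import pytest

import minarg as m
from minarg.arg_model import Arg, Strand
from minarg.transforms import (
    EventCounts,
    compactify,
    event_counts,
    is_removable,
    md_check,
    node_merge,
    reduce_arg,
    remove_vertex,
    remove_vertices,
)


def _s(p, c, t, labels=()):
    return Strand(p, c, t, frozenset(labels))


class TestRemoveVertex:
    def test_fig2_label_union(self, fig2):
        g = remove_vertex(fig2, "v")
        labels = {
            (s.parent, s.child, s.tree): s.labels for s in g.strands if s.labels
        }
        assert labels == {
            ("a", "u1", 1): frozenset({"c", "d"}),
            ("b", "u2", 2): frozenset({"q"}),
        }
        assert "v" not in g.vertices

    def test_empty_incoming_labels_leave_outgoing_unchanged(self, fig2):
        bare = fig2.replace(strands=tuple(s.with_labels(()) for s in fig2.strands))
        g = remove_vertex(bare, "v")
        assert all(not s.labels for s in g.strands)
        assert g.children("a") == {"u1", "u2", "u3"}

    def test_leaf_removal_rejected(self, fig2):
        with pytest.raises(m.ArgError, match="leaf"):
            remove_vertex(fig2, "u1")

    def test_multiple_same_tree_parents_rejected(self, fig2):
        # give v a second red parent
        arg = fig2.replace(
            vertices={**fig2.vertices, "p2": 9.0},
            strands=fig2.strands + (_s("p2", "v", 1),),
        )
        with pytest.raises(m.ArgError, match="parents in tree 1"):
            remove_vertex(arg, "v")
        assert not is_removable(arg, "v")

    def test_unknown_vertex(self, fig2):
        with pytest.raises(m.ArgError):
            remove_vertex(fig2, "ghost")


class TestRemoveVertices:
    def test_empty_set_is_identity(self, fig2):
        assert remove_vertices(fig2, []) == fig2

    def test_pair_orders_agree_on_samples(self, small_args):
        checked = 0
        for arg in small_args[:40]:
            removable = [v for v in sorted(arg.vertices) if is_removable(arg, v)]
            for v1, v2 in itertools.combinations(removable, 2):
                try:
                    g12 = remove_vertex(remove_vertex(arg, v1), v2)
                    g21 = remove_vertex(remove_vertex(arg, v2), v1)
                except m.ArgError:
                    continue
                checked += 1
                assert m.samples_equal(
                    m.compute_samples(g12), m.compute_samples(g21)
                ), (v1, v2)
        assert checked > 50

    def test_motif_removal_leaves_chain_material(self):
        unb = m.unbounded_pattern_fixture(2)
        u = [
            v
            for v in sorted(unb.vertices)
            if not unb.is_leaf(v)
            and len(unb.children(v)) >= 2
            and not m.is_t_coalescent(unb, v)
            and is_removable(unb, v)
        ]
        g = remove_vertices(unb, u)
        assert m.samples_equal(m.compute_samples(unb), m.compute_samples(g))


class TestResolvability:
    def test_fig2_marked_vertex_is_resolvable(self, fig2):
        assert m.is_resolvable(fig2, "v")

    def test_pass_through_exchange_vertex_is_not(self):
        cfg = m.SimConfig(K=3, N=20, M=2, junction_recomb_probs=0.02,
                          mutation_rate=0.05)
        for seed in range(40):
            rng = np.random.default_rng(seed)
            arg = m.annotate_mutations(m.simulate_binary_arg(cfg, rng), cfg, rng)
            recs = [
                v
                for v in sorted(arg.vertices)
                if len(arg.children(v)) == 1 and len(arg.parents(v)) >= 2
            ]
            if recs:
                assert not m.is_resolvable(arg, recs[0])
                return
        pytest.fail("no recombination pass-through vertex sampled")

    def test_resolvable_coalescent_implies_t_coalescent(self, small_args):
        for arg in small_args:
            for v in sorted(arg.vertices):
                if (
                    is_removable(arg, v)
                    and len(arg.children(v)) >= 2
                    and m.is_resolvable(arg, v)
                ):
                    assert m.is_t_coalescent(arg, v)


class TestReduce:
    def test_already_reduced_is_fixpoint(self):
        arg = Arg(
            1, (1.0,),
            {"a": 0.0, "b": 0.0, "r": 9.0},
            (_s("r", "a", 1), _s("r", "b", 1)),
            ("a", "b"),
        )
        assert reduce_arg(arg) == arg

    def test_chain_of_three_unary_vertices_collapses(self):
        arg = Arg(
            1, (1.0,),
            {"a": 0.0, "b": 0.0, "m1": 1.0, "m2": 2.0, "m3": 3.0, "r": 9.0},
            (
                _s("m1", "a", 1, {"x"}),
                _s("m2", "m1", 1, {"y"}),
                _s("m3", "m2", 1),
                _s("r", "m3", 1, {"z"}),
                _s("r", "b", 1),
            ),
            ("a", "b"),
        )
        g = reduce_arg(arg)
        assert set(g.vertices) == {"a", "b", "r"}
        (strand,) = [s for s in g.strands if s.child == "a"]
        assert strand.labels == frozenset({"x", "y", "z"})

    def test_reduction_preserves_samples_and_structure(self, grid_std):
        for arg in grid_std[:40]:
            g = reduce_arg(arg)
            assert m.samples_equal(m.compute_samples(arg), m.compute_samples(g))
            assert m.structure_preserving(arg, g)


class TestCompactify:
    def test_unbounded_fixture_gains_apex_gmrca(self):
        unb = m.unbounded_pattern_fixture(3)
        g = compactify(unb)
        apex = m.find_gmrca(g)
        assert apex is not None
        assert len(g.children(apex)) <= unb.M * unb.K

    def test_samples_preserved(self):
        unb = m.unbounded_pattern_fixture(2)
        assert m.samples_equal(
            m.compute_samples(unb), m.compute_samples(compactify(unb))
        )

    def test_rejects_bounded_arg(self):
        arg = m.simulate_binary_arg(m.SimConfig(K=3, N=20, M=1, seed=2))
        with pytest.raises(m.ArgError, match="GMRCA"):
            compactify(arg)


class TestNodeMerge:
    def merge_case(self):
        # two pass-through vertices on disjoint segments at equal times
        return Arg(
            2, (1.0, 1.0),
            {"l1": 0.0, "l2": 0.0, "x": 1.0, "y": 1.0, "r1": 3.0, "r2": 4.0},
            (
                _s("r1", "x", 1, {"a"}),
                _s("x", "l1", 1),
                _s("r1", "l2", 1),
                _s("r2", "y", 2, {"b"}),
                _s("y", "l2", 2),
                _s("r2", "l1", 2),
            ),
            ("l1", "l2"),
        )

    def test_disjoint_merge_preserves_samples_and_structure(self):
        arg = self.merge_case()
        g = node_merge(arg, "x", "y")
        assert m.samples_equal(m.compute_samples(arg), m.compute_samples(g))
        assert m.structure_preserving(arg, g)
        assert "x~y" in g.vertices

    def test_overlapping_sg_rejected(self):
        # sibling subtrees of the same tree: no path, but sg overlaps
        arg = Arg(
            1, (1.0,),
            {"l1": 0.0, "l2": 0.0, "l3": 0.0, "l4": 0.0,
             "p": 1.0, "q": 1.0, "top": 9.0},
            (
                _s("p", "l1", 1), _s("p", "l2", 1),
                _s("q", "l3", 1), _s("q", "l4", 1),
                _s("top", "p", 1), _s("top", "q", 1),
            ),
            ("l1", "l2", "l3", "l4"),
        )
        with pytest.raises(m.ArgError, match="overlap"):
            node_merge(arg, "p", "q")

    def test_ancestor_descendant_rejected(self, fig2):
        with pytest.raises(m.ArgError, match="path"):
            node_merge(fig2, "a", "v")


class TestMinimalDescriptor:
    def test_unbounded_instance_gets_bounded_descriptor(self):
        counts = set()
        for d in range(1, 6):
            md = m.minimal_descriptor(m.unbounded_pattern_fixture(d))
            counts.add(len(md.vertices))
            g = m.find_gmrca(md)
            assert g is not None and len(md.children(g)) <= 4
        assert len(counts) == 1

    def test_single_tree_arg_is_already_minimal(self):
        arg = m.simulate_binary_arg(m.SimConfig(K=5, N=20, M=1, seed=3))
        md = m.minimal_descriptor(arg)
        assert md == reduce_arg(arg)

    def test_idempotent_up_to_graph_equality(self, grid_std_mds):
        for md in grid_std_mds[:30]:
            assert m.minimal_descriptor(md) == md

    def test_preserves_samples_and_structure(self, grid_std, grid_std_mds):
        for arg, md in list(zip(grid_std, grid_std_mds))[:60]:
            assert m.samples_equal(m.compute_samples(arg), m.compute_samples(md))
            assert m.structure_preserving(arg, md)


class TestEventCounts:
    def test_minimal_two_leaf_tree(self):
        arg = Arg(
            1, (1.0,),
            {"a": 0.0, "b": 0.0, "r": 9.0},
            (_s("r", "a", 1), _s("r", "b", 1)),
            ("a", "b"),
        )
        assert event_counts(arg) == EventCounts(
            n_c=1, n_e=0, n_v=1, n_exchange_vertices=0
        )

    def test_fig2_counts(self, fig2):
        ec = event_counts(fig2)
        assert ec == EventCounts(n_c=4, n_e=1, n_v=4, n_exchange_vertices=1)

    def test_leaf_exchange_events_are_excluded(self):
        # a leaf with two parents encodes one exchange event, not counted
        arg = Arg(
            2, (1.0, 1.0),
            {"a": 0.0, "b": 0.0, "p": 5.0, "q": 6.0, "top": 9.0},
            (
                _s("p", "a", 1), _s("q", "a", 2),
                _s("top", "p", 1), _s("top", "q", 2),
                _s("p", "b", 1), _s("q", "b", 2),
            ),
            ("a", "b"),
        )
        assert event_counts(arg).n_e == 0


class TestMdCheck:
    def test_clean_on_extracted_descriptors(self, grid_std_mds):
        for md in grid_std_mds[:60]:
            assert md_check(md) == []

    def test_flags_non_t_coalescent_vertex(self):
        unb = m.unbounded_pattern_fixture(1)
        codes = {v.code for v in md_check(unb)}
        assert "non-t-coalescent" in codes

    def test_flags_gapped_vertex_in_binary_mode(self, fig2):
        arg = fig2.replace(
            vertices={**fig2.vertices, "g": 9.0, "g2": 10.0},
            strands=fig2.strands
            + (_s("g", "a", 1), _s("g", "w", 3), _s("g2", "g", 1), _s("g2", "g", 3)),
        )
        codes = {v.code for v in md_check(arg, binary=True)}
        assert "gapped" in codes
        assert "gapped" not in {v.code for v in md_check(fig2, binary=True)}

    def test_flags_out_degree_violation_in_binary_mode(self, fig2):
        codes = {v.code for v in md_check(fig2, binary=True)}
        assert "binary-outdegree" in codes  # b and w have 3 children
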