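import math

import numpy as np
import pytest

from quartetnet import (
    IdentifiabilityError,
    NetworkError,
    ParseError,
    RootingError,
    apply_identifiability_constraints,
    bad_diamond_reparam,
    hybrid_cycles,
    induced_subnetwork,
    major_tree,
    parse_enewick,
    root_with_outgroup,
    same_topology,
    validate_level1,
    write_enewick,
)
from conftest import TWO_CYCLES7, random_valid_network


class TestParsing:
    def test_tree_is_a_network_without_hybrids(self):
        net = parse_enewick("(A,(B,(C,D)));")
        assert net.taxa() == ["A", "B", "C", "D"]
        assert net.h == 0
        assert validate_level1(net) == []

    def test_hybrid_fields_are_mapped(self):
        net = parse_enewick("((A,(B)#H1:1.0::0.7),(#H1:0.5::0.3,C),D);")
        assert net.h == 1
        h = net.hybrid_nodes()[0]
        emaj, emin = net.hybrid_parents(h)
        assert emaj.gamma == pytest.approx(0.7)
        assert emin.gamma == pytest.approx(0.3)
        assert emaj.major and not emin.major
        assert emaj.length == pytest.approx(1.0)

    def test_gamma_complement_filled_in(self):
        net = parse_enewick("((A,(B)#H1:1.0::0.7),(#H1,C),D);")
        _maj, emin = net.hybrid_parents(net.hybrid_nodes()[0])
        assert emin.gamma == pytest.approx(0.3)

    @pytest.mark.parametrize("bad, exc", [
        ("((A,(B)#H1),(#H1,C),(#H1,D));", ParseError),      # tag 3 times
        ("((A,(B)#H1:::1.4),(#H1,C),D);", ParseError),      # gamma > 1
        ("((A,(B)#H1:::0.6),(#H1:::0.6,C),D);", ParseError),  # sum != 1
        ("((A,B),(A,C));", NetworkError),                   # duplicate leaf
        ("(A,(B,(C,D))", ParseError),                       # unbalanced
    ])
    def test_malformed_input_rejected(self, bad, exc):
        with pytest.raises(exc):
            parse_enewick(bad)

    def test_polytomy_rejected_in_networks(self):
        with pytest.raises(NetworkError):
            parse_enewick("(A,B,C,D,E);")


class TestRoundTrip:
    def test_round_trip_preserves_structure_lengths_gammas(
            self, single_desc_net):
        text = write_enewick(single_desc_net)
        back = parse_enewick(text)
        assert same_topology(single_desc_net, back, mode="semi")
        assert sorted(e.length for e in back.edges.values()) == pytest.approx(
            sorted(e.length for e in single_desc_net.edges.values()),
            abs=1e-9)
        g1 = sorted(e.gamma for e in back.edges.values() if e.hybrid)
        g2 = sorted(e.gamma for e in single_desc_net.edges.values()
                    if e.hybrid)
        assert g1 == pytest.approx(g2)

    def test_round_trip_on_random_networks(self, rng):
        for _ in range(25):
            net = random_valid_network(rng)
            back = parse_enewick(write_enewick(net))
            assert same_topology(net, back, mode="semi")

    def test_missing_lengths_roundtrip(self):
        net = parse_enewick("(A,(B,(C,D)));")
        assert write_enewick(net).count(":") == 0

    def test_hybrid_tag_count_matches_h(self, rng):
        for _ in range(10):
            net = random_valid_network(rng)
            assert write_enewick(net).count("#H") == 2 * net.h


class TestRoundTripProperty:
    """Hypothesis-driven round trip: random binary trees with random
    lengths survive write -> parse unchanged."""

    from hypothesis import given, settings, strategies as st

    @given(st.data())
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_random_tree_round_trip(self, data):
        from hypothesis import strategies as st

        from quartetnet import Network

        n = data.draw(st.integers(min_value=3, max_value=9))
        net = Network()
        c = net.add_node()
        for i in range(3):
            net.add_edge(c, net.add_node(f"s{i}"), 1.0)
        for i in range(3, n):
            eid = data.draw(st.sampled_from(sorted(net.edges)))
            m = net.subdivide(eid)
            length = data.draw(st.floats(min_value=0.0, max_value=50.0,
                                         allow_nan=False))
            net.add_edge(m, net.add_node(f"s{i}"), length)
        back = parse_enewick(write_enewick(net))
        assert same_topology(net, back, mode="unrooted")
        assert sorted(filter(None, (e.length for e in back.edges.values()))) \
            == pytest.approx(sorted(filter(None, (e.length
                                                  for e in net.edges.values()))),
                             abs=1e-9)


class TestValidation:
    def test_shared_cycle_edge_reported(self):
        # two hybrids whose parents sit on the same edges: cycles overlap
        bad = ("((a,((b)#H1:::0.6)#H2:::0.6),"
               "(#H1:::0.4,(#H2:::0.4,c)),d);")
        msgs = validate_level1(parse_enewick(bad, validate=False))
        assert msgs  # not a valid level-1 network

    def test_two_cycle_fixture_is_valid(self):
        net = parse_enewick(TWO_CYCLES7)
        assert validate_level1(net) == []
        assert sorted(i.k for i in hybrid_cycles(net)) == [3, 4]


class TestCycleClassification:
    def test_counts_partition_taxa(self, rng):
        for _ in range(20):
            net = random_valid_network(rng, h=1)
            (info,) = hybrid_cycles(net)
            assert sum(info.counts) == len(net.taxa())
            assert info.k >= 2

    @pytest.mark.parametrize("newick, klass", [
        # 4-cycle, hybrid with a single leaf, one parent holding 2 taxa
        ("((((e)#H1:::0.7,(a,b)),(#H1:::0.3,d)),f);", "diamond_good"),
        # 4-cycle, 2-taxon subtree opposite the hybrid node
        ("((((x)#H1:::0.7,p),(#H1:::0.3,q)),(d1,d2));", "diamond_bad_I"),
        # 4-cycle, 2-taxon subtree below the hybrid node
        ("((((a,b))#H1:::0.7,p),(#H1:::0.3,q),r);", "diamond_bad_II"),
        # 3-cycle with every subtree holding >= 2 taxa
        ("(((a1,a2))#H1:::0.7,(#H1:::0.3,(b1,b2)),(c1,c2));",
         "triangle_good"),
        # 3-cycle with a single-taxon subtree at two cycle nodes
        ("(((a1,a2),(b)#H1:::0.7),#H1:::0.3,c);", "triangle_other"),
    ])
    def test_classes_follow_subtree_counts(self, newick, klass):
        net = parse_enewick(newick)
        (info,) = hybrid_cycles(net)
        assert info.klass == klass

    def test_every_hybrid_gets_exactly_one_class(self, rng):
        for _ in range(20):
            net = random_valid_network(rng)
            infos = hybrid_cycles(net)
            assert len(infos) == net.h
            allowed = {"cycle2", "triangle_good", "triangle_other",
                       "diamond_good", "diamond_bad_I", "diamond_bad_II",
                       "k5plus"}
            assert all(i.klass in allowed for i in infos)


class TestRooting:
    def test_descendant_of_hybrid_cannot_be_outgroup(self):
        net = parse_enewick("((A,(B)#H1:1.0::0.7),(#H1:0.5::0.3,C),D);")
        root_with_outgroup(net, "A")  # fine
        with pytest.raises(RootingError):
            root_with_outgroup(net, "B")  # B hangs below the hybrid node

    def test_any_leaf_roots_a_tree(self):
        net = parse_enewick("(A,(B,(C,D)));")
        for taxon in net.taxa():
            rooted = root_with_outgroup(net, taxon)
            assert len(rooted.children[rooted.root]) == 2

    def test_rooted_view_is_acyclic_with_correct_degrees(self, rng):
        for _ in range(10):
            net = random_valid_network(rng)
            rooted = net.rooted()
            order = rooted.topo_order()  # raises if cyclic
            assert set(order) == set(net.nodes()) | {rooted.root}
            for h in net.hybrid_nodes():
                assert len(rooted.parents[h]) == 2


class TestMajorTree:
    def test_tree_is_its_own_major_tree(self):
        net = parse_enewick("(A,(B,(C,D)));")
        assert same_topology(major_tree(net), net)

    def test_single_descendant_fixture_major_tree(self, single_desc_net):
        mt = major_tree(single_desc_net)
        assert mt.h == 0
        expect = parse_enewick("((a,b),(c,d));")
        assert same_topology(mt, expect, mode="unrooted")

    def test_major_tree_has_all_taxa_no_hybrids(self, rng):
        for _ in range(10):
            net = random_valid_network(rng)
            mt = major_tree(net)
            assert mt.h == 0
            assert mt.taxa() == net.taxa()
            n = len(mt.taxa())
            internal = [e for e in mt.internal_edges()]
            assert len(internal) == n - 3  # unrooted binary tree

    def test_restriction_preserves_taxa(self, rng):
        for _ in range(10):
            net = random_valid_network(rng, n=7)
            taxa = net.taxa()[:4]
            sub = induced_subnetwork(net, taxa)
            assert sub.taxa() == sorted(taxa)
            assert sub.h <= net.h


class TestIdentifiabilityConstraints:
    def test_good_diamond_keeps_cycle_parameters_free(self, good_diamond5):
        net, pmap = apply_identifiability_constraints(good_diamond5)
        kinds = [k for k, _ in pmap.entries]
        assert kinds.count("gamma") == 1
        # hybrid-edge lengths are pinned (single descendant) but both cycle
        # tree edges stay free
        assert len(pmap.pinned) == 2
        for eid in pmap.pinned:
            assert net.edges[eid].hybrid

    def test_bad_diamond_reparam_printed_values(self):
        u, v = bad_diamond_reparam(0.2, 1.0, 2.0)
        assert u == pytest.approx(0.2 * (1 - math.exp(-1)), abs=5e-6)
        assert v == pytest.approx(0.8 * (1 - math.exp(-2)), abs=5e-6)
        assert (round(u, 5), round(v, 5)) == (0.12642, 0.69173)

    def test_bad_diamond_I_merges_cycle_tree_edges(self):
        net = parse_enewick(
            "((((x:0.2)#H1:0.0::0.25,p:0.4):1.0,(#H1:0.0::0.75,q:0.6):0.5)"
            ":0.4,(d1:0.3,d2:0.3):0.6);")
        (info,) = hybrid_cycles(net)
        assert info.klass == "diamond_bad_I"
        out, pmap = apply_identifiability_constraints(net)
        pair = [ref for k, ref in pmap.entries if k == "t_pair"]
        assert len(pair) == 1
        e1, e2 = pair[0]
        assert out.edges[e1].length == pytest.approx(out.edges[e2].length)

    def test_bad_diamond_II_pins_edge_below_hybrid(self, bad_diamond2_6):
        out, pmap = apply_identifiability_constraints(bad_diamond2_6)
        (info,) = hybrid_cycles(out)
        below = out.hybrid_child_edge(info.hybrid)
        assert below.id in pmap.pinned
        assert below.length == 0.0

    def test_good_triangle_pins_cycle_tree_edge(self):
        net = parse_enewick(
            "(((a1:1,a2:1):1)#H1:0.2::0.7,(#H1:0.3::0.3,(b1:1,b2:1):1):0.4,"
            "(c1:1,c2:1):1);")
        (info,) = hybrid_cycles(net)
        assert info.klass == "triangle_good"
        out, pmap = apply_identifiability_constraints(net)
        assert info.triangle_tree_edge in pmap.pinned
        assert out.edges[info.triangle_tree_edge].length == 0.0

    def test_unidentifiable_classes_rejected(self):
        triangle = parse_enewick("(((a1,a2),(b)#H1:::0.7),#H1:::0.3,c);")
        with pytest.raises(IdentifiabilityError):
            apply_identifiability_constraints(triangle)
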