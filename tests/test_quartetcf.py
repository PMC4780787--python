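import itertools
import math

import numpy as np
import pytest

from quartetnet import (
    NetworkError,
    canonical_quartet_networks,
    enumerate_histories_cf,
    expected_cf,
    expected_cf_hybrid_single_descendant,
    expected_cf_hybrid_two_descendants,
    expected_cf_tree,
    extract_quartet_subnetwork,
    hybrid_cycles,
    parse_enewick,
    reduce_undetectable_cycle,
    validate_level1,
)
from conftest import random_valid_network


class TestClosedForms:
    @pytest.mark.parametrize("t, expected", [
        (0.0, (1 / 3, 1 / 3, 1 / 3)),               # star: pure ILS
        (math.inf, (1.0, 0.0, 0.0)),                # no ILS
        (math.log(2), (2 / 3, 1 / 6, 1 / 6)),
    ])
    def test_tree_cf(self, t, expected):
        assert expected_cf_tree(t) == pytest.approx(expected, abs=1e-12)

    def test_tree_cf_rejects_negative_length(self):
        with pytest.raises(ValueError):
            expected_cf_tree(-0.1)

    def test_single_descendant_reduces_to_tree_at_gamma_bounds(self):
        assert expected_cf_hybrid_single_descendant(1.0, 2.0, 0.0) == \
            pytest.approx(expected_cf_tree(1.0), abs=1e-15)
        assert expected_cf_hybrid_single_descendant(1.0, 2.0, 1.0) == \
            pytest.approx(expected_cf_tree(3.0), abs=1e-15)

    def test_single_descendant_worked_value(self):
        cf = expected_cf_hybrid_single_descendant(1.0, 2.0, 0.3)
        assert tuple(round(x, 5) for x in cf) == (0.81837, 0.09082, 0.09082)

    def test_two_descendants_no_ils_limit(self):
        cf = expected_cf_hybrid_two_descendants(math.inf, 1, 1, 1, 0.2)
        assert cf == pytest.approx((1.0, 0.0, 0.0), abs=1e-12)

    def test_two_descendants_tree_reduction(self):
        cf = expected_cf_hybrid_two_descendants(0.0, 1.0, 0.5, 7.0, 0.0)
        assert cf == pytest.approx(expected_cf_tree(1.5), abs=1e-15)

    def test_two_descendants_worked_value(self):
        cf = expected_cf_hybrid_two_descendants(1, 1, 1, 1, 0.2)
        assert round(cf[0], 5) == 0.94856


class TestEngineAgainstClosedForms:
    """The enumeration engine is the source of truth; the closed forms must
    agree with it everywhere on a parameter grid."""

    def test_single_descendant_grid(self, single_desc_net):
        net = single_desc_net
        h = net.hybrid_nodes()[0]
        emaj, emin = net.hybrid_parents(h)
        # shared internal exposure: the merged 1.0 internal edge; the extra
        # minor exposure is the 2.0 cycle edge
        leafset = set(net.leaves().values())
        shared = [e for e in net.edges.values() if e.length == 1.0
                  and e.u not in leafset and e.v not in leafset][0]
        extra = [e for e in net.edges.values() if e.length == 2.0][0]
        for t1, t2, g in itertools.product((0.05, 0.4, 1.3), (0.1, 2.5),
                                           (0.0, 0.15, 0.5, 0.9, 1.0)):
            shared.length = t1
            extra.length = t2
            emin.gamma, emaj.gamma = g, 1 - g
            got = expected_cf(net, "abcd").cf
            want = expected_cf_hybrid_single_descendant(t1, t2, g)
            assert got == pytest.approx(want, abs=1e-9)

    def test_two_descendant_grid(self, two_desc_net):
        net = two_desc_net
        h = net.hybrid_nodes()[0]
        emaj, emin = net.hybrid_parents(h)
        below = net.hybrid_child_edge(h)
        leafset = set(net.leaves().values())
        above = [e for e in net.edges.values()
                 if not e.hybrid and e.id != below.id
                 and e.u not in leafset and e.v not in leafset][0]
        for t1, t2, g in itertools.product((0.05, 0.8), (0.3, 1.7),
                                           (0.1, 0.45, 0.8)):
            below.length = t1
            above.length = t2
            emaj.length, emin.length = 0.6, 1.4
            emin.gamma, emaj.gamma = g, 1 - g
            got = expected_cf(net, "abcd").cf
            want = expected_cf_hybrid_two_descendants(t1, t2, 0.6, 1.4, g)
            assert got == pytest.approx(want, abs=1e-9)

    def test_engine_on_tree_equals_tree_formula(self, rng):
        for _ in range(10):
            t = float(rng.uniform(0, 3))
            net = parse_enewick(f"((a:1,b:1):{t},(c:1,d:1):0.0);")
            rooted = net.rooted()
            cf = enumerate_histories_cf(rooted)
            assert cf.cf == pytest.approx(expected_cf_tree(t), abs=1e-12)


class TestNormalizationAndSymmetry:
    def test_cf_sums_to_one(self, rng):
        for _ in range(30):
            net = random_valid_network(rng)
            taxa = net.taxa()[:4]
            if len(taxa) < 4:
                continue
            cf = expected_cf(net, taxa)
            assert sum(cf.cf) == pytest.approx(1.0, abs=1e-9)

    def test_gamma_symmetry(self, two_desc_net):
        """Which hybrid edge is called major is a convention: exchanging the
        two parallel edges' roles while replacing gamma by 1 - gamma leaves
        expected CFs unchanged."""
        net = two_desc_net
        base = expected_cf(net, "abcd").cf
        h = net.hybrid_nodes()[0]
        emaj, emin = net.hybrid_parents(h)
        # the 2-cycle's edges are interchangeable: swap lengths with gammas
        emaj.length, emin.length = emin.length, emaj.length
        emaj.gamma, emin.gamma = 1 - emaj.gamma, 1 - emin.gamma
        emaj.major, emin.major = False, True
        assert base == pytest.approx(expected_cf(net, "abcd").cf, abs=1e-12)

    def test_root_invariance(self, rng):
        """Expected CFs agree across every valid rooting (the semi-directed
        network determines them; the root adds nothing)."""
        from quartetnet.quartetcf import QuartetProgram

        checked = 0
        for _ in range(40):
            net = random_valid_network(rng)
            taxa = net.taxa()
            for quartet in itertools.combinations(taxa, 4):
                ref = None
                for eid in net.valid_root_edges():
                    prog = QuartetProgram(net.rooted(at_edge=eid), quartet)
                    cf = prog.evaluate()
                    if ref is None:
                        ref = cf
                    else:
                        assert cf == pytest.approx(ref, abs=1e-12)
                        checked += 1
                break  # one quartet per network keeps this quick
        assert checked > 50


class TestReductions:
    def test_three_cycle_transformed_length(self, single_desc_net):
        """-log((1-g) e^-t1 + g e^-(t1+t2)) for t1=1, t2=2, g=0.3, matching
        the minor CF 0.09082 via (1/3) e^-t."""
        sub = extract_quartet_subnetwork(single_desc_net, "abcd")
        red = reduce_undetectable_cycle(sub)
        assert red.network.h == 0
        length = sum(e.length for e in red.network.internal_edges())
        assert length == pytest.approx(1.3002938, abs=1e-6)
        assert math.exp(-length) / 3 == pytest.approx(0.09082, abs=5e-6)

    def test_gamma_zero_reduces_to_major_length(self):
        net = parse_enewick(
            "((a:1,b:1):0.5,((#H1:0.1::0,d:1):2,(c:1)#H1:0.1::1):0.5);")
        red = reduce_undetectable_cycle(extract_quartet_subnetwork(net, "abcd"))
        length = sum(e.length for e in red.network.internal_edges())
        assert length == pytest.approx(1.0, abs=1e-9)

    def test_two_cycle_reduction_preserves_cfs(self, two_desc_net):
        before = expected_cf(two_desc_net, "abcd").cf
        red = reduce_undetectable_cycle(
            extract_quartet_subnetwork(two_desc_net, "abcd"))
        assert red.network.h == 0
        after = expected_cf(red.network, "abcd").cf
        assert after == pytest.approx(before, abs=1e-9)

    def test_three_cycle_reduction_preserves_cfs_on_grid(self,
                                                         single_desc_net):
        net = single_desc_net
        h = net.hybrid_nodes()[0]
        emaj, emin = net.hybrid_parents(h)
        extra = [e for e in net.edges.values() if e.length == 2.0][0]
        for t2, g in itertools.product((0.2, 1.0, 3.0), (0.1, 0.5, 0.95)):
            extra.length = t2
            emin.gamma, emaj.gamma = g, 1 - g
            before = expected_cf(net, "abcd").cf
            red = reduce_undetectable_cycle(
                extract_quartet_subnetwork(net, "abcd"))
            after = expected_cf(red.network, "abcd").cf
            assert after == pytest.approx(before, abs=1e-9)

    def test_extraction_preserves_expected_cfs(self, rng):
        """CFs computed on the full network equal CFs of the extracted
        4-taxon subnetwork."""
        for _ in range(15):
            net = random_valid_network(rng, n=7)
            taxa = sorted(net.taxa())[:4]
            full = expected_cf(net, taxa).cf
            sub = extract_quartet_subnetwork(net, taxa).network
            assert expected_cf(sub, taxa).cf == pytest.approx(full, abs=1e-9)

    def test_irreducible_raises(self, good_diamond5):
        sub = extract_quartet_subnetwork(good_diamond5,
                                         ["a", "d", "e", "f"])
        if sub.network.h == 0:
            pytest.skip("restriction dropped the reticulation")
        with pytest.raises(NetworkError):
            reduce_undetectable_cycle(sub)


class TestCanonicalQuartetNetworks:
    def test_exactly_five_up_to_relabeling(self):
        nets = canonical_quartet_networks()
        assert len(nets) == 5
        for net in nets:
            assert validate_level1(net) == []
            assert net.h == 1
        ks = sorted(hybrid_cycles(n)[0].k for n in nets)
        assert ks == [2, 2, 3, 3, 4]

    def test_merged_two_cycles_are_tree_equivalent(self):
        """Both orientations of a single-cut 2-cycle produce CFs in the same
        tree family (equal minor CFs), which is what licenses counting them
        as one network."""
        for hybrid_low in (False, True):
            net = parse_enewick(
                "(a:1,((b:1,(c:1,d:1):0.4):0.3,x:1):0.2);", validate=False)
            # place a 2-cycle on a's external edge, hybrid at either end
            eid = net._adj[net.leaves()["a"]][0]
            m1 = net.subdivide(eid)
            seg = net.incident(m1)[0]
            m2 = net.subdivide(seg.id)
            pair = [e for e in net.incident(m1) if e.other(m1) == m2][0]
            h, o = (m1, m2) if hybrid_low else (m2, m1)
            pair.hybrid, pair.gamma, pair.major = True, 0.7, True
            if pair.v != h:
                pair.u, pair.v = pair.v, pair.u
            net.add_edge(o, h, 0.9, hybrid=True, gamma=0.3, major=False)
            net.remove_node(net.leaves()["x"])
            net.cleanup()
            assert validate_level1(net) == []
            cf = expected_cf(net, "abcd").cf
            assert cf[1] == pytest.approx(cf[2], abs=1e-12)


def build_diamond(hybrid_at: int, two_d: bool, gamma: float,
                  lengths: dict[str, float]):
    """A 4-cycle network with pendant subtrees (x, d*, b, c) in cyclic
    order; the hybrid node sits at cycle position ``hybrid_at``.  With
    ``two_d`` the d-pendant is the cherry (d1, d2).  Cycle tree edges get
    lengths from ``lengths`` keyed '01', '12', '23', '03'; hybrid edges get
    length 0."""
    from quartetnet import Network

    net = Network()
    cyc = [net.add_node() for _ in range(4)]
    pendants = []
    for i, lab in enumerate(("x", "d", "b", "c")):
        if lab == "d" and two_d:
            mid = net.add_node()
            net.add_edge(cyc[i], mid, 0.3)
            for nm in ("d1", "d2"):
                net.add_edge(mid, net.add_node(nm), 0.4)
        else:
            leaf = net.add_node("d1" if lab == "d" else lab)
            net.add_edge(cyc[i], leaf, 0.4)
        pendants.append(lab)
    for (i, j) in ((0, 1), (1, 2), (2, 3), (0, 3)):
        hybrid = hybrid_at in (i, j) and True or False
        key = f"{i}{j}"
        if hybrid_at in (i, j):
            other = j if hybrid_at == i else i
            net.add_edge(cyc[other], cyc[hybrid_at], 0.0, hybrid=True,
                         gamma=None, major=False)
        else:
            net.add_edge(cyc[i], cyc[j], lengths[key])
    es = [e for e in net.edges.values() if e.hybrid]
    es[0].gamma, es[0].major = gamma, gamma >= 0.5
    es[1].gamma, es[1].major = 1 - gamma, gamma < 0.5
    return net


def _fit_cf_distance(target_net, candidate_net, quartets):
    """Least worst-case CF distance achievable by tuning the candidate's
    free parameters (its topology stays fixed)."""
    from scipy.optimize import minimize

    from quartetnet import CFEvaluator, apply_identifiability_constraints

    target = np.array([expected_cf(target_net, q).cf for q in quartets])
    cand, pmap = apply_identifiability_constraints(candidate_net)
    ev = CFEvaluator(cand, quartets)
    bounds = pmap.bounds()

    def obj(theta):
        pmap.set_vector(cand, np.clip(theta, [b[0] for b in bounds],
                                      [b[1] for b in bounds]))
        got = np.array(ev.evaluate())
        return float(((got - target) ** 2).sum())

    best = np.inf
    for seed in range(4):
        rng = np.random.default_rng(seed)
        x0 = np.array([rng.uniform(*b) for b in bounds])
        r = minimize(obj, x0, method="Nelder-Mead", bounds=bounds,
                     options={"xatol": 1e-9, "fatol": 1e-14,
                              "maxfev": 20000, "adaptive": True})
        best = min(best, r.fun)
    return math.sqrt(best)


class TestDetectability:
    """On 4 taxa a diamond's hybrid position is not identifiable: the two
    placements span the same CF family.  A fifth taxon below the cherry
    pendant separates them (here: hybrid adjacent to the d-subtree = good
    diamond, hybrid opposite it = bad diamond I)."""

    LEN = {"01": 0.7, "12": 0.5, "23": 0.9, "03": 0.6}

    def test_four_taxon_pair_not_distinguishable(self):
        n_good = build_diamond(0, False, 0.3, self.LEN)   # hybrid next to d
        n_bad = build_diamond(3, False, 0.3, self.LEN)    # hybrid opposite d
        quartets = [tuple(sorted(n_good.taxa()))]
        d = _fit_cf_distance(n_good, n_bad, quartets)
        assert d < 1e-6

    def test_fifth_taxon_separates_the_pair(self):
        n_good = build_diamond(0, True, 0.3, self.LEN)
        n_bad = build_diamond(3, True, 0.3, self.LEN)
        from quartetnet import hybrid_cycles as hc

        assert hc(n_good)[0].klass == "diamond_good"
        assert hc(n_bad)[0].klass == "diamond_bad_I"
        quartets = list(itertools.combinations(sorted(n_good.taxa()), 4))
        d = _fit_cf_distance(n_good, n_bad, quartets)
        assert d > 1e-3
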