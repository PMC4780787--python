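"""Expected quartet concordance factors under the coalescent with hybridization.

For four sampled taxa a < b < c < d the three unrooted quartet topologies
are listed in the fixed order q1 = ab|cd, q2 = ac|bd, q3 = ad|bc.  On a
species tree with internal branch length t (coalescent units) the expected
CFs are (1 - 2/3 e^-t, 1/3 e^-t, 1/3 e^-t).  On a level-1 network each
lineage passing a hybrid node independently follows the minor parent edge
with probability gamma, so expected CFs are mixtures of tree CFs over the
lineages' choices, with extra coalescent opportunities inside reticulation
cycles.

The general solver here (`QuartetProgram` / `enumerate_histories_cf`) makes
no case distinctions: it enumerates each lineage's possible leaf-to-root
paths, and for every joint choice runs an exact dynamic program over edge
co-occupancy.  Within an edge of length t carrying j uncoalesced lineages,
some pair coalesces with probability 1 - exp(-C(j,2) t), the first pair
uniform among the C(j,2); the first coalescence among the four sampled
lineages determines the quartet topology.  The closed forms printed for the
single-descendant and two-descendant hybrid cases are kept as fast paths and
checked against this engine in the test suite.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .network import (
    Edge,
    Network,
    NetworkError,
    RootedNetwork,
    induced_subnetwork,
    same_topology,
)

__all__ = [
    "QuartetCF",
    "QuartetSubnetwork",
    "expected_cf_tree",
    "expected_cf_hybrid_single_descendant",
    "expected_cf_hybrid_two_descendants",
    "enumerate_histories_cf",
    "expected_cf",
    "reduce_undetectable_cycle",
    "extract_quartet_subnetwork",
    "canonical_quartet_networks",
    "CFEvaluator",
]

CF_SUM_TOL = 1e-9

# first coalescing pair of taxon indices (sorted taxa 0..3) -> split index
_PAIR_TO_SPLIT = {
    frozenset((0, 1)): 0, frozenset((2, 3)): 0,
    frozenset((0, 2)): 1, frozenset((1, 3)): 1,
    frozenset((0, 3)): 2, frozenset((1, 2)): 2,
}


@dataclass(frozen=True)
class QuartetCF:
    """Expected (or observed) quartet CFs for one sorted 4-taxon set."""

    taxa: tuple[str, str, str, str]
    cf: tuple[float, float, float]

    def __post_init__(self):
        if list(self.taxa) != sorted(self.taxa):
            raise ValueError("taxa must be sorted")
        if any(x < -CF_SUM_TOL or x > 1 + CF_SUM_TOL for x in self.cf):
            raise ValueError(f"CF outside [0, 1]: {self.cf}")
        if abs(sum(self.cf) - 1.0) > CF_SUM_TOL:
            raise ValueError(f"CFs sum to {sum(self.cf)}, expected 1")


@dataclass
class QuartetSubnetwork:
    """A 4-taxon restriction together with its reduction log."""

    network: Network
    log: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# closed forms
# ---------------------------------------------------------------------------

def expected_cf_tree(t: float) -> tuple[float, float, float]:
    """Species-tree CFs for internal branch length t: the major split gets
    1 - 2/3 e^-t, the two minor splits 1/3 e^-t each."""
    if t < 0:
        raise ValueError(f"negative branch length {t}")
    m = math.exp(-t) / 3.0
    return (1.0 - 2.0 * m, m, m)


def expected_cf_hybrid_single_descendant(t1: float, t2: float, gamma: float
                                         ) -> tuple[float, float, float]:
    """One taxon below the hybrid node: the two parental routes display the
    same quartet topology with internal lengths t1 and t1 + t2, so
    CF_major = (1-g)(1 - 2/3 e^-t1) + g (1 - 2/3 e^-(t1+t2))."""
    if t1 < 0 or t2 < 0:
        raise ValueError("negative branch length")
    if not 0.0 <= gamma <= 1.0:
        raise ValueError(f"gamma {gamma} outside [0, 1]")
    minor = (1.0 - gamma) * math.exp(-t1) / 3.0 + gamma * math.exp(-t1 - t2) / 3.0
    return (1.0 - 2.0 * minor, minor, minor)


def expected_cf_hybrid_two_descendants(t1: float, t2: float, t3: float,
                                       t4: float, gamma: float
                                       ) -> tuple[float, float, float]:
    """A cherry below the hybrid node (lengths: t1 below the hybrid, t3/t4
    the major/minor hybrid edges, t2 above their reunion):

    CF_major = 1 - e^-t1 + e^-t1 [ (1-g)^2 (1 - 2/3 e^-(t2+t3))
               + 2 g (1-g) (1 - 2/3 e^-t2) + g^2 (1 - 2/3 e^-(t4+t2)) ]

    and the two minor CFs share the remainder equally.
    """
    if min(t1, t2, t3, t4) < 0:
        raise ValueError("negative branch length")
    if not 0.0 <= gamma <= 1.0:
        raise ValueError(f"gamma {gamma} outside [0, 1]")
    g = gamma
    e1 = math.exp(-t1)
    major = 1.0 - e1 + e1 * (
        (1.0 - g) ** 2 * (1.0 - 2.0 / 3.0 * math.exp(-t2 - t3))
        + 2.0 * g * (1.0 - g) * (1.0 - 2.0 / 3.0 * math.exp(-t2))
        + g ** 2 * (1.0 - 2.0 / 3.0 * math.exp(-t4 - t2)))
    minor = (1.0 - major) / 2.0
    return (major, minor, minor)


# ---------------------------------------------------------------------------
# the coalescent-history enumeration engine
# ---------------------------------------------------------------------------

class QuartetProgram:
    """Pre-compiled exact CF computation for one 4-taxon set.

    Compilation fixes everything that depends on the topology alone (lineage
    paths, hybrid choices, edge co-occupancy); evaluation reads the current
    branch lengths and gammas, so the same program can be re-evaluated as an
    optimizer moves the continuous parameters.
    """

    def __init__(self, rooted: RootedNetwork, taxa: Sequence[str]):
        self.taxa = tuple(sorted(taxa))
        if len(set(self.taxa)) != 4:
            raise ValueError("need exactly 4 distinct taxa")
        net = rooted.net
        leaves = net.leaves()
        for t in self.taxa:
            if t not in leaves:
                raise NetworkError(f"taxon {t!r} not in leaf set")
        root_src = net.edges[rooted.root_edge]
        leafnodes = set(leaves.values())
        # a pendant root edge with missing length is equivalent, by root
        # invariance, to rooting at its internal endpoint: zero exposure
        root_ext = root_src.u in leafnodes or root_src.v in leafnodes

        def length_ref(e: Edge):
            # synthetic root halves refer back to the split edge
            if e.id < 0:
                if root_src.length is None and root_ext:
                    return (None, 0.0)
                return (root_src, 0.5)
            return (e, 1.0)

        def gamma_ref(e: Edge):
            return root_src if e.id < 0 else e

        topo_index = {v: i for i, v in enumerate(rooted.topo_order())}

        # every leaf-to-root path, as (edge, child-end node) pairs
        paths: list[list[list[tuple[Edge, int]]]] = []
        for t in self.taxa:
            acc: list[list[tuple[Edge, int]]] = []

            def climb(v: int, so_far: list[tuple[Edge, int]]):
                ps = rooted.parents.get(v, [])
                if not ps:
                    acc.append(so_far)
                    return
                for (_p, e) in ps:
                    climb(_p, so_far + [(e, v)])

            climb(leaves[t], [])
            paths.append(acc)

        self.combos = []
        for choice in itertools.product(*paths):
            grefs = []
            occupancy: dict[int, tuple[Edge, int, set[int]]] = {}
            for ti, path in enumerate(choice):
                for e, child in path:
                    if e.hybrid:
                        grefs.append(gamma_ref(e))
                    key = id(e)
                    if key not in occupancy:
                        occupancy[key] = (e, child, set())
                    occupancy[key][2].add(ti)
            steps = []
            shared = [(e, ch, occ) for (e, ch, occ) in occupancy.values()
                      if len(occ) >= 2]
            shared.sort(key=lambda item: topo_index[item[1]])
            for e, _ch, occ in shared:
                j = len(occ)
                npairs = j * (j - 1) // 2
                qidx = [_PAIR_TO_SPLIT[frozenset(p)]
                        for p in itertools.combinations(sorted(occ), 2)]
                lref = length_ref(e)
                if steps and steps[-1][1] == occ:
                    steps[-1][0].append(lref)  # same lineages: pool lengths
                else:
                    steps.append(([lref], occ, npairs, qidx))
            # deduplicate gamma refs per path position (a ref can repeat when
            # two taxa share a hybrid edge on their paths: each contributes)
            self.combos.append((grefs, steps))

    def evaluate(self) -> tuple[float, float, float]:
        q = [0.0, 0.0, 0.0]
        for grefs, steps in self.combos:
            w = 1.0
            for e in grefs:
                if e.gamma is None:
                    raise NetworkError(f"gamma unset on hybrid edge {e.id}")
                w *= e.gamma
            if w == 0.0:
                continue
            alive = w
            for lrefs, _occ, npairs, qidx in steps:
                t = 0.0
                for e, f in lrefs:
                    if e is None:
                        continue
                    if e.length is None:
                        raise NetworkError(
                            f"internal edge {e.id} has no length set")
                    t += f * e.length
                pno = math.exp(-npairs * t)
                inc = alive * (1.0 - pno) / npairs
                for k in qidx:
                    q[k] += inc
                alive *= pno
            # all four lineages reach the root uncoalesced: uniform pairs
            for k in range(3):
                q[k] += alive / 3.0
        s = q[0] + q[1] + q[2]
        return (q[0] / s, q[1] / s, q[2] / s)


def enumerate_histories_cf(rooted: RootedNetwork,
                           taxa: Optional[Sequence[str]] = None) -> QuartetCF:
    """Exact expected CFs on a rooted 4-taxon network by history enumeration."""
    if taxa is None:
        taxa = sorted(rooted.net.leaves())
    prog = QuartetProgram(rooted, taxa)
    return QuartetCF(prog.taxa, prog.evaluate())


class CFEvaluator:
    """Compiled CF programs for many 4-taxon sets on one network topology.

    Built once per candidate topology; re-evaluated cheaply as branch lengths
    and inheritance probabilities change in place.
    """

    def __init__(self, net: Network, quartets: Iterable[Sequence[str]]):
        self.net = net
        self.rooted = net.rooted()
        self.quartets = [tuple(sorted(q)) for q in quartets]
        self.programs = [QuartetProgram(self.rooted, q) for q in self.quartets]

    def evaluate(self) -> list[tuple[float, float, float]]:
        return [p.evaluate() for p in self.programs]


def expected_cf_table(net: Network, sets=None, ngenes: float = 1.0):
    """A CF table holding the exact expected CFs of a network (useful as
    noise-free input for optimization and search self-consistency checks)."""
    from .cftables import QuartetCFRecord, QuartetCFTable, quartet_sets

    if sets is None:
        sets = quartet_sets(net.taxa(), "all")
    ev = CFEvaluator(net, sets)
    recs = [QuartetCFRecord(q, cf, ngenes=ngenes)
            for q, cf in zip(ev.quartets, ev.evaluate())]
    return QuartetCFTable(recs)


def expected_cf(net: Network, taxa: Sequence[str]) -> QuartetCF:
    """Expected CFs of any level-1 network restricted to 4 of its taxa.

    Root-placement invariant: any valid rooting yields the same values.
    """
    rooted = net.rooted()
    prog = QuartetProgram(rooted, taxa)
    return QuartetCF(prog.taxa, prog.evaluate())


# ---------------------------------------------------------------------------
# 4-taxon extraction and reductions
# ---------------------------------------------------------------------------

def extract_quartet_subnetwork(net: Network, taxa: Sequence[str]
                               ) -> QuartetSubnetwork:
    """Restrict to 4 taxa, dropping reticulations that lose their descendants."""
    taxa = sorted(taxa)
    if len(set(taxa)) != 4:
        raise ValueError("need exactly 4 distinct taxa")
    sub = induced_subnetwork(net, taxa)
    log = [f"restricted to {{{', '.join(taxa)}}}; h = {sub.h}"]
    return QuartetSubnetwork(sub, log)


def _quartet_internal_length(tree: Network) -> float:
    """Total internal-path length of a 4-taxon tree (0 for a star)."""
    leaves = set(tree.leaves().values())
    total = 0.0
    for e in tree.edges.values():
        if e.u in leaves or e.v in leaves:
            continue
        if e.length is None:
            raise NetworkError(f"internal edge {e.id} has no length")
        total += e.length
    return total


def _taxa_below_hybrid(net: Network, h: int) -> int:
    child = net.hybrid_child_edge(h)
    seen = {h}
    stack = [child.other(h)]
    count = 0
    while stack:
        x = stack.pop()
        if x in seen:
            continue
        seen.add(x)
        if net.names[x] is not None:
            count += 1
        for e in net.incident(x):
            stack.append(e.other(x))
    return count


def reduce_undetectable_cycle(subnet: QuartetSubnetwork) -> QuartetSubnetwork:
    """Remove one reducible reticulation, preserving expected quartet CFs.

    Two exact local rules are implemented:

    * 2-cycle (parallel hybrid edges, lengths ta major / tb minor) traversed
      by at most two sampled lineages: replaced by a single tree edge whose
      no-coalescence probability matches the mixture over the independent
      parental choices.
    * 3-cycle whose hybrid node has a single sampled descendant: conditional
      on that lineage's parental choice the network is a displayed tree, so
      the mixture of the two same-topology displayed trees collapses to one
      tree with internal length -log(g_u e^-Lu + g_v e^-Lv) — for the
      single-descendant case this is the printed t3 = -log((1-g)e^-t1 +
      g e^-(t1+t2)) transformation.

    Raises :class:`NetworkError` when no reticulation is reducible by these
    rules (such quartet networks are handled by the enumeration engine).
    """
    net = subnet.network
    for h in net.hybrid_nodes():
        emaj, emin = net.hybrid_parents(h)
        if emaj.gamma is None:
            raise NetworkError(f"gamma unset at hybrid {h}")
        o1, o2 = emaj.other(h), emin.other(h)
        nb = _taxa_below_hybrid(net, h)
        if o1 == o2:  # 2-cycle
            if nb > 2:
                continue
            ta, tb = emaj.length, emin.length
            if ta is None or tb is None:
                raise NetworkError("hybrid edge lengths unset")
            g = emin.gamma
            if nb <= 1:
                surv = (1.0 - g) * math.exp(-ta) + g * math.exp(-tb)
            else:
                surv = ((1.0 - g) ** 2 * math.exp(-ta)
                        + g ** 2 * math.exp(-tb) + 2.0 * g * (1.0 - g))
            out = net.copy()
            teq = -math.log(surv) if surv > 0 else float("inf")
            out.remove_edge(emaj.id)
            out.remove_edge(emin.id)
            out.add_edge(o1, h, teq)
            out.cleanup()
            return QuartetSubnetwork(out, subnet.log + [
                f"2-cycle at hybrid {h} ({nb} lineage(s)) -> edge {teq:.6g}"])
        # 3-cycle with one descendant: mixture of two displayed trees
        cyc_tree = [e for e in net.incident(o1)
                    if e.other(o1) == o2 and not e.hybrid]
        if cyc_tree and nb == 1 and net.h == 1:
            trees = []
            for drop in (emin, emaj):
                t = net.copy()
                t.remove_edge(drop.id)
                keep = [e for e in t.incident(h) if e.hybrid and e.v == h][0]
                keep.hybrid, keep.gamma, keep.major = False, None, True
                t.cleanup()
                trees.append(t)
            tmaj, tmin = trees
            if not same_topology(tmaj, tmin, mode="unrooted"):
                raise NetworkError("displayed trees differ in topology; "
                                   "3-cycle not reducible")
            lu = _quartet_internal_length(tmaj)
            lv = _quartet_internal_length(tmin)
            g = emin.gamma
            mix = (1.0 - g) * math.exp(-lu) + g * math.exp(-lv)
            leq = -math.log(mix) if mix > 0 else float("inf")
            out = tmaj.copy()
            internals = [e for e in out.internal_edges()]
            # put the whole transformed length on one internal edge
            for i, e in enumerate(internals):
                e.length = leq if i == 0 else 0.0
            return QuartetSubnetwork(out, subnet.log + [
                f"3-cycle at hybrid {h} -> tree, internal length {leq:.6g}"])
    raise NetworkError("no reticulation reducible by the local rules")


# ---------------------------------------------------------------------------
# canonical 4-taxon networks with one hybridization
# ---------------------------------------------------------------------------

def _quartet_tree(pairing: tuple[tuple[str, str], tuple[str, str]],
                  length: float = 1.0) -> Network:
    net = Network()
    x = net.add_node()
    y = net.add_node()
    net.add_edge(x, y, length)
    for side, pair in zip((x, y), pairing):
        for name in pair:
            leaf = net.add_node(name)
            net.add_edge(side, leaf, 1.0)
    return net


def _canonicalize_2cycle(net: Network) -> Network:
    """Place a 2-cycle's hybrid node at the end with the smaller subtree.

    Which end of a pair of parallel hybrid edges carries the hybrid node is
    statistically silent: a 2-cycle is undetectable, and either orientation
    is CF-equivalent to the same tree family for every parameter value.  The
    enumeration therefore counts the two orientations as one network.
    """
    from .network import hybrid_cycles

    infos = hybrid_cycles(net)
    if len(infos) != 1 or infos[0].k != 2:
        return net
    info = infos[0]
    if info.counts[1] <= info.counts[0]:  # hybrid side already smaller
        return net
    out = net.copy()
    o, h = info.cycle_nodes
    for eid in info.cycle_edges:
        e = out.edges[eid]
        e.u, e.v = h, o  # reverse both parallel edges: hybrid moves to o
    return out


def canonical_quartet_networks(gamma: float = 0.3) -> list[Network]:
    """All semi-directed 4-taxon level-1 networks with h = 1, up to tip
    relabeling: brute force over hybrid placements on the three quartet
    trees (cycle sizes k in {2, 3, 4}), validated and deduplicated by
    semi-directed isomorphism of the unlabeled shapes (with 2-cycles
    canonicalized first, since their hybrid-node position is undetectable).
    """
    from .network import validate_level1

    candidates: list[Network] = []
    pairings = [(("a", "b"), ("c", "d")),
                (("a", "c"), ("b", "d")),
                (("a", "d"), ("b", "c"))]

    def consider(net: Network) -> None:
        if validate_level1(net):
            return
        if not net.has_valid_root():
            return
        net = _canonicalize_2cycle(net)
        for kept in candidates:
            if same_topology(kept, net, mode="semi", labeled=False):
                return
        candidates.append(net)

    for pairing in pairings:
        base = _quartet_tree(pairing)
        eids = sorted(base.edges)
        # 2-cycles: both subdivision nodes on one edge, either one hybrid
        for eid in eids:
            for hybrid_low in (False, True):
                net = base.copy()
                m1 = net.subdivide(eid)
                seg = [e for e in net.incident(m1)][0]
                m2 = net.subdivide(seg.id)
                pair_eid = [e for e in net.incident(m1)
                            if e.other(m1) == m2][0].id
                h, o = (m1, m2) if hybrid_low else (m2, m1)
                e_par = net.edges[pair_eid]
                e_par.hybrid = True
                e_par.gamma = 1.0 - gamma
                e_par.major = True
                if e_par.v != h:
                    e_par.u, e_par.v = e_par.v, e_par.u
                net.add_edge(o, h, 1.0, hybrid=True, gamma=gamma, major=False)
                consider(net)
        # k >= 3: origin and target on distinct edges, either target piece
        # becoming the partner hybrid edge
        for eo in eids:
            for et in eids:
                if eo == et:
                    continue
                for which in (0, 1):
                    net = base.copy()
                    mo = net.subdivide(eo)
                    mt = net.subdivide(et)
                    pieces = [e for e in net.incident(mt)]
                    part = pieces[which]
                    part.hybrid = True
                    part.gamma = 1.0 - gamma
                    part.major = True
                    if part.v != mt:
                        part.u, part.v = part.v, part.u
                    net.add_edge(mo, mt, 1.0, hybrid=True,
                                 gamma=gamma, major=False)
                    consider(net)
    return candidates
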