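"""Bootstrap summaries, model selection for h, and network comparison.

Bootstrap networks are estimated from resampled CF tables (each CF drawn
uniformly from its 95% credibility interval, renormalized).  Support for the
major tree is the percentage of bootstrap major trees containing an
equivalent edge (same bipartition); support for each reticulation is the
percentage of bootstrap networks containing an equivalent minor hybrid edge,
two edges being equivalent when they are of the same type and define the
same hardwired clusters.  The number of hybridizations is chosen by a slope
heuristic on the negative log-pseudolikelihood profile: the score drops
sharply up to the best h and roughly linearly afterwards, so the chosen h is
the breakpoint of the best two-segment piecewise-linear fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .cftables import QuartetCFTable, resample_cf_table
from .network import Network, major_tree
from .search import SearchConfig, SearchResult, snaq_search

__all__ = [
    "BootstrapSummary",
    "bootstrap_networks",
    "summarize_bootstrap",
    "slope_heuristic",
    "robinson_foulds",
    "hardwired_cluster_distance",
    "hybridization_match",
]


# ---------------------------------------------------------------------------
# tree and network distances
# ---------------------------------------------------------------------------

def _bipartitions(tree: Network) -> set[frozenset[str]]:
    """Nontrivial splits of an unrooted tree, each as the side not
    containing the alphabetically first taxon."""
    taxa = tree.taxa()
    if not taxa:
        return set()
    anchor = taxa[0]
    leafset = set(tree.leaves().values())
    out: set[frozenset[str]] = set()
    for e in tree.edges.values():
        if e.u in leafset or e.v in leafset:
            continue
        side = _taxa_beyond(tree, e, e.u)
        if anchor in side:
            side = frozenset(taxa) - side
        if 2 <= len(side) <= len(taxa) - 2:
            out.add(frozenset(side))
    return out


def _taxa_beyond(net: Network, edge, endpoint: int) -> frozenset[str]:
    seen = {endpoint}
    out = set()
    stack = [endpoint]
    while stack:
        v = stack.pop()
        nm = net.names.get(v)
        if nm is not None:
            out.add(nm)
        for e in net.incident(v):
            if e.id == edge.id:
                continue
            w = e.other(v)
            if w not in seen:
                seen.add(w)
                stack.append(w)
    return frozenset(out)


def robinson_foulds(tree1: Network, tree2: Network) -> int:
    """Symmetric difference of the nontrivial bipartitions of two unrooted
    trees on the same taxa."""
    if tree1.taxa() != tree2.taxa():
        raise ValueError("trees are on different taxon sets")
    if tree1.h or tree2.h:
        raise ValueError("Robinson-Foulds is defined here for trees (h = 0)")
    return len(_bipartitions(tree1) ^ _bipartitions(tree2))


def _hardwired_clusters(net: Network, outgroup: str) -> list[frozenset[str]]:
    """Multiset of hardwired clusters (taxa below each edge) of the network
    rooted at the outgroup."""
    rooted = net.rooted(outgroup=outgroup)
    out = []
    for v, kids in rooted.children.items():
        for (c, _e) in kids:
            cl = rooted.cluster(c)
            if cl:
                out.append(cl)
    return out


def hardwired_cluster_distance(net1: Network, net2: Network,
                               outgroup: str) -> int:
    """Symmetric difference of the hardwired-cluster multisets of two
    networks rooted at the same outgroup."""
    if net1.taxa() != net2.taxa():
        raise ValueError("networks are on different taxon sets")
    from collections import Counter

    c1 = Counter(_hardwired_clusters(net1, outgroup))
    c2 = Counter(_hardwired_clusters(net2, outgroup))
    return sum(((c1 - c2) + (c2 - c1)).values())


def _reduce_to_hybrid(net: Network, which: int) -> Network:
    """Keep only the ``which``-th reticulation (by sorted hybrid node id),
    suppressing the minor hybrid edge of every other one."""
    out = net.copy()
    while True:
        hybrids = out.hybrid_nodes()
        if len(hybrids) <= 1:
            return out
        keep = sorted(net.hybrid_nodes())[which]
        victim = next(h for h in hybrids if h != keep)
        _emaj, emin = out.hybrid_parents(victim)
        out.remove_edge(emin.id)
        for e in out.incident(victim):
            if e.hybrid and e.v == victim:
                e.hybrid, e.gamma, e.major = False, None, True
        out.cleanup()


def hybridization_match(true_net: Network, est_net: Network,
                        which_hybrid: int, outgroup: str) -> bool:
    """Whether one estimated reticulation matches the true one: all other
    reticulations are removed by suppressing their minor hybrid edges, both
    networks are rooted at the known outgroup, and the reduced networks must
    have hardwired cluster distance 0 (same donor edge into the same
    recipient edge of the major tree)."""
    a = _reduce_to_hybrid(true_net, which_hybrid)
    b = _reduce_to_hybrid(est_net, which_hybrid)
    return hardwired_cluster_distance(a, b, outgroup) == 0


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def bootstrap_networks(table: QuartetCFTable, start_tree: Network,
                       config: SearchConfig, B: int
                       ) -> list[SearchResult]:
    """B network estimations, each from a CF table resampled within its
    credibility intervals; replicate seeds derive from the config seed."""
    if B < 1:
        raise ValueError("need at least one bootstrap replicate")
    if not table.has_bounds():
        raise ValueError("bootstrap requires credibility bounds on all records")
    seed_seq = np.random.SeedSequence(config.seed)
    out = []
    for i, child in enumerate(seed_seq.spawn(B)):
        s1, s2 = (int(x % (2 ** 31)) for x in child.generate_state(2))
        boot = resample_cf_table(table, seed=s1)
        cfg = SearchConfig(**{**config.__dict__, "seed": s2})
        out.append(snaq_search(boot, start_tree, cfg))
    return out


@dataclass
class BootstrapSummary:
    """Support percentages over bootstrap networks.

    ``tree_edge_support`` maps each nontrivial bipartition of the reference
    major tree to the percentage of bootstrap major trees containing it.
    ``hybrid_support`` maps each reference reticulation (minor hybrid edge,
    keyed by its (donor cluster, recipient cluster) pair) to its support;
    ``alternative_placements`` lists every minor-hybrid-edge placement seen
    in the bootstrap networks with its frequency.
    """

    tree_edge_support: dict[frozenset, float] = field(default_factory=dict)
    hybrid_support: dict[tuple, float] = field(default_factory=dict)
    alternative_placements: dict[tuple, float] = field(default_factory=dict)


def _minor_edge_keys(net: Network, outgroup: str) -> list[tuple]:
    """(donor cluster, recipient cluster) of each minor hybrid edge under a
    rooting at the outgroup."""
    rooted = net.rooted(outgroup=outgroup)
    keys = []
    for h in net.hybrid_nodes():
        _emaj, emin = net.hybrid_parents(h)
        donor = rooted.cluster(emin.u)
        recipient = rooted.cluster(emin.v)
        keys.append((donor, recipient))
    return keys


def summarize_bootstrap(nets: Sequence[Network], reference: Network,
                        outgroup: Optional[str] = None) -> BootstrapSummary:
    """Edge and reticulation supports of a reference network across
    bootstrap networks (all on the same taxa)."""
    taxa = reference.taxa()
    for n in nets:
        if n.taxa() != taxa:
            raise ValueError("bootstrap network on different taxon set")
    if outgroup is None:
        outgroup = taxa[0]
    B = len(nets)
    ref_major = major_tree(reference)
    ref_splits = _bipartitions(ref_major)
    boot_splits = [_bipartitions(major_tree(n)) for n in nets]
    tree_support = {s: 100.0 * sum(s in bs for bs in boot_splits) / B
                    for s in ref_splits}

    ref_keys = _minor_edge_keys(reference, outgroup)
    seen: dict[tuple, int] = {}
    for n in nets:
        for key in _minor_edge_keys(n, outgroup):
            seen[key] = seen.get(key, 0) + 1
    hybrid_support = {k: 100.0 * seen.get(k, 0) / B for k in ref_keys}
    alternatives = {k: 100.0 * c / B for k, c in sorted(
        seen.items(), key=lambda kv: -kv[1])}
    return BootstrapSummary(tree_support, hybrid_support, alternatives)


# ---------------------------------------------------------------------------
# slope heuristic for the number of hybridizations
# ---------------------------------------------------------------------------

def slope_heuristic(scores: Sequence[float]) -> int:
    """Choose h from negative log-pseudolikelihood scores at h = 0..h_max.

    Fits every two-segment piecewise-linear model (segments meeting at a
    candidate breakpoint h = b, each segment needing at least two points,
    b = 0 meaning a single line) and returns the breakpoint with the least
    total squared error; ties, including exactly linear profiles, resolve to
    the smallest h.  Scores should be non-increasing; violations are
    tolerated.
    """
    y = np.asarray(scores, dtype=float)
    H = len(y) - 1
    if H < 2:
        raise ValueError("need scores for at least three h values")
    x = np.arange(len(y), dtype=float)

    def sse(i, j):  # fit y[i:j+1] by a line
        if j - i < 1:
            return 0.0
        xs, ys = x[i:j + 1], y[i:j + 1]
        A = np.vstack([xs, np.ones_like(xs)]).T
        coef, *_ = np.linalg.lstsq(A, ys, rcond=None)
        r = ys - A @ coef
        return float(r @ r)

    best_b, best = 0, sse(0, H)
    for b in range(1, H):
        total = sse(0, b) + sse(b, H)
        if total < best - 1e-12:
            best_b, best = b, total
    return best_b
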