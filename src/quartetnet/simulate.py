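"""Gene-tree simulation under the network multispecies coalescent.

Lineages are traced from the leaves toward the root of a (rooted view of a)
level-1 network.  Within an edge of length t coalescent units carrying j
lineages, pairwise coalescences occur at rate 1 per pair (waiting times
Exp(j(j-1)/2), truncated at the edge length).  At a hybrid node each
remaining lineage independently follows the minor parent edge with
probability gamma.  Lineages surviving to the root coalesce under the
unconstrained Kingman coalescent.

This module is also the repository's synthetic-data generator: it builds
random level-1 networks by the study recipe — a Kingman coalescent species
tree, plus hybridizations whose origin and target are chosen uniformly among
edges, rejecting candidates that violate the level-1 or searchability
constraints — and fixes four simulation designs (n, h) = (6, 1), (6, 2),
(10, 1), (15, 3) with inheritance probabilities 0.2-0.3 and the structural
features those designs are stated to contain (4-cycles throughout, a bad
diamond I in the (6, 2) design, a bad diamond II in the (10, 1) design).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .cftables import GClade, GeneTree, GeneTreeSample, QuartetCFTable, count_quartets
from .network import Network, hybrid_cycles, validate_level1

__all__ = [
    "SimSpec",
    "simulate_gene_trees",
    "simulate_cf_table",
    "random_coalescent_tree",
    "random_network",
    "default_sim_networks",
]


@dataclass
class SimSpec:
    """What to simulate: a network (lengths in coalescent units, gammas set),
    the number of independent genes, a seed, and samples per taxon."""

    network: Network
    ngenes: int
    seed: Optional[int] = None
    samples_per_taxon: int = 1
    outgroup: Optional[str] = None

    def __post_init__(self):
        if self.ngenes < 0:
            raise ValueError("negative number of genes")
        if self.samples_per_taxon < 1:
            raise ValueError("need at least one sample per taxon")


def _coalesce(lin: list, t: float, rng) -> list:
    """Kingman coalescent for duration t (may be inf) among lineages given
    as [clade, age] pairs, where age is the exposure accumulated since the
    clade's node was created (it becomes that node's branch length)."""
    elapsed = 0.0
    while len(lin) >= 2:
        j = len(lin)
        w = rng.expovariate(j * (j - 1) / 2.0)
        if elapsed + w > t:
            break
        elapsed += w
        for x in lin:
            x[1] += w
        i = int(rng.random() * j)
        k = int(rng.random() * (j - 1))
        if k >= i:
            k += 1
        a = lin[i]
        b = lin[k]
        ca, cb = a[0], b[0]
        merged = [GClade(children=(
            GClade(ca.name, a[1], None, ca.children),
            GClade(cb.name, b[1], None, cb.children))), 0.0]
        if i < k:
            i, k = k, i
        del lin[i]
        del lin[k]
        lin.append(merged)
    if math.isfinite(t) and t > elapsed:
        dt = t - elapsed
        for x in lin:
            x[1] += dt
    return lin


def simulate_gene_trees(spec: SimSpec) -> GeneTreeSample:
    """Independent gene trees under the network coalescent, reproducible
    under the SimSpec seed.  Branch lengths reflect accumulated coalescent
    exposure; quartet analyses use topologies only."""
    import random as _random

    errors = validate_level1(spec.network)
    if errors:
        raise ValueError("invalid network: " + "; ".join(errors))
    rng = _random.Random(spec.seed)
    rooted = spec.network.rooted(outgroup=spec.outgroup)
    net = spec.network

    # compile a per-node program: (is_root, leaf labels or None,
    # child edge slots, [(edge slot, length, gamma-if-minor), ...])
    edge_slot: dict[int, int] = {}

    def slot(e) -> int:
        return edge_slot.setdefault(id(e), len(edge_slot))

    program = []
    for v in rooted.topo_order():
        is_root = v == rooted.root
        name = net.names.get(v)
        kids = rooted.children.get(v, [])
        if name is not None and not kids:
            if spec.samples_per_taxon == 1:
                labels = [name]
            else:
                labels = [f"{name}_{i + 1}"
                          for i in range(spec.samples_per_taxon)]
        else:
            labels = None
        child_slots = [slot(e) for (_c, e) in kids]
        pinfo = []
        for (_p, e) in rooted.parents.get(v, []):
            g = None
            if e.hybrid and not e.major:
                g = e.gamma
                if g is None:
                    raise ValueError(f"gamma unset at hybrid node {v}")
            pinfo.append((slot(e), e.length, g))
        if len(pinfo) == 2 and all(gi is None for _s, _t, gi in pinfo):
            raise ValueError(f"hybrid node {v} lacks a minor edge")
        program.append((is_root, labels, child_slots, pinfo))

    tops: list = [None] * len(edge_slot)
    trees = []
    for _ in range(spec.ngenes):
        for is_root, labels, child_slots, pinfo in program:
            if labels is not None:
                lins = [[GClade(name=nm), 0.0] for nm in labels]
            else:
                lins = []
                for s in child_slots:
                    lins.extend(tops[s])
            if is_root:
                final = _coalesce(lins, math.inf, rng)
                trees.append(GeneTree(final[0][0]))
                continue
            if len(pinfo) == 2:
                minor = next(p for p in pinfo if p[2] is not None)
                major = next(p for p in pinfo if p[2] is None)
                g = minor[2]
                take, rest = [], []
                for x in lins:
                    (take if rng.random() < g else rest).append(x)
                groups = ((minor, take), (major, rest))
            else:
                groups = ((pinfo[0], lins),)
            for (s, t, _g), group in groups:
                if t is None:
                    if len(group) > 1:
                        raise ValueError(
                            "an internal edge with missing length carries "
                            f"{len(group)} lineages")
                    t = 0.0
                tops[s] = _coalesce(group, t, rng)
    if spec.samples_per_taxon == 1:
        taxa = sorted(net.leaves())
    else:
        taxa = sorted({n for tr in trees for n in tr.leaf_names()})
    return GeneTreeSample(taxa, trees)


def simulate_cf_table(spec: SimSpec,
                      sets: Optional[Sequence[Sequence[str]]] = None
                      ) -> QuartetCFTable:
    """simulate_gene_trees followed by quartet counting."""
    sample = simulate_gene_trees(spec)
    if not sample.trees:
        raise ValueError("no genes simulated (ngenes = 0)")
    return count_quartets(sample, sets=sets)


# ---------------------------------------------------------------------------
# random level-1 networks (the synthetic-data generator)
# ---------------------------------------------------------------------------

def random_coalescent_tree(n: int, rng, prefix: str = "t") -> Network:
    """A Kingman coalescent species tree on n taxa, lengths in coalescent
    units (pairwise coalescence rate 1)."""
    if n < 2:
        raise ValueError("need at least 2 taxa")
    net = Network()
    active = []
    for i in range(n):
        leaf = net.add_node(f"{prefix}{i + 1}")
        active.append((leaf, 0.0))
    now = 0.0
    while len(active) > 1:
        j = len(active)
        now += rng.exponential(2.0 / (j * (j - 1)))
        i, k = rng.choice(j, size=2, replace=False)
        (a, ha), (b, hb) = active[int(i)], active[int(k)]
        parent = net.add_node()
        net.add_edge(parent, a, now - ha)
        net.add_edge(parent, b, now - hb)
        active = [x for m, x in enumerate(active) if m not in (int(i), int(k))]
        active.append((parent, now))
    # suppress the degree-2 root so the tree is semi-directed/unrooted
    root = active[0][0]
    if net.degree(root) == 2:
        net.suppress_node(root)
    return net


_SEARCHABLE = {"triangle_good", "diamond_good", "diamond_bad_I",
               "diamond_bad_II", "k5plus"}


def random_network(n: int, h: int, rng, gammas: Sequence[float] = (0.3,),
                   max_tries: int = 2000,
                   require_classes: Optional[Sequence[str]] = None,
                   require_k: Optional[Sequence[int]] = None,
                   searchable_only: bool = True,
                   hybrid_length: float = 0.0,
                   min_internal: float = 0.0) -> Network:
    """A random level-1 network: coalescent tree plus h hybridizations whose
    origin and target edges are chosen uniformly, rejecting non-level-1 or
    (optionally) non-searchable candidates and candidates without the
    required cycle classes / cycle sizes.  ``min_internal`` additionally
    rejects draws with internal tree edges shorter than that (near-zero
    internal branches are hard polytomies, outside the model's t > 0
    regularity assumption)."""
    for _ in range(max_tries):
        net = random_coalescent_tree(n, rng)
        ok = True
        for i in range(h):
            g = gammas[i % len(gammas)]
            if not _add_random_hybridization(net, rng, g, hybrid_length):
                ok = False
                break
        if not ok:
            continue
        if validate_level1(net) or not net.has_valid_root():
            continue
        infos = hybrid_cycles(net)
        classes = [c.klass for c in infos]
        if searchable_only and any(c not in _SEARCHABLE for c in classes):
            continue
        if require_classes is not None:
            pool = list(classes)
            missing = False
            for want in require_classes:
                if want in pool:
                    pool.remove(want)
                else:
                    missing = True
                    break
            if missing:
                continue
        if require_k is not None:
            if sorted(c.k for c in infos) != sorted(require_k):
                continue
        if min_internal > 0.0:
            leafset = set(net.leaves().values())
            if any(not e.hybrid and e.u not in leafset and e.v not in leafset
                   and (e.length is None or e.length < min_internal)
                   for e in net.edges.values()):
                continue
        return net
    raise RuntimeError(f"no admissible network found in {max_tries} tries "
                       f"(n={n}, h={h})")


def _add_random_hybridization(net: Network, rng, gamma: float,
                              hybrid_length: float) -> bool:
    eids = sorted(net.edges)
    if len(eids) < 2:
        return False
    i, k = rng.choice(len(eids), size=2, replace=False)
    eo, et = eids[int(i)], eids[int(k)]
    mo = net.subdivide(eo, float(rng.uniform(0.2, 0.8)))
    mt = net.subdivide(et, float(rng.uniform(0.2, 0.8)))
    pieces = [e for e in net.incident(mt)]
    part = pieces[int(rng.integers(2))]
    if part.hybrid:
        return False
    part.hybrid = True
    part.gamma = 1.0 - gamma
    part.major = True
    if part.v != mt:
        part.u, part.v = part.v, part.u
    net.add_edge(mo, mt, hybrid_length, hybrid=True, gamma=gamma, major=False)
    return not validate_level1(net)


#: seeds found by scanning the generator so each design carries the stated
#: structural features; the recipe, not these numbers, defines the designs
_DESIGN_SEEDS = {
    (6, 1): 91,
    (6, 2): 9440,
    (10, 1): 532,
    (15, 3): 19227,
}


def default_sim_networks() -> dict[tuple[int, int], Network]:
    """The four simulation designs (n, h) = (6,1), (6,2), (10,1), (15,3).

    Each is regenerated by the randomized recipe under a frozen seed chosen
    so that: every cycle has k >= 4; the (6, 2) design contains a bad
    diamond I; the (10, 1) design contains a bad diamond II; the (15, 3)
    design's cycles span k = 4, 5, 6.  Minor-edge inheritance probabilities
    are 0.3 (and 0.2 for second reticulations).
    """
    out = {}
    for (n, h), seed in _DESIGN_SEEDS.items():
        rng = np.random.default_rng(seed)
        kwargs = {}
        if (n, h) == (6, 1):
            kwargs = dict(gammas=(0.3,), require_k=[4], min_internal=0.1)
        elif (n, h) == (6, 2):
            kwargs = dict(gammas=(0.3, 0.2), require_k=[4, 4],
                          require_classes=["diamond_bad_I"], min_internal=0.1)
        elif (n, h) == (10, 1):
            kwargs = dict(gammas=(0.3,), require_classes=["diamond_bad_II"],
                          min_internal=0.03)
        elif (n, h) == (15, 3):
            # cycles of sizes 4, 5 and 6: one hard short cycle plus two
            # longer, easier ones (larger combinations are essentially
            # unreachable under this recipe)
            kwargs = dict(gammas=(0.3, 0.2, 0.3), require_k=[4, 5, 6],
                          min_internal=0.01)
        out[(n, h)] = random_network(n, h, rng, max_tries=1, **kwargs)
    return out
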