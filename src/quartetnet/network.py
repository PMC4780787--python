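"""Semi-directed, level-1 phylogenetic networks.

A semi-directed network is an unrooted leaf-labeled graph in which tree
edges carry no direction but hybrid edges do: each hybrid node has exactly
two incoming hybrid edges (with inheritance probabilities summing to 1) and
one outgoing tree edge.  The root is not part of the object, but at least
one valid root placement must exist: a position from which every edge can be
directed away from the root without reversing any hybrid edge.

The class is *level-1*: every edge belongs to at most one cycle of the
underlying undirected graph, so reticulation cycles never overlap.  Branch
lengths are in coalescent units; external (leaf) edge lengths are allowed to
be missing because they are not identifiable from quartet topologies with a
single sampled individual per taxon.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional

__all__ = [
    "Network",
    "RootedNetwork",
    "HybridCycleInfo",
    "ParameterMap",
    "NetworkError",
    "ParseError",
    "RootingError",
    "IdentifiabilityError",
    "parse_enewick",
    "write_enewick",
    "validate_level1",
    "hybrid_cycles",
    "root_with_outgroup",
    "major_tree",
    "apply_identifiability_constraints",
    "bad_diamond_reparam",
    "induced_subnetwork",
    "same_topology",
]

GAMMA_TOL = 1e-6
#: default length given to internal edges whose length is missing
DEFAULT_INTERNAL_LENGTH = 1.0
#: finite stand-in for an infinite branch length during optimization
TMAX = 10.0
TMIN = 1e-10


class NetworkError(ValueError):
    """Structural violation of the semi-directed network invariants."""


class ParseError(NetworkError):
    """Malformed extended-Newick input."""


class RootingError(NetworkError):
    """No valid root placement at the requested position."""


class IdentifiabilityError(NetworkError):
    """Network contains a reticulation class excluded from the search space."""


@dataclass
class Edge:
    """Undirected tree edge, or directed hybrid edge ``u -> v`` (v hybrid)."""

    id: int
    u: int
    v: int
    length: Optional[float] = None
    hybrid: bool = False
    gamma: Optional[float] = None
    major: bool = True

    def other(self, node: int) -> int:
        return self.v if node == self.u else self.u


def _sum_lengths(a: Optional[float], b: Optional[float]) -> Optional[float]:
    if a is None or b is None:
        return None
    return a + b


class Network:
    """Leaf-labeled semi-directed phylogenetic network (possibly a tree)."""

    def __init__(self) -> None:
        self.names: dict[int, Optional[str]] = {}
        self.edges: dict[int, Edge] = {}
        self._adj: dict[int, list[int]] = {}
        self._next_node = 0
        self._next_edge = 0

    # -- construction ------------------------------------------------------

    def add_node(self, name: Optional[str] = None) -> int:
        nid = self._next_node
        self._next_node += 1
        self.names[nid] = name
        self._adj[nid] = []
        return nid

    def add_edge(
        self,
        u: int,
        v: int,
        length: Optional[float] = None,
        hybrid: bool = False,
        gamma: Optional[float] = None,
        major: bool = True,
    ) -> int:
        eid = self._next_edge
        self._next_edge += 1
        self.edges[eid] = Edge(eid, u, v, length, hybrid, gamma, major)
        self._adj[u].append(eid)
        self._adj[v].append(eid)
        return eid

    def remove_edge(self, eid: int) -> None:
        e = self.edges.pop(eid)
        self._adj[e.u].remove(eid)
        self._adj[e.v].remove(eid)

    def remove_node(self, nid: int) -> None:
        for eid in list(self._adj[nid]):
            self.remove_edge(eid)
        del self._adj[nid]
        del self.names[nid]

    def copy(self) -> "Network":
        net = Network()
        net.names = dict(self.names)
        net.edges = {i: Edge(e.id, e.u, e.v, e.length, e.hybrid, e.gamma, e.major)
                     for i, e in self.edges.items()}
        net._adj = {v: list(a) for v, a in self._adj.items()}
        net._next_node = self._next_node
        net._next_edge = self._next_edge
        return net

    # -- queries -----------------------------------------------------------

    def nodes(self) -> Iterable[int]:
        return self._adj.keys()

    def incident(self, v: int) -> list[Edge]:
        return [self.edges[i] for i in self._adj[v]]

    def degree(self, v: int) -> int:
        return len(self._adj[v])

    def is_leaf(self, v: int) -> bool:
        return self.names.get(v) is not None and len(self._adj[v]) <= 1

    def leaves(self) -> dict[str, int]:
        return {self.names[v]: v for v in self._adj
                if self.names[v] is not None and len(self._adj[v]) <= 1}

    def taxa(self) -> list[str]:
        return sorted(self.leaves())

    def hybrid_nodes(self) -> list[int]:
        seen = []
        for e in self.edges.values():
            if e.hybrid and e.v not in seen:
                seen.append(e.v)
        return sorted(seen)

    @property
    def h(self) -> int:
        return len(self.hybrid_nodes())

    def hybrid_parents(self, h: int) -> tuple[Edge, Edge]:
        """(major, minor) hybrid edges into hybrid node ``h``."""
        es = [e for e in self.incident(h) if e.hybrid and e.v == h]
        if len(es) != 2:
            raise NetworkError(f"node {h} has {len(es)} incoming hybrid edges")
        es.sort(key=lambda e: (not e.major, e.id))
        return es[0], es[1]

    def hybrid_child_edge(self, h: int) -> Edge:
        es = [e for e in self.incident(h) if not (e.hybrid and e.v == h)]
        if len(es) != 1:
            raise NetworkError(f"hybrid node {h} has {len(es)} outgoing edges")
        return es[0]

    def internal_edges(self) -> list[Edge]:
        lv = set(self.leaves().values())
        return [e for e in self.edges.values() if e.u not in lv and e.v not in lv]

    # -- surgery -----------------------------------------------------------

    def subdivide(self, eid: int, frac: float = 0.5) -> int:
        """Split an edge with a new degree-2 node; returns the new node id.

        A hybrid edge ``u -> v`` is split into a tree edge ``u - m`` and a
        hybrid edge ``m -> v`` carrying the gamma.
        """
        e = self.edges[eid]
        m = self.add_node()
        la = lb = None
        if e.length is not None:
            la, lb = e.length * frac, e.length * (1.0 - frac)
        self.remove_edge(eid)
        self.add_edge(e.u, m, la)
        self.add_edge(m, e.v, lb, hybrid=e.hybrid, gamma=e.gamma, major=e.major)
        return m

    def suppress_node(self, v: int) -> int:
        """Merge the two edges at a degree-2 non-hybrid node; returns new edge id."""
        eids = list(self._adj[v])
        if len(eids) != 2:
            raise NetworkError(f"cannot suppress node {v} of degree {len(eids)}")
        e1, e2 = (self.edges[i] for i in eids)
        h1 = e1.hybrid and e1.v != v
        h2 = e2.hybrid and e2.v != v
        if (e1.hybrid and e1.v == v) or (e2.hybrid and e2.v == v):
            raise NetworkError(f"node {v} is a hybrid child; cannot suppress")
        if h1 and h2:
            raise NetworkError(f"node {v} is the origin of two hybrid edges")
        length = _sum_lengths(e1.length, e2.length)
        if h1 or h2:
            eh, et = (e1, e2) if h1 else (e2, e1)
            w = et.other(v)
            self.remove_node(v)
            return self.add_edge(w, eh.v, length, hybrid=True,
                                 gamma=eh.gamma, major=eh.major)
        a, b = e1.other(v), e2.other(v)
        self.remove_node(v)
        return self.add_edge(a, b, length)

    def cleanup(self, keep: Optional[set[int]] = None) -> None:
        """Restore degree invariants after pruning.

        Iteratively removes dangling internal nodes, drops reticulations whose
        hybrid node lost its descendants, and suppresses degree-2 pass-through
        nodes (kept when suppression is impossible, e.g. the apex of a
        2-cycle or the shared origin of two hybrid edges).
        """
        keep = keep or set()
        changed = True
        while changed:
            changed = False
            for v in list(self._adj):
                if v not in self._adj or v in keep:
                    continue
                deg = len(self._adj[v])
                named = self.names[v] is not None
                ine = [i for i in self._adj[v]
                       if self.edges[i].hybrid and self.edges[i].v == v]
                if named and deg <= 1:
                    continue
                if deg == 0:
                    self.remove_node(v)
                    changed = True
                elif len(ine) == 2 and deg == 2:
                    # reticulation with no descendants: drop both hybrid edges
                    self.remove_node(v)
                    changed = True
                elif deg == 1 and not ine:
                    self.remove_node(v)
                    changed = True
                elif deg == 2 and not ine:
                    e1, e2 = (self.edges[i] for i in self._adj[v])
                    hy = [e for e in (e1, e2) if e.hybrid]
                    if len(hy) == 2:
                        if e1.v == e2.v and e1.other(v) == e2.other(v):
                            continue  # apex of a 2-cycle: keep
                        continue  # origin of two hybrid edges: keep
                    if e1.other(v) == e2.other(v):
                        continue  # suppressing would create a self-loop
                    self.suppress_node(v)
                    changed = True

    # -- rooting -----------------------------------------------------------

    def valid_root_edges(self) -> list[int]:
        return [eid for eid in sorted(self.edges) if self._orient(eid) is not None]

    def has_valid_root(self) -> bool:
        return any(self._orient(eid) is not None for eid in self.edges)

    def _orient(self, root_eid: int):
        """Try to direct every edge away from a root placed on ``root_eid``.

        Returns ``{edge_id: (parent, child)}`` or None if the placement
        conflicts with a hybrid-edge direction.
        """
        e0 = self.edges[root_eid]
        direction: dict[int, tuple[int, int]] = {}
        visited: set[int] = set()
        stack: list[int] = []

        def arrive(node: int, via: Optional[int]) -> bool:
            if node in visited:
                if via is not None and self.edges[via].hybrid \
                        and self.edges[via].v == node:
                    return True  # second parent of a hybrid node
                return False
            visited.add(node)
            stack.append(node)
            return True

        # the root sits on e0: both endpoints become its children
        if e0.hybrid:
            # allowed only when directed consistently: root -> e0.v stays
            # hybrid, root -> e0.u runs against nothing (u becomes a child)
            pass
        for end in (e0.u, e0.v):
            if not arrive(end, None):
                return None
        direction[root_eid] = (-1, -1)  # split by the root
        while stack:
            x = stack.pop()
            for eid in self._adj[x]:
                if eid in direction:
                    continue
                e = self.edges[eid]
                if e.hybrid:
                    if x != e.u:
                        continue  # only traversable from origin to hybrid
                    direction[eid] = (e.u, e.v)
                    if not arrive(e.v, eid):
                        return None
                else:
                    y = e.other(x)
                    direction[eid] = (x, y)
                    if not arrive(y, eid):
                        return None
        if len(visited) != len(self._adj) or len(direction) != len(self.edges):
            return None
        for h in self.hybrid_nodes():
            ins = [e for e in self.incident(h) if e.hybrid and e.v == h]
            if len(ins) != 2:
                return None
        return direction

    def rooted(self, outgroup: Optional[str] = None,
               at_edge: Optional[int] = None) -> "RootedNetwork":
        """A rooted (fully directed) view of this network.

        With ``outgroup`` the root goes on that taxon's external edge; with
        neither argument the first valid placement is used, preferring
        external edges of alphabetically early taxa for determinism.
        """
        if outgroup is not None:
            leaves = self.leaves()
            if outgroup not in leaves:
                raise RootingError(f"taxon {outgroup!r} not in leaf set")
            at_edge = self._adj[leaves[outgroup]][0]
        if at_edge is not None:
            direction = self._orient(at_edge)
            if direction is None:
                bad = [e.id for e in self.edges.values() if e.hybrid]
                raise RootingError(
                    f"no valid root on edge {at_edge}"
                    + (f" (outgroup {outgroup!r})" if outgroup else "")
                    + f": placement conflicts with hybrid edge(s) {bad}")
            return RootedNetwork(self, at_edge, direction)
        order = []
        leaves = self.leaves()
        for name in sorted(leaves):
            order.append(self._adj[leaves[name]][0])
        order += [eid for eid in sorted(self.edges) if eid not in order]
        for eid in order:
            direction = self._orient(eid)
            if direction is not None:
                return RootedNetwork(self, eid, direction)
        raise RootingError("network admits no valid root placement")


class RootedNetwork:
    """Directed view of a :class:`Network`, rooted on one of its edges.

    The root is a synthetic node of outdegree 2 splitting the chosen edge;
    every other edge is directed away from it.  Hybrid nodes have indegree 2
    (their hybrid edges), all other non-root nodes indegree 1.
    """

    def __init__(self, net: Network, root_edge: int,
                 direction: dict[int, tuple[int, int]]):
        self.net = net
        self.root_edge = root_edge
        self.root = -1
        self.children: dict[int, list[tuple[int, Edge]]] = {v: [] for v in net.nodes()}
        self.children[self.root] = []
        self.parents: dict[int, list[tuple[int, Edge]]] = {v: [] for v in net.nodes()}
        e0 = net.edges[root_edge]
        half = None if e0.length is None else e0.length / 2.0
        ea = Edge(-2, self.root, e0.u, half)
        eb = Edge(-3, self.root, e0.v, half, hybrid=e0.hybrid,
                  gamma=e0.gamma, major=e0.major)
        for e in (ea, eb):
            self.children[self.root].append((e.v, e))
            self.parents[e.v].append((self.root, e))
        for eid, (p, c) in direction.items():
            if eid == root_edge:
                continue
            e = net.edges[eid]
            self.children[p].append((c, e))
            self.parents[c].append((p, e))
        for v in self.children:
            self.children[v].sort(key=lambda t: t[1].id)

    def topo_order(self) -> list[int]:
        """Nodes ordered leaves first, root last."""
        indeg = {v: len(self.parents.get(v, [])) for v in self.children}
        out = {v: len(self.children[v]) for v in self.children}
        ready = [v for v in self.children if out[v] == 0]
        order = []
        seen_out = dict(out)
        while ready:
            v = ready.pop()
            order.append(v)
            for (p, _e) in self.parents.get(v, []):
                seen_out[p] -= 1
                if seen_out[p] == 0:
                    ready.append(p)
        if len(order) != len(self.children):
            raise NetworkError("rooted view is not acyclic")
        return order

    def cluster(self, v: int) -> frozenset[str]:
        """Hardwired cluster: taxa reachable below node ``v``."""
        out: set[str] = set()
        stack = [v]
        seen = set()
        while stack:
            x = stack.pop()
            if x in seen:
                continue
            seen.add(x)
            name = self.net.names.get(x)
            if name is not None and not self.children.get(x):
                out.add(name)
            for (c, _e) in self.children.get(x, []):
                stack.append(c)
        return frozenset(out)


# ---------------------------------------------------------------------------
# extended-Newick parsing and writing
# ---------------------------------------------------------------------------

_STOP = set("(),:;#[]")


def _scan(s: str, i: int) -> tuple[str, int]:
    j = i
    while j < len(s) and s[j] not in _STOP and not s[j].isspace():
        j += 1
    return s[i:j], j


def _skip_ws(s: str, i: int) -> int:
    while i < len(s) and s[i].isspace():
        i += 1
    return i


def _parse_subtree(s: str, i: int) -> tuple[dict, int]:
    i = _skip_ws(s, i)
    rec = {"children": [], "name": None, "htag": None}
    if i < len(s) and s[i] == "(":
        i += 1
        while True:
            child, i = _parse_branch(s, i)
            rec["children"].append(child)
            i = _skip_ws(s, i)
            if i < len(s) and s[i] == ",":
                i += 1
                continue
            if i < len(s) and s[i] == ")":
                i += 1
                break
            raise ParseError(f"expected ',' or ')' at position {i}")
        label, i = _scan(s, i)
        if label:
            rec["name"] = label
    else:
        label, i = _scan(s, i)
        rec["name"] = label or None
    if i < len(s) and s[i] == "#":
        tag, i = _scan(s, i + 1)
        if not tag:
            raise ParseError(f"empty hybrid tag at position {i}")
        rec["htag"] = tag
    return rec, i


def _parse_branch(s: str, i: int) -> tuple[dict, int]:
    rec, i = _parse_subtree(s, i)
    fields: list[str] = []
    while i < len(s) and s[i] == ":":
        f, i = _scan(s, i + 1)
        fields.append(f)
    rec["length"] = float(fields[0]) if fields and fields[0] else None
    rec["support"] = float(fields[1]) if len(fields) > 1 and fields[1] else None
    rec["gamma"] = float(fields[2]) if len(fields) > 2 and fields[2] else None
    return rec, i


def parse_enewick(text: str, validate: bool = True) -> Network:
    """Parse an extended-Newick string into a semi-directed network.

    Hybrid nodes are tagged ``#H<id>`` and must appear exactly twice; the
    inheritance probability gamma sits in the third colon field of a hybrid
    edge (``(...)#H1:length:support:gamma``).  If gamma is given on only one
    of the two hybrid edges the partner receives ``1 - gamma``; the edge with
    gamma >= 0.5 is marked major.  A taxon sitting at a hybrid node may be
    written ``name#H1`` as shorthand for ``(name)#H1``.
    """
    text = text.strip()
    if not text.endswith(";"):
        raise ParseError("missing terminal ';'")
    rec, i = _parse_branch(text, 0)
    i = _skip_ws(text, i)
    if i != len(text) - 1:
        raise ParseError(f"trailing characters at position {i}")

    net = Network()
    hyb_node: dict[str, int] = {}
    hyb_count: dict[str, int] = {}
    hyb_edges: dict[str, list[int]] = {}
    hyb_named: dict[str, Optional[str]] = {}

    def build(r: dict, parent: Optional[int]) -> None:
        tag = r["htag"]
        if tag is not None:
            hyb_count[tag] = hyb_count.get(tag, 0) + 1
            if tag in hyb_node:
                nid = hyb_node[tag]
            else:
                nid = net.add_node(None)
                hyb_node[tag] = nid
                hyb_edges[tag] = []
                hyb_named[tag] = None
            if r["name"]:
                if hyb_named[tag] and hyb_named[tag] != r["name"]:
                    raise ParseError(f"conflicting names on hybrid #{tag}")
                hyb_named[tag] = r["name"]
        else:
            nid = net.add_node(r["name"] if not r["children"] else None)
        if parent is not None:
            eid = net.add_edge(parent, nid, r.get("length"),
                               hybrid=tag is not None, gamma=r.get("gamma"))
            if tag is not None:
                hyb_edges[tag].append(eid)
        for ch in r["children"]:
            build(ch, nid)

    root = net.add_node(rec["name"] if not rec["children"] else None)
    if rec["htag"]:
        raise ParseError("root cannot be a hybrid node")
    for ch in rec["children"]:
        build(ch, root)

    for tag, cnt in hyb_count.items():
        if cnt != 2:
            raise ParseError(f"hybrid tag #{tag} appears {cnt} times, expected 2")
    # taxon-at-hybrid shorthand: give the hybrid node a leaf child
    for tag, name in hyb_named.items():
        h = hyb_node[tag]
        has_child = any(not (e.hybrid and e.v == h) for e in net.incident(h))
        if name is not None:
            if has_child:
                raise ParseError(f"hybrid #{tag} has both a name and children")
            leaf = net.add_node(name)
            net.add_edge(h, leaf, None)

    # gammas and major flags
    for tag, eids in hyb_edges.items():
        e1, e2 = (net.edges[i] for i in eids)
        for e in (e1, e2):
            if e.gamma is not None and not (0.0 <= e.gamma <= 1.0):
                raise ParseError(f"gamma {e.gamma} outside [0, 1] on #{tag}")
        if e1.gamma is None and e2.gamma is not None:
            e1.gamma = 1.0 - e2.gamma
        elif e2.gamma is None and e1.gamma is not None:
            e2.gamma = 1.0 - e1.gamma
        elif e1.gamma is not None and e2.gamma is not None:
            if abs(e1.gamma + e2.gamma - 1.0) > GAMMA_TOL:
                raise ParseError(
                    f"gammas on #{tag} sum to {e1.gamma + e2.gamma}, expected 1")
        if e1.gamma is not None and e1.gamma != e2.gamma:
            majr = e1 if e1.gamma > e2.gamma else e2
        else:
            majr = e1  # tie or unset: first-encountered edge is major
        for e in (e1, e2):
            e.major = e is majr

    # suppress a degree-2 root so only the semi-directed structure remains
    while len(net._adj.get(root, [])) == 1 and net.names[root] is None:
        e = net.incident(root)[0]
        other = e.other(root)
        net.remove_node(root)
        root = other
    if len(net._adj.get(root, [])) == 2 and net.names[root] is None:
        es = net.incident(root)
        into_root = [e for e in es if e.hybrid and e.v == root]
        if into_root:
            raise ParseError("root placed below a hybrid node")
        try:
            net.suppress_node(root)
        except NetworkError as exc:
            raise ParseError(str(exc)) from exc

    if validate:
        errors = validate_level1(net)
        if errors:
            raise NetworkError("; ".join(errors))
    return net


def write_enewick(net: Network, root_at: Optional[str] = None,
                  digits: int = 12) -> str:
    """Serialize to extended Newick, rooting at ``root_at`` if given.

    Each hybrid node appears twice: its subtree under the major parent and a
    bare ``#H<k>`` stub under the minor parent, both annotated
    ``:length:support:gamma`` (support left empty).
    """
    rooted = net.rooted(outgroup=root_at)
    hyb_ids: dict[int, int] = {}
    for k, h in enumerate(net.hybrid_nodes(), start=1):
        hyb_ids[h] = k

    def fmt(x: Optional[float]) -> str:
        if x is None:
            return ""
        s = f"{x:.{digits}g}"
        return s

    def edge_suffix(e: Edge) -> str:
        if e.hybrid:
            return f":{fmt(e.length)}::{fmt(e.gamma)}"
        if e.length is None:
            return ""
        return f":{fmt(e.length)}"

    def render(v: int, via: Edge) -> str:
        if v in hyb_ids:
            tag = f"#H{hyb_ids[v]}"
            if not via.major:
                return f"{tag}{edge_suffix(via)}"
            kids = [c for c in rooted.children[v]]
            inner = ",".join(render(c, e) for c, e in kids)
            return f"({inner}){tag}{edge_suffix(via)}"
        kids = rooted.children.get(v, [])
        if not kids:
            return f"{net.names[v]}{edge_suffix(via)}"
        inner = ",".join(render(c, e) for c, e in kids)
        return f"({inner}){edge_suffix(via)}"

    parts = [render(c, e) for c, e in rooted.children[rooted.root]]
    return f"({','.join(parts)});"


# ---------------------------------------------------------------------------
# validation and cycle classification
# ---------------------------------------------------------------------------

def validate_level1(net: Network, strict_degrees: bool = True) -> list[str]:
    """Diagnostics for the semi-directed level-1 invariants (empty = valid)."""
    out: list[str] = []
    names = [n for n in net.names.values() if n is not None]
    if len(names) != len(set(names)):
        dup = sorted({n for n in names if names.count(n) > 1})
        out.append(f"duplicate leaf labels: {dup}")

    hybrids = net.hybrid_nodes()
    for h in hybrids:
        ins = [e for e in net.incident(h) if e.hybrid and e.v == h]
        outs = [e for e in net.incident(h) if not (e.hybrid and e.v == h)]
        if len(ins) != 2 or len(outs) != 1:
            out.append(f"hybrid node {h} has {len(ins)} hybrid parents and "
                       f"{len(outs)} other edges (expected 2 and 1)")
            continue
        g1, g2 = ins[0].gamma, ins[1].gamma
        if g1 is not None and g2 is not None and abs(g1 + g2 - 1.0) > GAMMA_TOL:
            out.append(f"gammas at hybrid {h} sum to {g1 + g2}")
        if any(e.hybrid for e in outs):
            out.append(f"hybrid node {h} has a hybrid child edge")

    if strict_degrees:
        for v in net.nodes():
            deg = net.degree(v)
            if net.names[v] is not None:
                if deg != 1:
                    out.append(f"leaf {net.names[v]} has degree {deg}")
            elif v in hybrids:
                pass  # checked above
            elif deg != 3:
                out.append(f"internal node {v} has degree {deg} (expected 3)")

    if any("hybrid node" in msg for msg in out):
        return out

    # cyclomatic number must equal h for edge-disjoint cycles to be possible
    ncomp = _n_components(net)
    if ncomp != 1:
        out.append(f"graph has {ncomp} connected components")
        return out
    cyclo = len(net.edges) - len(net._adj) + ncomp
    if cyclo != len(hybrids):
        out.append(f"{cyclo} independent cycles for {len(hybrids)} hybrid "
                   "nodes: graph is not level-1")
        return out

    seen_edges: dict[int, int] = {}
    for h in hybrids:
        cyc = _hybrid_cycle(net, h)
        if cyc is None:
            out.append(f"hybrid node {h}: parents are disconnected outside "
                       "the reticulation")
            continue
        _nodes, eids = cyc
        for eid in eids:
            if eid in seen_edges:
                out.append(f"edge {eid} lies in the cycles of hybrid nodes "
                           f"{seen_edges[eid]} and {h}: not level-1")
            seen_edges[eid] = h

    if not out and not net.has_valid_root():
        out.append("no valid root placement exists")
    return out


def _n_components(net: Network) -> int:
    seen: set[int] = set()
    comps = 0
    for start in net.nodes():
        if start in seen:
            continue
        comps += 1
        stack = [start]
        while stack:
            x = stack.pop()
            if x in seen:
                continue
            seen.add(x)
            for e in net.incident(x):
                stack.append(e.other(x))
    return comps


def _hybrid_cycle(net: Network, h: int):
    """Cycle through hybrid ``h``: (ordered nodes, ordered edge ids).

    Nodes run from the major parent around the cycle to the minor parent and
    end at the hybrid node itself.  Returns None if the parents are not
    connected outside ``h``.
    """
    emaj, emin = net.hybrid_parents(h)
    o1, o2 = emaj.other(h), emin.other(h)
    if o1 == o2:  # 2-cycle: parallel hybrid edges
        return [o1, h], [emaj.id, emin.id]
    # BFS from o1 to o2 avoiding node h
    prev: dict[int, tuple[int, int]] = {o1: (-1, -1)}
    queue = [o1]
    while queue:
        x = queue.pop(0)
        if x == o2:
            break
        for e in net.incident(x):
            y = e.other(x)
            if y == h or y in prev:
                continue
            prev[y] = (x, e.id)
            queue.append(y)
    if o2 not in prev:
        return None
    path_nodes = [o2]
    path_edges: list[int] = []
    x = o2
    while x != o1:
        p, eid = prev[x]
        path_edges.append(eid)
        path_nodes.append(p)
        x = p
    path_nodes.reverse()   # o1 .. o2
    path_edges.reverse()
    nodes = path_nodes + [h]
    eids = path_edges + [emin.id, emaj.id]
    return nodes, eids


@dataclass
class HybridCycleInfo:
    """Structure of one reticulation cycle.

    ``counts`` lists the number of taxa in the subtree hanging off each cycle
    node, ordered from the major parent around the cycle to the minor parent
    and ending with the hybrid node's own subtree.  For a 4-cycle this makes
    ``counts = (n0, n1, n2, n3)`` with n0/n2 the two hybrid parents, n1 the
    node opposite the hybrid, and n3 the hybrid's descendants — identifiable
    ("good diamond") iff n0 >= 2 or n2 >= 2 or both n1, n3 >= 2.
    """

    hybrid: int
    k: int
    counts: tuple[int, ...]
    klass: str
    cycle_nodes: tuple[int, ...] = ()
    cycle_edges: tuple[int, ...] = ()

    #: tree edge closing the cycle between the two parents (k=3 only)
    @property
    def triangle_tree_edge(self) -> Optional[int]:
        return self.cycle_edges[0] if self.k == 3 else None


def hybrid_cycles(net: Network) -> list[HybridCycleInfo]:
    """Classify every reticulation cycle of a valid level-1 network."""
    infos = []
    for h in net.hybrid_nodes():
        cyc = _hybrid_cycle(net, h)
        if cyc is None:
            raise NetworkError(f"hybrid {h} has no closed cycle (not level-1?)")
        nodes, eids = cyc
        k = len(nodes)
        counts = tuple(_subtree_taxa(net, v, set(eids)) for v in nodes)
        infos.append(HybridCycleInfo(h, k, counts, _classify(k, counts),
                                     tuple(nodes), tuple(eids)))
    return infos


def _subtree_taxa(net: Network, v: int, cycle_eids: set[int]) -> int:
    count = 0
    seen = {v}
    stack = [v]
    while stack:
        x = stack.pop()
        if net.names[x] is not None:
            count += 1
        for e in net.incident(x):
            if e.id in cycle_eids:
                continue
            y = e.other(x)
            if y not in seen:
                seen.add(y)
                stack.append(y)
    return count


def _classify(k: int, counts: tuple[int, ...]) -> str:
    if k == 2:
        return "cycle2"
    if k == 3:
        return "triangle_good" if all(c >= 2 for c in counts) else "triangle_other"
    if k == 4:
        n0, n1, n2, n3 = counts  # parents: n0, n2; opposite: n1; hybrid: n3
        if n0 >= 2 or n2 >= 2 or (n1 >= 2 and n3 >= 2):
            return "diamond_good"
        if n1 >= 2:
            return "diamond_bad_I"
        if n3 >= 2:
            return "diamond_bad_II"
        return "diamond_good"  # all subtrees single taxa: n = 4
    return "k5plus"


def root_with_outgroup(net: Network, taxon: str) -> RootedNetwork:
    """Root on the outgroup's external edge; errors if a hybrid forbids it."""
    return net.rooted(outgroup=taxon)


def major_tree(net: Network) -> Network:
    """The tree left by deleting the minor hybrid edge at each reticulation."""
    out = net.copy()
    while out.hybrid_nodes():
        h = out.hybrid_nodes()[0]
        _emaj, emin = out.hybrid_parents(h)
        e = out.edges[emin.id]
        out.remove_edge(e.id)
        keep = out.edges[[i for i in out._adj[h]
                          if out.edges[i].hybrid and out.edges[i].v == h][0]]
        keep.hybrid = False
        keep.gamma = None
        keep.major = True
        out.cleanup()
    out.cleanup()
    return out


# ---------------------------------------------------------------------------
# identifiability constraints and the optimizer's parameter map
# ---------------------------------------------------------------------------

def bad_diamond_reparam(gamma: float, t_minor: float, t_major: float
                        ) -> tuple[float, float]:
    """The two identifiable combinations of a bad diamond I:
    ``(gamma (1 - exp(-t_minor)), (1 - gamma)(1 - exp(-t_major)))``."""
    return (gamma * (1.0 - math.exp(-t_minor)),
            (1.0 - gamma) * (1.0 - math.exp(-t_major)))


@dataclass
class ParameterMap:
    """Free parameters of a constrained network, as one flat vector.

    Entries are ``('t', edge_id)`` for a free internal branch length,
    ``('gamma', hybrid_node)`` for an inheritance probability, and
    ``('t_pair', (edge_id, edge_id))`` for the shared length of a bad
    diamond I's two cycle tree edges (whose two identifiable combinations
    gamma(1-e^-t0) and (1-gamma)(1-e^-t1) are spanned exactly by forcing
    t0 = t1).  Edges pinned to 0 by the constraints — and hybrid edges whose
    length cannot affect CFs because a single lineage traverses them — are
    listed separately.
    """

    entries: list[tuple] = field(default_factory=list)
    pinned: list[int] = field(default_factory=list)

    def bounds(self) -> list[tuple[float, float]]:
        return [(0.0, 1.0) if kind == "gamma" else (0.0, TMAX)
                for kind, _ in self.entries]

    def get_vector(self, net: Network) -> list[float]:
        vec = []
        for kind, ref in self.entries:
            if kind == "t":
                t = net.edges[ref].length
                vec.append(DEFAULT_INTERNAL_LENGTH if t is None else min(t, TMAX))
            elif kind == "gamma":
                _maj, emin = net.hybrid_parents(ref)
                vec.append(0.1 if emin.gamma is None else emin.gamma)
            elif kind == "t_pair":
                ts = [net.edges[eid].length for eid in ref
                      if net.edges[eid].length is not None]
                vec.append(min(sum(ts) / len(ts), TMAX) if ts
                           else DEFAULT_INTERNAL_LENGTH)
        return vec

    def set_vector(self, net: Network, vec) -> None:
        for (kind, ref), x in zip(self.entries, vec):
            if kind == "t":
                net.edges[ref].length = max(0.0, float(x))
            elif kind == "gamma":
                g = min(1.0, max(0.0, float(x)))
                emaj, emin = net.hybrid_parents(ref)
                emin.gamma = g
                emaj.gamma = 1.0 - g
            elif kind == "t_pair":
                for eid in ref:
                    net.edges[eid].length = max(0.0, float(x))


def apply_identifiability_constraints(net: Network
                                      ) -> tuple[Network, ParameterMap]:
    """Pin or merge the parameters that quartet CFs cannot separate.

    Hybrid edges traversed by a single sampled lineage (hybrid node with one
    descendant taxon) get length 0 and are never optimized, like external
    edges: one lineage cannot coalesce, so those lengths cannot move any CF.
    Per cycle class: good triangle — the cycle's tree edge between the two
    parents is set to 0; bad diamond I — only gamma(1-e^-t0) and
    (1-gamma)(1-e^-t1) are identifiable (t0/t1 the cycle tree edges on the
    minor/major side), spanned exactly by forcing t0 = t1; bad diamond II —
    the tree edge below the hybrid node is set to 0.  Networks with a
    2-cycle or a non-good triangle are rejected: those reticulations are
    undetectable or unidentifiable and excluded from the search space.
    """
    out = net.copy()
    pmap = ParameterMap()
    pinned: set[int] = set()
    paired: set[int] = set()

    infos = hybrid_cycles(out)
    for info in infos:
        if info.klass in ("cycle2", "triangle_other"):
            raise IdentifiabilityError(
                f"hybrid {info.hybrid} forms a {info.klass} reticulation, "
                "which is not identifiable and not searchable")
        pmap.entries.append(("gamma", info.hybrid))
        emaj, emin = out.hybrid_parents(info.hybrid)
        if info.counts[-1] == 1:  # single lineage through the hybrid edges
            for e in (emaj, emin):
                e.length = 0.0
                pinned.add(e.id)
                pmap.pinned.append(e.id)
        if info.klass == "triangle_good":
            eid = info.triangle_tree_edge
            out.edges[eid].length = 0.0
            pinned.add(eid)
            pmap.pinned.append(eid)
        elif info.klass == "diamond_bad_I":
            # cycle edges run major parent - opposite - minor parent, then
            # the two hybrid edges; the tree edges are the first two
            e_majside = out.edges[info.cycle_edges[0]]
            e_minside = out.edges[info.cycle_edges[1]]
            pmap.entries.append(("t_pair", (e_majside.id, e_minside.id)))
            paired.update((e_majside.id, e_minside.id))
            # canonicalize to equal tree-edge lengths preserving the two
            # identifiable combinations
            if e_majside.length is not None and e_minside.length is not None \
                    and emin.gamma is not None:
                u, v = bad_diamond_reparam(emin.gamma, e_minside.length,
                                           e_majside.length)
                s = min(u + v, 1.0 - 1e-12)
                t = -math.log(1.0 - s)
                g = u / s if s > 0 else 0.5
                e_majside.length = e_minside.length = t
                emin.gamma, emaj.gamma = g, 1.0 - g
        elif info.klass == "diamond_bad_II":
            eid = out.hybrid_child_edge(info.hybrid).id
            out.edges[eid].length = 0.0
            pinned.add(eid)
            pmap.pinned.append(eid)

    leafset = set(out.leaves().values())
    for eid in sorted(out.edges):
        e = out.edges[eid]
        if e.u in leafset or e.v in leafset:
            continue  # external edges are not identifiable, never optimized
        if eid in pinned or eid in paired:
            continue
        pmap.entries.append(("t", eid))
    return out, pmap


# ---------------------------------------------------------------------------
# induced subnetworks and topology comparison
# ---------------------------------------------------------------------------

def induced_subnetwork(net: Network, taxa: Iterable[str]) -> Network:
    """Restriction of the network to a subset of its taxa.

    Other leaves are pruned; reticulations whose hybrid node loses all its
    descendants disappear; degree-2 pass-through nodes are suppressed with
    lengths summed where the merge is representable.  The result preserves
    the expected quartet CFs of the original network on the kept taxa.
    """
    keep = set(taxa)
    leaves = net.leaves()
    missing = keep - set(leaves)
    if missing:
        raise NetworkError(f"taxa not in leaf set: {sorted(missing)}")
    out = net.copy()
    for name, v in out.leaves().items():
        if name not in keep:
            out.remove_node(v)
    out.cleanup()
    return out


def to_multigraph(net: Network, mode: str = "semi"):
    """networkx MultiGraph encoding for isomorphism tests.

    mode 'semi' keeps hybrid-node and hybrid-edge marks (which determine the
    hybrid-edge directions of a valid network); 'unrooted' drops them.
    """
    import networkx as nx

    g = nx.MultiGraph()
    hybrids = set(net.hybrid_nodes()) if mode == "semi" else set()
    for v in net.nodes():
        g.add_node(v, label=net.names[v] or "", hybrid=v in hybrids)
    for e in net.edges.values():
        g.add_edge(e.u, e.v, hybrid=e.hybrid if mode == "semi" else False)
    return g


def same_topology(a: Network, b: Network, mode: str = "semi",
                  labeled: bool = True) -> bool:
    """Isomorphism of two networks as leaf-labeled (multi)graphs.

    mode 'semi' compares semi-directed topologies (hybrid directions
    included); 'unrooted' ignores which edges are hybrid.  ``labeled=False``
    compares shapes up to relabeling of tips.
    """
    import networkx as nx
    from networkx.algorithms import isomorphism as iso

    ga, gb = to_multigraph(a, mode), to_multigraph(b, mode)
    if ga.number_of_nodes() != gb.number_of_nodes() \
            or ga.number_of_edges() != gb.number_of_edges():
        return False

    if labeled:
        def nm(x, y):
            return x["label"] == y["label"] and x["hybrid"] == y["hybrid"]
    else:
        def nm(x, y):
            return bool(x["label"]) == bool(y["label"]) \
                and x["hybrid"] == y["hybrid"]

    def em(xs, ys):
        return sorted(d["hybrid"] for d in xs.values()) \
            == sorted(d["hybrid"] for d in ys.values())

    gm = iso.MultiGraphMatcher(ga, gb, node_match=nm, edge_match=em)
    return gm.is_isomorphic()
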