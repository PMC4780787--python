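"""Heuristic search over semi-directed level-1 network space.

Hill-climbing from a starting tree, proposing one of five moves chosen
uniformly among those currently legal: (1) move the origin of a hybrid
edge, (2) move its target, (3) flip the direction of a hybrid edge,
(4) a nearest-neighbor interchange on a tree edge, (5) add a hybridization
while h < h_max.  Every proposal must remain a semi-directed level-1
network with an admissible reticulation class (2-cycles and non-good
triangles are unidentifiable and excluded) and at least one valid root
placement.  A proposal is accepted when its optimized pseudolikelihood
improves the current score by more than the tolerance; hybridization
deletion is never proposed directly but happens when the optimizer drives
an inheritance probability to 0 (the hybrid edge is removed, re-attachment
is attempted in the neighborhood of its old position, and failing that the
reticulation is dropped).  A branch length optimized to 0 triggers an
immediate NNI attempt on that branch.  A run stops after a fixed number of
consecutive failed proposals; several independent runs are performed and
the best network returned.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .cftables import QuartetCFTable
from .network import (
    IdentifiabilityError,
    Network,
    NetworkError,
    hybrid_cycles,
    validate_level1,
)
from .pseudolik import OptimResult, optimize_parameters

__all__ = [
    "SearchConfig",
    "SearchResult",
    "starter_tree",
    "propose_move",
    "is_searchable",
    "handle_boundary",
    "snaq_search",
]


def starter_tree(table: QuartetCFTable) -> Network:
    """A quick quartet-based starting tree: neighbor joining on the
    CF-derived dissimilarity d(a, b) = mean over 4-taxon sets containing a
    and b of 1 - CF(split pairing a with b)."""
    from skbio import DistanceMatrix
    from skbio.tree import nj

    from .network import parse_enewick

    taxa = table.taxa
    idx = {t: i for i, t in enumerate(taxa)}
    n = len(taxa)
    tot = np.zeros((n, n))
    cnt = np.zeros((n, n))
    for r in table.records:
        for q, (i, j) in enumerate(((0, 1), (0, 2), (0, 3))):
            a, b = r.taxa[i], r.taxa[j]
            c, d = [t for k, t in enumerate(r.taxa) if k not in (i, j)]
            for x, y in ((a, b), (c, d)):
                ii, jj = idx[x], idx[y]
                tot[ii, jj] += 1.0 - r.cf[q]
                tot[jj, ii] += 1.0 - r.cf[q]
                cnt[ii, jj] += 1
                cnt[jj, ii] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(cnt > 0, tot / np.maximum(cnt, 1), 1.0)
    np.fill_diagonal(d, 0.0)
    tree = nj(DistanceMatrix(d, ids=taxa))
    net = parse_enewick(str(tree).strip())
    for e in net.edges.values():
        e.length = None if e.length is None else max(e.length, 0.0)
    return net

ALLOWED_CLASSES = {"triangle_good", "diamond_good", "diamond_bad_I",
                   "diamond_bad_II", "k5plus"}


@dataclass
class SearchConfig:
    """Knobs of the network search."""

    h_max: int = 1
    runs: int = 10
    seed: Optional[int] = 0
    max_failures: int = 30          # consecutive rejected proposals per run
    ftol: float = 1e-6              # score improvement needed to accept
    gamma_tol: float = 1e-4
    t_tol: float = 1e-4
    restarts: int = 1               # optimizer restarts per proposal
    opt_xtol: float = 1e-4
    opt_ftol: float = 1e-6
    maxfev: Optional[int] = None
    fractional: bool = False
    move_weights: Optional[dict[str, float]] = None

    def __post_init__(self):
        if self.h_max < 0:
            raise ValueError("h_max must be >= 0")
        if self.runs < 1:
            raise ValueError("need at least one run")


@dataclass
class SearchResult:
    """Best network over all runs, with per-run traces."""

    network: Network
    score: float
    traces: list[list[tuple]] = field(default_factory=list)  # (step, move, accepted, score)
    run_seeds: list[int] = field(default_factory=list)
    run_scores: list[float] = field(default_factory=list)


# ---------------------------------------------------------------------------
# structural moves
# ---------------------------------------------------------------------------

def _internal_tree_edges(net: Network) -> list[int]:
    leaves = set(net.leaves().values())
    return [e.id for e in net.edges.values()
            if not e.hybrid and e.u not in leaves and e.v not in leaves]


def _nni(net: Network, rng, eid: Optional[int] = None) -> Optional[Network]:
    cands = _internal_tree_edges(net)
    if not cands:
        return None
    if eid is None:
        eid = cands[int(rng.integers(len(cands)))]
    out = net.copy()
    e = out.edges[eid]
    at_u = [i for i in out._adj[e.u] if i != eid]
    at_v = [i for i in out._adj[e.v] if i != eid]
    if len(at_u) != 2 or len(at_v) != 2:
        return None
    eu = out.edges[at_u[int(rng.integers(2))]]
    ev = out.edges[at_v[int(rng.integers(2))]]
    # swap one subtree across the edge
    for moved, frm, to in ((eu, e.u, e.v), (ev, e.v, e.u)):
        if moved.u == frm:
            moved.u = to
        else:
            moved.v = to
        out._adj[frm].remove(moved.id)
        out._adj[to].append(moved.id)
    return out


def _move_origin(net: Network, rng) -> Optional[Network]:
    hybrids = net.hybrid_nodes()
    if not hybrids:
        return None
    out = net.copy()
    h = hybrids[int(rng.integers(len(hybrids)))]
    emaj, emin = out.hybrid_parents(h)
    e = (emaj, emin)[int(rng.integers(2))]
    o, length, gamma, major = e.u, e.length, e.gamma, e.major
    out.remove_edge(e.id)
    try:
        out.suppress_node(o)
    except NetworkError:
        return None
    targets = [i for i in sorted(out.edges)]
    f = targets[int(rng.integers(len(targets)))]
    o2 = out.subdivide(f, float(rng.uniform(0.2, 0.8)))
    out.add_edge(o2, h, length, hybrid=True, gamma=gamma, major=major)
    return out


def _move_target(net: Network, rng) -> Optional[Network]:
    hybrids = net.hybrid_nodes()
    if not hybrids:
        return None
    out = net.copy()
    h = hybrids[int(rng.integers(len(hybrids)))]
    emaj, emin = out.hybrid_parents(h)
    e = (emaj, emin)[int(rng.integers(2))]
    partner = emin if e is emaj else emaj
    o, length, gamma = e.u, e.length, e.gamma
    out.remove_edge(e.id)
    partner = out.edges[partner.id]
    partner.hybrid, partner.gamma, partner.major = False, None, True
    try:
        out.suppress_node(h)
    except NetworkError:
        return None
    if o not in out._adj:  # origin vanished with the suppression
        return None
    targets = [i for i in sorted(out.edges) if i not in out._adj[o]]
    if not targets:
        return None
    g = targets[int(rng.integers(len(targets)))]
    h2 = out.subdivide(g, float(rng.uniform(0.2, 0.8)))
    pieces = [pe for pe in out.incident(h2)]
    part = pieces[int(rng.integers(2))]
    if part.hybrid:
        return None
    part.hybrid = True
    part.gamma = None if gamma is None else 1.0 - gamma
    part.major = True
    if part.v != h2:
        part.u, part.v = part.v, part.u
    out.add_edge(o, h2, length, hybrid=True, gamma=gamma, major=False)
    _renormalize_majors(out, h2)
    return out


def _flip_direction(net: Network, rng) -> Optional[Network]:
    hybrids = net.hybrid_nodes()
    if not hybrids:
        return None
    out = net.copy()
    h = hybrids[int(rng.integers(len(hybrids)))]
    emaj, emin = out.hybrid_parents(h)
    e = (emaj, emin)[int(rng.integers(2))]
    partner = emin if e is emaj else emaj
    p = e.u
    # the flipped edge now points into p; p's other edges are candidates for
    # the second hybrid parent of p
    others = [out.edges[i] for i in out._adj[p] if i != e.id]
    others = [x for x in others if not x.hybrid]
    if not others:
        return None
    new_partner = others[int(rng.integers(len(others)))]
    e.u, e.v = h, p
    partner = out.edges[partner.id]
    partner.hybrid, partner.gamma, partner.major = False, None, True
    new_partner.hybrid = True
    new_partner.gamma = None if e.gamma is None else 1.0 - e.gamma
    if new_partner.v != p:
        new_partner.u, new_partner.v = new_partner.v, new_partner.u
    _renormalize_majors(out, p)
    return out


def _renormalize_majors(net: Network, h: int) -> None:
    es = [e for e in net.incident(h) if e.hybrid and e.v == h]
    if len(es) != 2:
        return
    g0 = es[0].gamma
    if g0 is None:
        es[0].major, es[1].major = True, False
    else:
        es[0].major = g0 >= 0.5
        es[1].major = not es[0].major


def _add_hybridization(net: Network, rng, gamma: float = 0.1,
                       length: float = 1.0,
                       pair: Optional[tuple[int, int]] = None
                       ) -> Optional[Network]:
    out = net.copy()
    eids = sorted(out.edges)
    if len(eids) < 2:
        return None
    if pair is None:
        i, k = rng.choice(len(eids), size=2, replace=False)
        eo, et = eids[int(i)], eids[int(k)]
    else:
        eo, et = pair
        if eo == et or eo not in out.edges or et not in out.edges:
            return None
    mo = out.subdivide(eo, float(rng.uniform(0.2, 0.8)))
    mt = out.subdivide(et, float(rng.uniform(0.2, 0.8)))
    pieces = [e for e in out.incident(mt)]
    part = pieces[int(rng.integers(2))]
    if part.hybrid:
        return None
    part.hybrid = True
    part.gamma = 1.0 - gamma
    part.major = True
    if part.v != mt:
        part.u, part.v = part.v, part.u
    out.add_edge(mo, mt, length, hybrid=True, gamma=gamma, major=False)
    return out


_MOVES = {
    "origin": _move_origin,
    "target": _move_target,
    "flip": _flip_direction,
    "nni": _nni,
    "add": _add_hybridization,
}


def propose_move(net: Network, rng, h_max: int,
                 weights: Optional[dict[str, float]] = None,
                 max_tries: int = 20) -> tuple[Network, str]:
    """One random candidate differing from ``net`` by a single move.

    The move type is drawn uniformly (or by ``weights``) among the types
    legal in the current state; a type whose random instantiation fails
    structurally is resampled.
    """
    legal = ["nni"]
    if net.h >= 1:
        legal += ["origin", "target", "flip"]
    if net.h < h_max:
        legal.append("add")
    w = np.array([1.0 if weights is None else weights.get(m, 1.0)
                  for m in legal])
    w = w / w.sum()
    for _ in range(max_tries):
        tag = legal[int(rng.choice(len(legal), p=w))]
        cand = _MOVES[tag](net, rng)
        if cand is not None:
            return cand, tag
    raise RuntimeError("no structurally valid move found")


def is_searchable(net: Network, h_max: int) -> tuple[bool, str]:
    """Whether a candidate lies in the searched space: valid level-1, at
    most h_max reticulations, a valid rooting, and only identifiable cycle
    classes (good triangles, diamonds, k >= 5)."""
    errors = validate_level1(net)
    if errors:
        return False, errors[0]
    if net.h > h_max:
        return False, f"h = {net.h} exceeds h_max = {h_max}"
    try:
        infos = hybrid_cycles(net)
    except NetworkError as exc:
        return False, str(exc)
    for info in infos:
        if info.klass not in ALLOWED_CLASSES:
            return False, (f"hybrid {info.hybrid} forms a {info.klass} "
                           "cycle (unidentifiable)")
    return True, ""


# ---------------------------------------------------------------------------
# boundary handling and the hill climb
# ---------------------------------------------------------------------------

def _optimize(net: Network, table: QuartetCFTable, cfg: SearchConfig,
              seed, restarts: Optional[int] = None,
              init: bool = False) -> Optional[OptimResult]:
    try:
        return optimize_parameters(
            net, table, restarts=cfg.restarts if restarts is None else restarts,
            xtol=cfg.opt_xtol, ftol=cfg.opt_ftol, gamma_tol=cfg.gamma_tol,
            t_tol=cfg.t_tol, maxfev=cfg.maxfev, seed=seed,
            fractional=cfg.fractional, init=init)
    except (IdentifiabilityError, NetworkError, ValueError):
        return None


def _neighbor_edges(net: Network, nodes) -> list[int]:
    out: set[int] = set()
    for v in nodes:
        if v in net._adj:
            for eid in net._adj[v]:
                out.add(eid)
                e = net.edges[eid]
                for w in (e.u, e.v):
                    out.update(net._adj[w])
    return sorted(out)


def handle_boundary(net: Network, optres: OptimResult,
                    table: QuartetCFTable, cfg: SearchConfig, rng,
                    current_score: float
                    ) -> tuple[Network, OptimResult, list[str]]:
    """React to parameter estimates on the boundary.

    gamma ~ 0 (or ~1): the unused hybrid edge is removed; re-attachment is
    attempted at random among edge pairs in the neighborhood of its old
    endpoints, keeping the first searchable improvement over the current
    score, otherwise the reticulation is deleted for good.
    """
    log: list[str] = []
    work, res = optres.network, optres
    for h in list(optres.boundary_gamma):
        if h not in work._adj:
            continue
        try:
            emaj, emin = work.hybrid_parents(h)
        except NetworkError:
            continue
        drop = emin if (emin.gamma or 0.0) <= (emaj.gamma or 1.0) else emaj
        gamma_used = 0.1
        pruned = work.copy()
        old_o, old_h = drop.u, drop.v
        pruned.remove_edge(drop.id)
        keep = [e for e in pruned.incident(h) if e.hybrid and e.v == h]
        for e in keep:
            e.hybrid, e.gamma, e.major = False, None, True
        pruned.cleanup()
        log.append(f"gamma at 0: removed hybrid edge {drop.id} at node {h}")
        # try re-attachment in the neighborhood of the old endpoints
        nbrs = _neighbor_edges(pruned, [old_o, old_h])
        pairs = [(a, b) for a in nbrs for b in nbrs if a != b]
        if pairs:
            order = rng.permutation(len(pairs))
        else:
            order = []
        reattached = False
        for idx in order:
            a, b = pairs[int(idx)]
            cand = _add_hybridization(pruned, rng, gamma=gamma_used,
                                      pair=(a, b))
            if cand is None:
                continue
            ok, _why = is_searchable(cand, cfg.h_max)
            if not ok:
                continue
            cres = _optimize(cand, table, cfg, seed=int(rng.integers(2**31)))
            if cres is None or cres.boundary_gamma:
                continue
            if cres.score.value > current_score + cfg.ftol:
                work, res = cres.network, cres
                log.append(f"re-attached hybridization on edges ({a}, {b})")
                reattached = True
                break
        if not reattached:
            pres = _optimize(pruned, table, cfg, seed=int(rng.integers(2**31)))
            if pres is not None:
                work, res = pres.network, pres
                log.append("hybridization deleted entirely")
    return work, res, log


def snaq_search(table: QuartetCFTable, start_tree: Network,
                config: SearchConfig) -> SearchResult:
    """Multi-run hill climb for the maximum-pseudolikelihood network."""
    if not table.records:
        raise ValueError("CF table holds no 4-taxon set")
    missing = set(table.taxa) - set(start_tree.taxa())
    if missing:
        raise ValueError(f"start tree lacks taxa {sorted(missing)}")
    ok, why = is_searchable(start_tree, config.h_max)
    if not ok:
        raise ValueError(f"start topology not searchable: {why}")

    seed_seq = np.random.SeedSequence(config.seed)
    run_seeds = [int(s.generate_state(1)[0] % (2**31))
                 for s in seed_seq.spawn(config.runs)]

    best_net, best_score = None, -np.inf
    traces, run_scores = [], []
    from .pseudolik import init_branch_lengths

    start = init_branch_lengths(start_tree, table)
    for seed in run_seeds:
        rng = np.random.default_rng(seed)
        # first optimization gets extra starts; later ones re-optimize from
        # the carried-over parameter values of the current network
        cur = _optimize(start, table, config,
                        seed=int(rng.integers(2**31)),
                        restarts=max(config.restarts, 3))
        if cur is None:
            raise ValueError("pseudolikelihood undefined on the start tree")
        cur_net, cur_score = cur.network, cur.score.value
        trace = [(0, "start", True, cur_score)]
        fails = 0
        step = 0
        forced_nni: list[int] = list(cur.boundary_t)
        while fails < config.max_failures:
            step += 1
            if forced_nni:
                eid = forced_nni.pop()
                cand = (_nni(cur_net, rng, eid)
                        if eid in cur_net.edges else None)
                tag = "nni(t=0)"
                if cand is None:
                    continue
            else:
                try:
                    cand, tag = propose_move(cur_net, rng, config.h_max,
                                             config.move_weights)
                except RuntimeError:
                    fails += 1
                    continue
            ok, _why = is_searchable(cand, config.h_max)
            if not ok:
                fails += 1
                trace.append((step, tag, False, cur_score))
                continue
            res = _optimize(cand, table, config,
                            seed=int(rng.integers(2**31)))
            if res is None:
                fails += 1
                trace.append((step, tag, False, cur_score))
                continue
            net2, res2 = res.network, res
            if res.boundary_gamma:
                net2, res2, _blog = handle_boundary(
                    cand, res, table, config, rng, cur_score)
            if res2.score.value > cur_score + config.ftol:
                ok2, why2 = is_searchable(net2, config.h_max)
                if not ok2:  # every accepted state must stay in the space
                    raise RuntimeError(
                        f"accepted state left the search space: {why2}")
                cur_net, cur_score = net2, res2.score.value
                forced_nni = list(res2.boundary_t)
                fails = 0
                trace.append((step, tag, True, cur_score))
            else:
                fails += 1
                trace.append((step, tag, False, cur_score))
        traces.append(trace)
        run_scores.append(cur_score)
        if cur_score > best_score:
            best_net, best_score = cur_net, cur_score
    return SearchResult(best_net, best_score, traces, run_seeds, run_scores)
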