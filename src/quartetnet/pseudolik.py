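"""Network pseudolikelihood and fixed-topology parameter optimization.

The pseudolikelihood of a network multiplies, over all sampled 4-taxon
sets s, the multinomial probability of the observed quartet counts
(X_q1, X_q2, X_q3) under the expected CFs of the 4-taxon subnetwork on s:

    log L = sum_s sum_i X_qi(s) log CF_qi(s)

(the multinomial coefficient is a data constant and omitted).  Branch
lengths and inheritance probabilities are optimized for a fixed topology
with a bound-constrained derivative-free local search, over the free
parameters left by the identifiability constraints (good-triangle and
bad-diamond-II edges pinned to zero, bad-diamond-I hybrid-edge lengths
merged).  Estimates on the boundary (gamma at 0 or 1, branch lengths at 0)
are flagged for the topology search to act on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import minimize

from .cftables import QuartetCFTable
from .network import (
    DEFAULT_INTERNAL_LENGTH,
    TMAX,
    Network,
    ParameterMap,
    apply_identifiability_constraints,
)
from .quartetcf import CFEvaluator

__all__ = [
    "PLScore",
    "OptimResult",
    "log_pseudolik",
    "init_branch_lengths",
    "optimize_parameters",
]

CF_CLAMP = 1e-12


@dataclass
class PLScore:
    """Log pseudolikelihood with its per-4-taxon-set contributions."""

    value: float
    per_set: list[float] = field(default_factory=list)


@dataclass
class OptimResult:
    """Optimized parameters for a fixed topology."""

    network: Network
    pmap: ParameterMap
    score: PLScore
    x: np.ndarray
    boundary_gamma: list[int] = field(default_factory=list)  # hybrid nodes
    boundary_t: list[int] = field(default_factory=list)      # edge ids
    converged: bool = True
    n_eval: int = 0


def _count_matrix(table: QuartetCFTable, fractional: bool) -> np.ndarray:
    return np.array([r.counts(fractional=fractional) for r in table.records],
                    dtype=float)


def _check_taxa(net: Network, table: QuartetCFTable) -> None:
    missing = set(table.taxa) - set(net.taxa())
    if missing:
        raise ValueError(f"table taxa not in network: {sorted(missing)}")


def log_pseudolik(net: Network, table: QuartetCFTable,
                  fractional: bool = False) -> PLScore:
    """Eq-style network score: sum over sets of X_qi log CF_qi, with
    expected CFs clamped below at 1e-12."""
    _check_taxa(net, table)
    ev = CFEvaluator(net, [r.taxa for r in table.records])
    cfs = np.maximum(np.array(ev.evaluate()), CF_CLAMP)
    x = _count_matrix(table, fractional)
    per = (x * np.log(cfs)).sum(axis=1)
    return PLScore(float(per.sum()), per.tolist())


# ---------------------------------------------------------------------------
# branch-length initialization from average observed CFs
# ---------------------------------------------------------------------------

def _reachable(net: Network, start_edge, from_node: int) -> set[str]:
    """Taxa reachable from ``from_node`` without crossing ``start_edge``."""
    seen = {from_node}
    out = set()
    stack = [from_node]
    while stack:
        v = stack.pop()
        nm = net.names.get(v)
        if nm is not None:
            out.add(nm)
        for e in net.incident(v):
            if e.id == start_edge.id:
                continue
            w = e.other(v)
            if w not in seen:
                seen.add(w)
                stack.append(w)
    return out


def init_branch_lengths(net: Network, table: QuartetCFTable,
                        consistent_inversion: bool = False,
                        tmin: float = 1e-10, tmax: float = TMAX) -> Network:
    """Initialize internal branch lengths from the data, in place-free form.

    For each internal edge, CF-bar averages the observed CF of the split
    matching that edge over the quartets that span it exactly (one taxon
    from each of the four subtrees at its endpoints).  The default applies
    the transform t = -log(1 - 3/2 CF-bar), clamped to [tmin, tmax] (CF-bar
    >= 2/3 maps to tmax); ``consistent_inversion`` uses the tree-CF
    inversion t = -log(3/2 (1 - CF-bar)) instead.  Uncovered edges get the
    default length 1.  Initialization only: the optimizer refines all free
    lengths afterwards.
    """
    _check_taxa(net, table)
    out = net.copy()
    by_set = {r.taxa: r for r in table.records}
    leafset = set(out.leaves().values())
    for e in out.edges.values():
        if e.u in leafset or e.v in leafset:
            continue
        groups_u = [_reachable(out, e, ne.other(e.u))
                    for ne in out.incident(e.u) if ne.id != e.id]
        groups_v = [_reachable(out, e, ne.other(e.v))
                    for ne in out.incident(e.v) if ne.id != e.id]
        if len(groups_u) != 2 or len(groups_v) != 2:
            if e.length is None:
                e.length = DEFAULT_INTERNAL_LENGTH
            continue
        vals = []
        for r in by_set.values():
            taxa = set(r.taxa)
            assign = []
            ok = True
            for grp in (*groups_u, *groups_v):
                cand = taxa & grp
                assign.append(cand)
            # need a system of distinct representatives, one per group,
            # exactly covering the 4 taxa; greedy works for 4 small sets
            pick: list[str] = []
            for cand in sorted(assign, key=len):
                free = cand - set(pick)
                if not free:
                    ok = False
                    break
                pick.append(sorted(free)[0])
            if not ok or len(set(pick)) != 4:
                continue
            # the split induced by e pairs the two u-side groups
            uside = sorted(taxa & (groups_u[0] | groups_u[1]))
            if len(uside) != 2:
                continue
            i, j = sorted(r.taxa.index(t) for t in uside)
            if (i, j) == (0, 1) or (i, j) == (2, 3):
                q = 0
            elif (i, j) == (0, 2) or (i, j) == (1, 3):
                q = 1
            else:
                q = 2
            vals.append(r.cf[q])
        if not vals:
            if e.length is None:
                e.length = DEFAULT_INTERNAL_LENGTH
            continue
        cfbar = sum(vals) / len(vals)
        if consistent_inversion:
            arg = 1.5 * (1.0 - cfbar)
        else:
            arg = 1.0 - 1.5 * cfbar
        t = tmax if arg <= 0 else -math.log(arg)
        e.length = min(max(t, tmin), tmax)
    return out


# ---------------------------------------------------------------------------
# derivative-free optimization
# ---------------------------------------------------------------------------

def optimize_parameters(topology: Network, table: QuartetCFTable, *,
                        restarts: int = 3,
                        xtol: float = 1e-4,
                        ftol: float = 1e-6,
                        gamma_tol: float = 1e-4,
                        t_tol: float = 1e-4,
                        maxfev: Optional[int] = None,
                        seed: Optional[int] = 0,
                        fractional: bool = False,
                        init: bool = True) -> OptimResult:
    """Maximize the pseudolikelihood over branch lengths and gammas.

    Derivative-free bound-constrained local search (adaptive Nelder-Mead)
    over the free parameters of the identifiability-constrained topology,
    restarted from jittered points; deterministic given the seed and
    tolerances.
    """
    _check_taxa(topology, table)
    work = topology
    if init:
        work = init_branch_lengths(work, table)
    net, pmap = apply_identifiability_constraints(work)
    x0 = np.array(pmap.get_vector(net), dtype=float)
    bounds = pmap.bounds()
    ev = CFEvaluator(net, [r.taxa for r in table.records])
    x_counts = _count_matrix(table, fractional)
    n_eval = 0

    def objective(theta: np.ndarray) -> float:
        nonlocal n_eval
        n_eval += 1
        pmap.set_vector(net, np.clip(theta, [b[0] for b in bounds],
                                     [b[1] for b in bounds]))
        cfs = np.maximum(np.array(ev.evaluate()), CF_CLAMP)
        return -float((x_counts * np.log(cfs)).sum())

    if not np.isfinite(objective(x0)):
        # re-initialize once from defaults, then give up
        x0 = np.array([0.1 if k == "gamma" else DEFAULT_INTERNAL_LENGTH
                       for k, _ in pmap.entries])
        if not np.isfinite(objective(x0)):
            raise ValueError("non-finite pseudolikelihood at the start point")

    rng = np.random.default_rng(seed)
    best = None
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    interior = np.array([0.1 if k == "gamma" else DEFAULT_INTERNAL_LENGTH
                         for k, _ in pmap.entries])
    starts = [x0]
    if restarts >= 2:
        starts.append(interior)
    for _ in range(max(0, restarts - 2)):
        draw = np.array([rng.uniform(0.0, 1.0) if k == "gamma"
                         else rng.uniform(0.0, 2.0)
                         for k, _ in pmap.entries])
        starts.append(np.clip(draw, lo, hi))
    options = {"xatol": xtol, "fatol": ftol, "adaptive": True}
    if maxfev is not None:
        options["maxfev"] = maxfev
    converged = True
    if len(x0):
        for s in starts:
            res = minimize(objective, s, method="Nelder-Mead", bounds=bounds,
                           options=options)
            if best is None or res.fun < best.fun:
                best = res
        xbest = np.clip(best.x, [b[0] for b in bounds],
                        [b[1] for b in bounds])
        converged = bool(best.success)
    else:
        xbest = x0
    final = -objective(xbest)
    pmap.set_vector(net, xbest)

    bgamma, bt = [], []
    for (kind, ref), val in zip(pmap.entries, xbest):
        if kind == "gamma" and (val < gamma_tol or val > 1.0 - gamma_tol):
            bgamma.append(ref)
        elif kind == "t" and val < t_tol:
            bt.append(ref)
    per = log_pseudolik(net, table, fractional=fractional).per_set
    return OptimResult(net, pmap, PLScore(final, per), xbest,
                       bgamma, bt, converged, n_eval)
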