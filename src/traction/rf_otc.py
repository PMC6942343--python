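"""RF-optimal tree completion: graft the reference tree's extra taxa.

The reference tree T is cut along its backbone (edges on paths between taxa
shared with the gene tree); the hanging components carrying missing taxa are
the superleaves.  A superleaf is Type I when its attachment edge maps to a
split shared with the gene tree, Type II otherwise.  The minimum achievable
RF distance after completion is RF(T|_R, t) + 2m with m the number of Type II
superleaves; every completion produced here carries that bound as a runtime
certificate.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional

from .tree_core import (
    Bipartition,
    TreeError,
    UnrootedTree,
    bipartitions,
    restrict,
    rf_distance,
)

__all__ = [
    "Backbone",
    "Superleaf",
    "CompletionResult",
    "OptimalityError",
    "backbone",
    "classify_superleaves",
    "otc_lower_bound",
    "octal_complete",
]


class OptimalityError(RuntimeError):
    """The completion failed its own optimality certificate (internal bug)."""


@dataclass(frozen=True)
class Backbone:
    """Edges of T on a path between two leaves of R (node-id edge keys)."""

    edges: frozenset
    nodes: frozenset


@dataclass(frozen=True)
class Superleaf:
    """A component of T hanging off the backbone whose taxa are all missing
    from the gene tree."""

    taxa: frozenset
    root: int
    component: frozenset
    attachment: Bipartition  # split of T|_R at the attachment edge
    sl_type: str  # "I" or "II"


@dataclass(frozen=True)
class CompletionResult:
    completed: UnrootedTree
    m: int
    achieved_rf: int
    lower_bound: int
    superleaves: tuple = field(default=(), compare=False)

    def report(self) -> str:
        return (f"m={self.m}\nlower_bound={self.lower_bound}\n"
                f"achieved_rf={self.achieved_rf}\n")


def backbone(T: UnrootedTree, R) -> Backbone:
    """Computed by pruning: repeatedly discard non-R pendant vertices."""
    R = frozenset(R)
    missing = R - T.leaf_set
    if missing:
        raise TreeError(f"taxa not in tree: {sorted(missing)}")
    if len(R) < 2:
        raise TreeError("backbone requires at least 2 retained taxa")
    deg = {v: T.degree(v) for v in T.nodes}
    alive = set(deg)
    leaves = T.leaves()
    stack = [v for v in alive if deg[v] <= 1 and leaves.get(v) not in R]
    while stack:
        v = stack.pop()
        if v not in alive:
            continue
        alive.discard(v)
        for u in T.neighbors(v):
            if u in alive:
                deg[u] -= 1
                if deg[u] <= 1 and leaves.get(u) not in R:
                    stack.append(u)
    edges = frozenset(e for e in T.edges() if e <= alive)
    return Backbone(edges=edges, nodes=frozenset(alive))


def classify_superleaves(T: UnrootedTree, t: UnrootedTree) -> list:
    """One Superleaf per backbone-free component of T holding missing taxa.

    ``t`` must be binary (completion runs after refinement); its leaf set is
    the retained set R.
    """
    if t.is_mul or T.is_mul:
        raise TreeError("superleaf classification requires singly-labeled trees")
    if not t.is_binary:
        raise TreeError("gene tree must be binary before completion")
    R = t.leaf_set
    missing = R - T.leaf_set
    if missing:
        raise TreeError(f"gene tree taxa absent from reference: {sorted(missing)}")
    bb = backbone(T, R)
    t_bips = bipartitions(t)
    leaves = T.leaves()

    # components over non-backbone edges
    seen: set = set()
    out = []
    for start in sorted(T.nodes):
        if start in seen:
            continue
        comp = {start}
        stack = [start]
        while stack:
            v = stack.pop()
            for u in T.neighbors(v):
                if u in comp or frozenset((v, u)) in bb.edges:
                    continue
                comp.add(u)
                stack.append(u)
        seen |= comp
        taxa = frozenset(leaves[v] for v in comp if v in leaves)
        if not taxa or taxa & R:
            continue
        roots = [v for v in comp
                 if any(frozenset((v, u)) in bb.edges for u in T.neighbors(v))]
        if len(roots) != 1:
            raise TreeError("superleaf component must touch the backbone at "
                            "exactly one node")  # cannot happen for binary T
        root = roots[0]
        # both backbone edges at the root map to one edge of T|_R: the split
        # of R reachable through either backbone neighbour
        bb_nbr = next(u for u in T.neighbors(root)
                      if frozenset((root, u)) in bb.edges)
        side = set()
        stack = [bb_nbr]
        visited = {root, bb_nbr}
        while stack:
            v = stack.pop()
            lab = leaves.get(v)
            if lab in R:
                side.add(lab)
            for u in T.neighbors(v):
                if u not in visited:
                    visited.add(u)
                    stack.append(u)
        attachment = Bipartition(side, R - side)
        shared = attachment.is_trivial or attachment in t_bips
        out.append(Superleaf(
            taxa=taxa,
            root=root,
            component=frozenset(comp),
            attachment=attachment,
            sl_type="I" if shared else "II",
        ))
    out.sort(key=lambda sl: min(sl.taxa))
    return out


def otc_lower_bound(t: UnrootedTree, T: UnrootedTree) -> int:
    """RF(T|_R, t) + 2m: the minimum achievable RF after completion."""
    R = t.leaf_set
    if R == T.leaf_set:
        return rf_distance(t, T)
    sls = classify_superleaves(T, t)
    m = sum(1 for sl in sls if sl.sl_type == "II")
    return rf_distance(restrict(T, R), t) + 2 * m


def _graft(growing: UnrootedTree, edge, T: UnrootedTree,
           sl: Superleaf) -> UnrootedTree:
    """Attach a copy of the superleaf's subtree into ``edge`` of growing."""
    t = growing.copy()
    u, v = sorted(edge)
    w = t.subdivide_edge(u, v)
    leaves = T.leaves()
    # copy the component minus its root, hanging from w
    mapping = {sl.root: w}
    order = [sl.root]
    i = 0
    while i < len(order):
        x = order[i]
        i += 1
        for y in T.neighbors(x):
            if y in mapping or y not in sl.component:
                continue
            mapping[y] = t._new_node(leaves.get(y))
            t.add_edge(mapping[x], mapping[y])
            order.append(y)
    return t


def _candidate_edges(tree: UnrootedTree) -> list:
    """Edges in a deterministic order (by sorted incident leaf-set key)."""
    root = min(tree._adj)
    below, parent = tree._below_leafsets(root)
    keyed = []
    for e in tree.edges():
        u, v = sorted(e)
        child = u if parent.get(u) == v else v
        keyed.append((tuple(sorted(below[child])), e))
    keyed.sort()
    return [e for _, e in keyed]


def octal_complete(t: UnrootedTree, T: UnrootedTree) -> CompletionResult:
    """Optimal completion of binary ``t`` with the taxa of binary ``T``.

    Superleaves are processed in deterministic order; each is grafted at the
    placement minimizing the RF distance to T restricted to the leaves placed
    so far.  The Eq.-1 lower bound is asserted on the result; on the (never
    observed) event the greedy pass misses it, a bounded exhaustive pass over
    sequential placements is attempted before declaring an internal error.
    """
    if t.is_mul or T.is_mul:
        raise TreeError("completion requires singly-labeled trees")
    if not t.is_binary:
        raise TreeError("gene tree must be binary before completion")
    if not T.is_binary:
        raise TreeError("reference tree must be binary")
    R = t.leaf_set
    missing = R - T.leaf_set
    if missing:
        raise TreeError(f"gene tree taxa absent from reference: {sorted(missing)}")
    if R == T.leaf_set:
        achieved = rf_distance(t, T)
        return CompletionResult(completed=t.copy(), m=0,
                                achieved_rf=achieved, lower_bound=achieved)
    sls = classify_superleaves(T, t)
    m = sum(1 for sl in sls if sl.sl_type == "II")
    lower = rf_distance(restrict(T, R), t) + 2 * m

    growing = t.copy()
    for sl in sls:
        best = None
        best_rf = None
        placed = growing.leaf_set | sl.taxa
        ref = restrict(T, placed)
        for e in _candidate_edges(growing):
            cand = _graft(growing, e, T, sl)
            score = rf_distance(cand, ref)
            if best_rf is None or score < best_rf:
                best, best_rf = cand, score
        growing = best
    achieved = rf_distance(growing, T)
    if achieved != lower:
        growing, achieved = _exhaustive_complete(t, T, sls, lower)
        if achieved != lower:
            raise OptimalityError(
                f"completion achieved RF {achieved}, certified bound {lower}")
    return CompletionResult(completed=growing, m=m, achieved_rf=achieved,
                            lower_bound=lower, superleaves=tuple(sls))


def _exhaustive_complete(t: UnrootedTree, T: UnrootedTree, sls: list,
                         lower: int, cap: int = 2_000_000):
    """Best tree over all sequential superleaf placements (fallback path)."""
    est = 1
    ne = len(t.edges())
    for i, sl in enumerate(sls):
        ne += 2 * len(sl.taxa)
        est *= ne
        if est > cap:
            raise OptimalityError(
                "greedy completion missed its certificate and the instance "
                "is too large for exhaustive recovery")
    best = [None, None]

    def rec(growing, i):
        if i == len(sls):
            score = rf_distance(growing, restrict(T, growing.leaf_set))
            if best[1] is None or score < best[1]:
                best[0], best[1] = growing, score
            return
        for e in _candidate_edges(growing):
            rec(_graft(growing, e, T, sls[i]), i + 1)

    rec(t.copy(), 0)
    return best[0], rf_distance(best[0], T)
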