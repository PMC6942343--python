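"""Shared generators and independent brute-force oracles.

The oracles here only use the low-level graph primitives (copy, subdivide,
add edge) and the bipartition extractor; every algorithmic decision under
test (compatibility, greedy refinement, superleaf classification, placement,
bounds) is re-derived independently by enumeration.
"""

from __future__ import annotations

import itertools
import random
from collections import deque

import pytest

from traction import tree_core as tc


# --------------------------------------------------------------- generators


def all_binary_topologies(labels):
    """Every unrooted binary topology on the labels, each exactly once,
    by sequential leaf insertion."""
    labels = sorted(labels)
    assert len(labels) >= 3
    trees = [tc.UnrootedTree.star(labels[:3])]
    for lab in labels[3:]:
        new = []
        for t in trees:
            for e in t.edges():
                t2 = t.copy()
                u, v = sorted(e)
                w = t2.subdivide_edge(u, v)
                t2.add_edge(w, t2._new_node(lab))
                new.append(t2)
        trees = new
    return trees


def contract_random_edges(tree, k, rng):
    t = tree.copy()
    for _ in range(k):
        internal = sorted(t.internal_edges(), key=sorted)
        if not internal:
            break
        u, v = sorted(rng.choice(internal))
        t.contract_edge(u, v)
    return t


def enumerate_binary_refinements(tree):
    """All binary trees refining ``tree``: the product of independent local
    resolutions of its polytomies."""
    root = min(tree._adj)
    below, parent = tree._below_leafsets(root)
    all_l = tree.leaf_set
    options = []
    for v in sorted(tree._adj):
        if v in tree._leaf or tree.degree(v) <= 3:
            continue
        stubs = []
        for u in tree._adj[v]:
            if parent.get(u) == v:
                stubs.append(below[u])
            else:
                stubs.append(all_l - below[v])
        metas = [str(i) for i in range(len(stubs))]
        local = []
        for mt in all_binary_topologies(metas):
            bips = []
            for pi in tc.bipartitions(mt):
                side = frozenset().union(*(stubs[int(m)] for m in pi.a))
                bips.append(tc.Bipartition(side, all_l - side))
            local.append(bips)
        options.append(local)
    out = []
    for combo in itertools.product(*options):
        t2 = tree.copy()
        for bips in combo:
            for pi in bips:
                t2 = tc.add_bipartition(t2, pi)
        out.append(t2)
    return out


# ------------------------------------------------------------------ oracles


def all_nontrivial_splits(labels):
    labels = frozenset(labels)
    out = set()
    for size in range(2, len(labels) - 1):
        for side in itertools.combinations(sorted(labels), size):
            out.add(tc.Bipartition(side, labels - frozenset(side)))
    return out


def bfs_edit_distance(t1, t2):
    """Minimum number of single-edge contractions/refinements turning t1
    into t2, by breadth-first search over bipartition-set states."""
    labels = t1.leaf_set
    assert labels == t2.leaf_set
    splits = all_nontrivial_splits(labels)
    start = frozenset(tc.bipartitions(t1))
    goal = frozenset(tc.bipartitions(t2))
    seen = {start: 0}
    q = deque([start])
    while q:
        cur = q.popleft()
        d = seen[cur]
        if cur == goal:
            return d
        nxts = [cur - {pi} for pi in cur]
        for pi in splits:
            if pi in cur:
                continue
            if all(pi.is_compatible_with(x) for x in cur):
                nxts.append(cur | {pi})
        for nxt in nxts:
            if nxt not in seen:
                seen[nxt] = d + 1
                q.append(nxt)
    raise AssertionError("edit-distance BFS failed to reach the goal")


def brute_matching_distance(t1, t2):
    b1 = list(tc.bipartitions(t1))
    b2 = list(tc.bipartitions(t2))
    assert len(b1) == len(b2)
    if not b1:
        return 0
    n = len(t1.leaf_set)

    def w(p, q):
        d = len(p.a ^ q.a)
        return min(d, n - d)

    return min(sum(w(p, q) for p, q in zip(b1, perm))
               for perm in itertools.permutations(b2))


def quartet_topology_by_restriction(tree, quartet):
    sub = tc.restrict(tree, quartet)
    bips = tc.bipartitions(sub)
    if not bips:
        return None
    (pi,) = bips
    return frozenset(pi.sides)


def brute_quartet_distance(t1, t2):
    labels = sorted(t1.leaf_set)
    return sum(
        1 for q in itertools.combinations(labels, 4)
        if quartet_topology_by_restriction(t1, q)
        != quartet_topology_by_restriction(t2, q))


def oracle_superleaf_components(T, R):
    """(component node set, root node) per hanging component of missing
    taxa — independent pruning reimplementation."""
    R = frozenset(R)
    leaves = T.leaves()
    alive = set(T.nodes)
    deg = {v: T.degree(v) for v in alive}
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
    bb_edges = {e for e in T.edges() if e <= alive}
    comps = []
    seen = set()
    for s in sorted(T.nodes):
        if s in seen:
            continue
        comp = {s}
        st = [s]
        while st:
            v = st.pop()
            for u in T.neighbors(v):
                if u not in comp and frozenset((v, u)) not in bb_edges:
                    comp.add(u)
                    st.append(u)
        seen |= comp
        taxa = {leaves[v] for v in comp if v in leaves}
        if taxa and not (taxa & R):
            roots = [v for v in comp
                     if any(frozenset((v, u)) in bb_edges
                            for u in T.neighbors(v))]
            assert len(roots) == 1
            comps.append((frozenset(comp), roots[0]))
    return comps


def oracle_graft(growing, edge, T, comp, root):
    g = growing.copy()
    u, v = sorted(edge)
    w = g.subdivide_edge(u, v)
    leaves = T.leaves()
    mapping = {root: w}
    order = [root]
    i = 0
    while i < len(order):
        x = order[i]
        i += 1
        for y in T.neighbors(x):
            if y in comp and y not in mapping:
                mapping[y] = g._new_node(leaves.get(y))
                g.add_edge(mapping[x], mapping[y])
                order.append(y)
    return g


def oracle_min_completion_rf(t, T):
    """Minimum RF(T', T) over all sequential attachments of every superleaf
    component onto every edge of the growing tree."""
    comps = oracle_superleaf_components(T, t.leaf_set)
    best = [None]

    def rec(g, i):
        if i == len(comps):
            d = tc.rf_distance(g, T)
            if best[0] is None or d < best[0]:
                best[0] = d
            return
        comp, root = comps[i]
        for e in g.edges():
            rec(oracle_graft(g, e, T, comp, root), i + 1)

    rec(t.copy(), 0)
    return best[0]


def oracle_min_refinement_rf(t, ref):
    """Minimum RF(B, ref) over all binary refinements B of t, plus the set
    of optimal refinements."""
    best = None
    optima = []
    for b in enumerate_binary_refinements(t):
        d = tc.rf_distance(b, ref)
        if best is None or d < best:
            best = d
            optima = [b]
        elif d == best:
            optima.append(b)
    return best, optima


@pytest.fixture
def rng():
    return random.Random(20240901)
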