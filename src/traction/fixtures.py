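"""Seeded synthetic instances for testing the correction pipeline.

Discordance between the species tree and the "true" gene tree is modeled
mechanically (random NNI for local rearrangements, random SPR for
transfer-like moves); estimation error is extra NNI moves plus oracle-style
support values: edges shared with the pre-error tree draw high support,
wrong edges draw low support, with an optional flip probability to emulate
misleading supports.  One master seed derives every sub-seed, so an
instance is reproducible from a single integer.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .tree_core import (
    TreeError,
    UnrootedTree,
    bipartitions,
    restrict,
)

__all__ = [
    "CorrectionInstance",
    "MulInstance",
    "random_binary_tree",
    "perturb",
    "nni_move",
    "spr_move",
    "degrade",
    "make_instance",
    "make_mul_instance",
]

DEFAULT_SUPPORT_THRESHOLD = 75.0


def _subseed(seed: int, tag: str) -> random.Random:
    # documented splitting rule: one master integer seeds every stage
    return random.Random(f"{seed}:{tag}")


def random_binary_tree(n: int, seed: int = 0, *, prefix: str = "s",
                       labels=None) -> UnrootedTree:
    """Random binary topology via sequential random edge attachment.

    Leaves are labeled ``<prefix>01 .. <prefix>n`` (zero-padded) unless an
    explicit label sequence is given.
    """
    if n < 3:
        raise TreeError("random binary tree needs n >= 3")
    rng = seed if isinstance(seed, random.Random) else random.Random(seed)
    if labels is None:
        width = len(str(n))
        labels = [f"{prefix}{i:0{width}d}" for i in range(1, n + 1)]
    else:
        labels = sorted(labels)
        if len(labels) != n:
            raise TreeError("label count does not match n")
    t = UnrootedTree.star(labels[:3])
    for lab in labels[3:]:
        u, v = sorted(rng.choice(sorted(t.edges(), key=sorted)))
        w = t.subdivide_edge(u, v)
        t.add_edge(w, t._new_node(lab))
    return t


def nni_move(tree: UnrootedTree, rng: random.Random) -> UnrootedTree:
    """One random nearest-neighbour interchange across an internal edge."""
    t = tree.copy()
    internal = sorted(t.internal_edges(), key=sorted)
    if not internal:
        return t
    u, v = sorted(rng.choice(internal))
    a = rng.choice(sorted(t.neighbors(u) - {v}))
    b = rng.choice(sorted(t.neighbors(v) - {u}))
    t.move_edge(u, a, v, a)
    t.move_edge(v, b, u, b)
    return t


def spr_move(tree: UnrootedTree, rng: random.Random) -> UnrootedTree:
    """One random subtree-prune-and-regraft move on a binary tree."""
    t = tree.copy()
    edges = sorted(t.edges(), key=sorted)
    rng.shuffle(edges)
    for e in edges:
        u, v = sorted(e)
        for prune_side, keep_side in ((v, u), (u, v)):
            # collect the pruned subtree's nodes
            comp = {prune_side}
            stack = [prune_side]
            while stack:
                x = stack.pop()
                for y in t.neighbors(x):
                    if y != keep_side and y not in comp and \
                            not (x == prune_side and y == keep_side):
                        comp.add(y)
                        stack.append(y)
            rest_edges = [f for f in t.edges()
                          if not (f & comp) and f != e]
            if not rest_edges:
                continue
            t.remove_edge(u, v)
            # keep_side may now have degree 2: suppress it locally
            if keep_side not in t._leaf and t.degree(keep_side) == 2:
                x, y = sorted(t.neighbors(keep_side))
                t.delete_node(keep_side)
                if y not in t._adj[x]:
                    t.add_edge(x, y)
                rest_edges = [f for f in rest_edges if keep_side not in f]
                if frozenset((x, y)) not in set(rest_edges):
                    rest_edges.append(frozenset((x, y)))
            target = rng.choice(sorted(rest_edges, key=sorted))
            x, y = sorted(target)
            w = t.subdivide_edge(x, y)
            t.add_edge(w, prune_side)
            t.canonicalize()
            return t
    return t


def perturb(tree: UnrootedTree, nni_moves: int = 0, spr_moves: int = 0,
            seed: int = 0) -> UnrootedTree:
    """Apply seeded random NNI then SPR moves; leaf set unchanged.

    Support annotations are dropped (they would be stale)."""
    rng = seed if isinstance(seed, random.Random) else random.Random(seed)
    t = tree.copy()
    t._sup.clear()
    for _ in range(nni_moves):
        t = nni_move(t, rng)
    for _ in range(spr_moves):
        t = spr_move(t, rng)
    return t


def degrade(tree: UnrootedTree, error_nni: int = 0, flip_prob: float = 0.0,
            prune_fraction: float = 0.0, seed: int = 0, *,
            support_threshold: float = DEFAULT_SUPPORT_THRESHOLD):
    """Emulate gene tree estimation error.

    Applies ``error_nni`` NNI moves, assigns oracle-style supports (edges
    shared with the input tree draw support >= threshold, unique edges draw
    support < threshold, each flipped with probability ``flip_prob``), then
    prunes a random ``prune_fraction`` of the leaves.  Returns the degraded
    tree and the retained taxon set R.
    """
    if not 0.0 <= flip_prob <= 1.0 or not 0.0 <= prune_fraction <= 1.0:
        raise TreeError("fractions must lie in [0, 1]")
    rng = seed if isinstance(seed, random.Random) else random.Random(seed)
    est = perturb(tree, nni_moves=error_nni, seed=rng)
    true_bips = bipartitions(tree)
    est_splits = _edge_splits(est)
    for e, pi in est_splits.items():
        shared = pi in true_bips
        if rng.random() < flip_prob:
            shared = not shared
        if shared:
            sup = rng.uniform(support_threshold, 100.0)
        else:
            sup = rng.uniform(0.0, support_threshold - 1e-9)
        u, v = sorted(e)
        est.set_support(u, v, sup)
    n = est.n_leaves
    k = int(round(prune_fraction * n))
    if n - k < 3:
        raise TreeError("pruning would leave fewer than 3 leaves")
    pruned = rng.sample(sorted(est.leaf_set), k) if k else []
    R = est.leaf_set - frozenset(pruned)
    if k:
        est = restrict(est, R)
    return est, frozenset(R)


def _edge_splits(tree: UnrootedTree) -> dict:
    """Non-trivial Bipartition per internal edge, keyed by edge."""
    from .tree_core import Bipartition
    all_leaves = tree.leaf_set
    if len(all_leaves) < 4:
        return {}
    root = min(tree._adj)
    below, parent = tree._below_leafsets(root)
    out = {}
    for v, p in parent.items():
        if p is None or v in tree._leaf or p in tree._leaf:
            continue
        s = below[v]
        if 1 < len(s) < len(all_leaves) - 1:
            out[frozenset((v, p))] = Bipartition(s, all_leaves - s)
    return out


@dataclass(frozen=True)
class CorrectionInstance:
    """Synthetic bundle: reference species tree, true gene tree (species
    tree after discordance moves) and a degraded estimate with supports."""

    species_tree: UnrootedTree
    true_gene_tree: UnrootedTree
    estimated_gene_tree: UnrootedTree
    retained: frozenset
    provenance: dict = field(compare=False, default_factory=dict)


def make_instance(n: int = 20, nni_moves: int = 0, spr_moves: int = 0,
                  error_nni: int = 0, flip_prob: float = 0.0,
                  prune_fraction: float = 0.0, seed: int = 0, *,
                  support_threshold: float = DEFAULT_SUPPORT_THRESHOLD
                  ) -> CorrectionInstance:
    species = random_binary_tree(n, _subseed(seed, "species"))
    true_gene = perturb(species, nni_moves=nni_moves, spr_moves=spr_moves,
                        seed=_subseed(seed, "discordance"))
    est, R = degrade(true_gene, error_nni=error_nni, flip_prob=flip_prob,
                     prune_fraction=prune_fraction,
                     seed=_subseed(seed, "error"),
                     support_threshold=support_threshold)
    return CorrectionInstance(
        species_tree=species,
        true_gene_tree=true_gene,
        estimated_gene_tree=est,
        retained=R,
        provenance={
            "n": n, "nni_moves": nni_moves, "spr_moves": spr_moves,
            "error_nni": error_nni, "flip_prob": flip_prob,
            "prune_fraction": prune_fraction, "seed": seed,
            "support_threshold": support_threshold,
        },
    )


@dataclass(frozen=True)
class MulInstance:
    """A species tree plus a MUL gene-family tree built by a duplication
    event, and a collapsed estimate of the latter."""

    species_tree: UnrootedTree
    mul_tree: UnrootedTree
    collapsed_mul_tree: UnrootedTree
    scenario: str


def _duplicate_at_root(species: UnrootedTree) -> UnrootedTree:
    """Whole-tree duplication: two copies of the species tree joined by an
    edge between subdivision points on each copy's smallest pendant edge."""
    out = UnrootedTree()
    out._allow_mul = True
    labels = species.leaves()
    anchors = []
    for _ in range(2):
        mapping = {v: out._new_node(labels.get(v)) for v in sorted(species.nodes)}
        for e in species.edges():
            u, v = sorted(e)
            out.add_edge(mapping[u], mapping[v])
        leaf = mapping[species.find_leaf(min(species.leaf_set))]
        (p,) = out._adj[leaf]
        anchors.append(out.subdivide_edge(leaf, p))
    out.add_edge(*anchors)
    return out


def _two_stars(labels) -> UnrootedTree:
    """Two species fans joined by a central edge: the root-duplication
    MUL-tree with every within-copy edge contracted."""
    out = UnrootedTree()
    out._allow_mul = True
    c1 = out._new_node()
    c2 = out._new_node()
    out.add_edge(c1, c2)
    for lab in sorted(labels):
        out.add_edge(c1, out._new_node(lab))
        out.add_edge(c2, out._new_node(lab))
    return out


def make_mul_instance(scenario: str, n: int = 5, seed: int = 0) -> MulInstance:
    """Duplication scenarios: "root-duplication" copies the whole species
    tree (every species at multiplicity 2); "leaf-duplication" turns one
    random leaf into a two-copy cherry."""
    if scenario not in ("root-duplication", "leaf-duplication"):
        raise TreeError(f"unknown scenario {scenario!r}")
    rng = _subseed(seed, f"mul:{scenario}")
    species = random_binary_tree(n, _subseed(seed, "species"))
    if scenario == "root-duplication":
        mul = _duplicate_at_root(species)
        collapsed = _two_stars(species.leaf_set)
    else:
        mul = species.copy()
        mul._allow_mul = True
        leaf = rng.choice(sorted(mul.leaf_set))
        nid = mul.find_leaf(leaf)
        del mul._leaf[nid]
        mul.add_edge(nid, mul._new_node(leaf))
        mul.add_edge(nid, mul._new_node(leaf))
        # collapsed estimate: all internal edges contracted (star)
        collapsed = UnrootedTree.star(
            sorted(lab for v, lab in mul.leaves().items()), mul=True)
    return MulInstance(species_tree=species, mul_tree=mul,
                       collapsed_mul_tree=collapsed, scenario=scenario)
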