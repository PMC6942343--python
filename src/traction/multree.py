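"""Multi-labeled (MUL) tree refinement against a singly-labeled reference.

A MUL-tree may carry several leaves per species (gene duplication context).
Refinement works by extending the reference so label multiplicities match,
relabeling both trees into singly-labeled trees over an indexed copy
alphabet (a consistent full differentiation), running the singly-labeled
refinement, and stripping the copy indices again.  No completion is
performed: label multiplicities of the two trees must already agree.
"""

from __future__ import annotations

import random
from collections import Counter
from dataclasses import dataclass
from typing import Union

from . import rf_otr
from .tree_core import TreeError, UnrootedTree

__all__ = [
    "MulTree",
    "DifferentiatedPair",
    "multiplicity",
    "extend",
    "differentiate",
    "traction_mt",
    "traction_mt_result",
]

# A MUL-tree is an UnrootedTree whose leaf labels may repeat; the alias keeps
# signatures readable.
MulTree = UnrootedTree


def multiplicity(tree: UnrootedTree) -> Counter:
    """Copy count per species."""
    return tree.leaf_multiset


@dataclass(frozen=True)
class DifferentiatedPair:
    """Two singly-labeled trees over a common indexed leaf set, plus the
    copy-index assignment (indexed label -> species) for each tree."""

    first: UnrootedTree
    second: UnrootedTree
    first_assignment: dict
    second_assignment: dict


def extend(T: UnrootedTree, R: MulTree) -> MulTree:
    """Replace each species leaf of singly-labeled T by a fan of as many
    copies as R carries, so the two trees get identical multiplicity
    profiles."""
    if T.is_mul:
        raise TreeError("the reference tree must be singly-labeled")
    if T.leaf_set != R.leaf_set:
        raise TreeError(
            "species sets differ: only in reference "
            f"{sorted(T.leaf_set - R.leaf_set)}, only in MUL-tree "
            f"{sorted(R.leaf_set - T.leaf_set)}")
    mult = multiplicity(R)
    out = T.copy()
    out._allow_mul = True
    for nid, lab in list(out._leaf.items()):
        k = mult[lab]
        if k == 1:
            continue
        del out._leaf[nid]  # leaf becomes the fan's internal node
        for _ in range(k):
            out.add_edge(nid, out._new_node(lab))
    return out


def _relabel(tree: MulTree) -> tuple:
    """Singly-labeled copy with species s renamed s_1..s_k in deterministic
    traversal order; returns (tree, indexed-label -> species map)."""
    t = tree.copy()
    t._allow_mul = False
    counters: Counter = Counter()
    assignment: dict = {}
    root = min(t._adj)
    order, _parent = t._postorder(root)
    # visit leaves in traversal order so the assignment is reproducible
    for v in order:
        lab = t._leaf.get(v)
        if lab is None:
            continue
        counters[lab] += 1
        new = f"{lab}_{counters[lab]}"
        if new in assignment:
            raise TreeError(f"indexed label collision on {new!r}")
        t._leaf[v] = new
        assignment[new] = lab
    return t, assignment


def differentiate(r1: MulTree, r2: MulTree) -> DifferentiatedPair:
    """A consistent full differentiation of two equal-multiplicity MUL-trees."""
    if multiplicity(r1) != multiplicity(r2):
        raise TreeError("multiplicity profiles differ; cannot differentiate")
    t1, a1 = _relabel(r1)
    t2, a2 = _relabel(r2)
    return DifferentiatedPair(first=t1, second=t2,
                              first_assignment=a1, second_assignment=a2)


def _strip_indices(tree: UnrootedTree, assignment: dict) -> MulTree:
    out = tree.copy()
    out._allow_mul = True
    for v, lab in list(out._leaf.items()):
        out._leaf[v] = assignment[lab]
    return out


@dataclass(frozen=True)
class MtResult:
    output: MulTree
    refinement: rf_otr.RefinementResult
    differentiated: DifferentiatedPair
    extended_reference: MulTree


def traction_mt_result(R: MulTree, T: UnrootedTree,
                       seed: Union[int, random.Random] = 0) -> MtResult:
    """Refine MUL-tree R toward binary singly-labeled reference T, keeping
    the differentiated intermediates for inspection."""
    if not T.is_binary:
        raise TreeError("reference tree must be binary")
    ext = extend(T, R)
    pair = differentiate(R, ext)
    result = rf_otr.refine(pair.first, pair.second, seed=seed)
    out = _strip_indices(result.t_star, pair.first_assignment)
    return MtResult(output=out, refinement=result, differentiated=pair,
                    extended_reference=ext)


def traction_mt(R: MulTree, T: UnrootedTree,
                seed: Union[int, random.Random] = 0) -> MulTree:
    """Binary MUL-tree refining R minimizing RF to the extended reference."""
    return traction_mt_result(R, T, seed=seed).output
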