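"""RF-optimal tree refinement: greedy insertion of compatible reference splits.

A binary refinement of the input tree minimizes the RF distance to the
reference (restricted to the shared leaf set) exactly when it displays every
reference bipartition compatible with the input.  The greedy step computes
that unique maximal compatible refinement; the resolve step completes it to a
binary tree, preferring previously collapsed edges of the original tree
before falling back to seeded random resolution.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Optional, Union

from .tree_core import (
    Bipartition,
    LeafSetMismatchError,
    TreeError,
    UnrootedTree,
    add_bipartition,
    bipartitions,
    is_compatible,
    random_binary_resolution,
    restrict,
)

__all__ = [
    "RefinementResult",
    "compatible_reference_bipartitions",
    "greedy_refine",
    "resolve",
    "refine",
]


@dataclass(frozen=True)
class RefinementResult:
    """Outcome of the refinement step.

    ``t_prime`` is the unique maximal compatible refinement; ``t_star`` is a
    binary refinement of it.  The three "added" sets are disjoint and
    partition C(t_star) \\ C(t).
    """

    t_prime: UnrootedTree
    t_star: UnrootedTree
    added_from_reference: frozenset
    added_from_original: frozenset
    added_random: frozenset


def _check_inputs(t: UnrootedTree, T: UnrootedTree) -> None:
    if t.is_mul or T.is_mul:
        raise TreeError("refinement requires singly-labeled trees")
    missing = t.leaf_set - T.leaf_set
    if missing:
        raise LeafSetMismatchError(
            f"gene tree taxa absent from reference tree: {sorted(missing)}")


def _reference_restriction(t: UnrootedTree, T: UnrootedTree) -> UnrootedTree:
    # complete gene tree: restriction is the identity, skip the surgery
    if t.leaf_set == T.leaf_set:
        return T.copy()
    return restrict(T, t.leaf_set)


def compatible_reference_bipartitions(t: UnrootedTree,
                                      T: UnrootedTree) -> frozenset:
    """Bipartitions of T restricted to t's taxa that are compatible with t
    and not already displayed by t (i.e. the insertable set C_0)."""
    _check_inputs(t, T)
    t_bips = bipartitions(t)
    ref = _reference_restriction(t, T)
    return frozenset(pi for pi in bipartitions(ref)
                     if pi not in t_bips and is_compatible(pi, t))


def greedy_refine(t: UnrootedTree, T: UnrootedTree) -> UnrootedTree:
    """The unique t' with C(t') = C(t) | C_0; insertion-order independent."""
    c0 = compatible_reference_bipartitions(t, T)
    out = t.copy()
    for pi in sorted(c0, key=Bipartition.sort_key):
        out = add_bipartition(out, pi)
    return out


def resolve(t_prime: UnrootedTree,
            original: Optional[UnrootedTree] = None,
            seed: Union[int, random.Random] = 0,
            *,
            reference_added: frozenset = frozenset()) -> RefinementResult:
    """Complete ``t_prime`` to a binary tree.

    Collapsed edges of ``original`` (a tree whose collapse produced the
    pre-refinement input) that are still compatible are restored first, in
    traversal order of the original's internal edges; a seeded random
    resolution finishes the job.  ``reference_added`` is carried into the
    result for bookkeeping by callers that ran :func:`greedy_refine`.
    """
    rng = seed if isinstance(seed, random.Random) else random.Random(seed)
    base = bipartitions(t_prime)
    cur = t_prime.copy()
    added_orig = set()
    if original is not None:
        if original.leaf_set != t_prime.leaf_set:
            raise LeafSetMismatchError(
                "original tree is not on the refined tree's leaf set")
        for pi in sorted(bipartitions(original), key=Bipartition.sort_key):
            if pi in base or pi in added_orig:
                continue
            if is_compatible(pi, cur):
                cur = add_bipartition(cur, pi)
                added_orig.add(pi)
    after_orig = bipartitions(cur)
    t_star = random_binary_resolution(cur, rng)
    added_rand = bipartitions(t_star) - after_orig
    return RefinementResult(
        t_prime=t_prime.copy(),
        t_star=t_star,
        added_from_reference=frozenset(reference_added),
        added_from_original=frozenset(added_orig),
        added_random=frozenset(added_rand),
    )


def refine(t: UnrootedTree,
           T: UnrootedTree,
           original: Optional[UnrootedTree] = None,
           seed: Union[int, random.Random] = 0) -> RefinementResult:
    """Greedy refinement followed by resolution, as one call."""
    c0 = compatible_reference_bipartitions(t, T)
    t_prime = t.copy()
    for pi in sorted(c0, key=Bipartition.sort_key):
        t_prime = add_bipartition(t_prime, pi)
    return resolve(t_prime, original=original, seed=seed, reference_added=c0)
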