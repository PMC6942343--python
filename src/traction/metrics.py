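"""Tree comparison distances: RF, normalized RF, matching and quartet.

Matching distance: minimum-weight perfect matching between the two
bipartition sets (equal-sized for binary trees), where the weight of a pair
is the orientation-minimized Hamming distance between the splits viewed as
indicator vectors.  Quartet distance: the number of 4-taxon subsets whose
induced quartet topologies differ; computed by direct enumeration.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Optional

import numpy as np
from scipy.optimize import linear_sum_assignment

from .tree_core import (
    Bipartition,
    TreeError,
    UnrootedTree,
    bipartitions,
    normalized_rf,
    rf_distance,
)

__all__ = [
    "TreeComparison",
    "matching_distance",
    "quartet_distance",
    "compare",
]


@dataclass(frozen=True)
class TreeComparison:
    rf: int
    normalized_rf: Optional[float]
    matching: Optional[int]
    quartet: Optional[int]
    n: int

    def report(self) -> str:
        lines = [f"n={self.n}", f"rf={self.rf}"]
        if self.normalized_rf is not None:
            lines.append(f"normalized_rf={self.normalized_rf:.6g}")
        if self.matching is not None:
            lines.append(f"matching={self.matching}")
        if self.quartet is not None:
            lines.append(f"quartet={self.quartet}")
        return "\n".join(lines) + "\n"


def _check_binary_pair(t1: UnrootedTree, t2: UnrootedTree, what: str) -> None:
    if t1.leaf_set != t2.leaf_set:
        raise TreeError(f"{what} requires identical leaf sets")
    if not (t1.is_binary and t2.is_binary):
        raise TreeError(f"{what} requires binary trees")
    if t1.is_mul or t2.is_mul:
        raise TreeError(f"{what} requires singly-labeled trees")


def _split_weight(p: Bipartition, q: Bipartition) -> int:
    # Hamming distance between indicator vectors, minimized over orientation
    d = len(p.a ^ q.a)
    return min(d, len(p.leaf_set) - d)


def matching_distance(t1: UnrootedTree, t2: UnrootedTree) -> int:
    _check_binary_pair(t1, t2, "matching distance")
    b1 = sorted(bipartitions(t1), key=Bipartition.sort_key)
    b2 = sorted(bipartitions(t2), key=Bipartition.sort_key)
    if len(b1) != len(b2):  # defensive; binary trees have n-3 splits each
        raise TreeError("bipartition sets of binary trees must be equal-sized")
    if not b1:
        return 0
    w = np.array([[_split_weight(p, q) for q in b2] for p in b1])
    rows, cols = linear_sum_assignment(w)
    return int(w[rows, cols].sum())


def _quartet_topology(bips, quartet) -> Optional[frozenset]:
    """The 2+2 pairing a binary tree induces on a 4-taxon set (None if no
    internal edge separates it, which cannot happen for binary trees)."""
    q = frozenset(quartet)
    for pi in bips:
        a = q & pi.a
        if len(a) == 2:
            return frozenset((a, q - a))
    return None


def quartet_distance(t1: UnrootedTree, t2: UnrootedTree) -> int:
    _check_binary_pair(t1, t2, "quartet distance")
    labels = sorted(t1.leaf_set)
    if len(labels) < 4:
        raise TreeError("quartet distance needs at least 4 leaves")
    b1 = list(bipartitions(t1))
    b2 = list(bipartitions(t2))
    diff = 0
    for quartet in combinations(labels, 4):
        if _quartet_topology(b1, quartet) != _quartet_topology(b2, quartet):
            diff += 1
    return diff


def compare(t1: UnrootedTree, t2: UnrootedTree) -> TreeComparison:
    """All applicable distances in one call.

    Non-binary inputs (or n < 4) populate only the RF fields.
    """
    if t1.leaf_set != t2.leaf_set:
        raise TreeError("compare requires identical leaf sets")
    n = t1.n_leaves
    rf = rf_distance(t1, t2)
    nrf = normalized_rf(t1, t2) if n >= 4 else None
    both_binary = t1.is_binary and t2.is_binary
    matching = matching_distance(t1, t2) if both_binary else None
    quartet = quartet_distance(t1, t2) if both_binary and n >= 4 else None
    return TreeComparison(rf=rf, normalized_rf=nrf, matching=matching,
                          quartet=quartet, n=n)
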