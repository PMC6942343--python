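"""Unrooted phylogenetic trees: newick I/O, bipartition algebra, RF distance.

Trees are stored as undirected graphs over integer node ids with leaf labels
attached to degree-1 nodes.  All semantics are anchor-free: rooted newick
input is unrooted on parse (degree-2 nodes are suppressed).  Edge support
values and branch lengths are carried as annotations, but every algorithm in
this package is purely topological.
"""

from __future__ import annotations

import random
from collections import Counter
from typing import Iterable, Iterator, Optional, Union

__all__ = [
    "TreeError",
    "NewickParseError",
    "LeafSetMismatchError",
    "MulTreeError",
    "IncompatibleBipartitionError",
    "Bipartition",
    "UnrootedTree",
    "validate_label",
    "parse_newick",
    "write_newick",
    "bipartitions",
    "restrict",
    "is_compatible",
    "add_bipartition",
    "rf_distance",
    "normalized_rf",
    "collapse_low_support",
    "random_binary_resolution",
    "trees_isomorphic",
]


class TreeError(ValueError):
    """Base error for malformed trees or invalid tree operations."""


class NewickParseError(TreeError):
    def __init__(self, message: str, position: Optional[int] = None):
        self.position = position
        if position is not None:
            message = f"{message} (at position {position})"
        super().__init__(message)


class LeafSetMismatchError(TreeError):
    """Two trees that must share a leaf set do not."""


class MulTreeError(TreeError):
    """A multi-labeled tree was supplied where a singly-labeled one is required."""


class IncompatibleBipartitionError(TreeError):
    """Attempt to insert a bipartition that no refinement of the tree displays."""


# Characters that cannot appear in a taxon label even when quoted on output.
_HARD_RESERVED = set("(),:;'\"[]")
_NEEDS_QUOTE = set(" \t")


def validate_label(label: str) -> str:
    if not isinstance(label, str) or not label:
        raise TreeError("taxon label must be a non-empty string")
    bad = set(label) & _HARD_RESERVED
    if bad:
        raise TreeError(
            f"taxon label {label!r} contains reserved characters: {sorted(bad)}"
        )
    if label != label.strip():
        raise TreeError(f"taxon label {label!r} has leading/trailing whitespace")
    return label


class Bipartition:
    """A split A|B of a leaf-label set, canonically oriented.

    The side containing the lexicographically smallest label is stored first,
    so equality and hashing are orientation-independent.
    """

    __slots__ = ("_a", "_b", "_hash", "_key")

    def __init__(self, a: Iterable[str], b: Iterable[str]):
        fa, fb = frozenset(a), frozenset(b)
        if not fa or not fb:
            raise TreeError("both sides of a bipartition must be non-empty")
        if fa & fb:
            raise TreeError("bipartition sides must be disjoint")
        if min(fa) > min(fb):
            fa, fb = fb, fa
        object.__setattr__(self, "_a", fa)
        object.__setattr__(self, "_b", fb)
        object.__setattr__(self, "_hash", hash((fa, fb)))
        object.__setattr__(self, "_key", None)

    @property
    def a(self) -> frozenset:
        return self._a

    @property
    def b(self) -> frozenset:
        return self._b

    @property
    def sides(self) -> tuple:
        return (self._a, self._b)

    @property
    def leaf_set(self) -> frozenset:
        return self._a | self._b

    @property
    def is_trivial(self) -> bool:
        return min(len(self._a), len(self._b)) == 1

    def restrict(self, subset: Iterable[str]) -> Optional["Bipartition"]:
        """The induced split on ``subset``, or None if a side becomes empty.

        The result may be trivial; callers filter as needed.
        """
        s = frozenset(subset)
        ra, rb = self._a & s, self._b & s
        if not ra or not rb:
            return None
        return Bipartition(ra, rb)

    def is_compatible_with(self, other: "Bipartition") -> bool:
        """Pairwise four-intersection rule: some side pair has empty overlap."""
        return (
            not (self._a & other._a)
            or not (self._a & other._b)
            or not (self._b & other._a)
            or not (self._b & other._b)
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, Bipartition):
            return NotImplemented
        return self._a == other._a and self._b == other._b

    def __hash__(self) -> int:
        return self._hash

    def __repr__(self) -> str:
        return "{}|{}".format(
            ",".join(sorted(self._a)), ",".join(sorted(self._b))
        )

    def sort_key(self):
        if self._key is None:
            object.__setattr__(self, "_key", (
                len(self._a) + len(self._b),
                tuple(sorted(self._a)), tuple(sorted(self._b))))
        return self._key


_EdgeKey = frozenset


class UnrootedTree:
    """Leaf-labeled unrooted tree, possibly multifurcating.

    In canonical form no node has degree 2 and no unlabeled node has degree
    less than 3 (except in degenerate trees with fewer than 3 leaves).
    """

    def __init__(self) -> None:
        self._adj: dict[int, set[int]] = {}
        self._leaf: dict[int, str] = {}
        self._sup: dict[frozenset, float] = {}
        self._len: dict[frozenset, float] = {}
        self._next = 0
        self._allow_mul = False

    # ------------------------------------------------------------------ build

    def _new_node(self, label: Optional[str] = None) -> int:
        nid = self._next
        self._next += 1
        self._adj[nid] = set()
        if label is not None:
            self._leaf[nid] = label
        return nid

    def add_edge(self, u: int, v: int, support: Optional[float] = None,
                 length: Optional[float] = None) -> None:
        if u == v or v in self._adj[u]:
            raise TreeError("invalid edge")
        self._adj[u].add(v)
        self._adj[v].add(u)
        key = frozenset((u, v))
        if support is not None:
            self._sup[key] = support
        if length is not None:
            self._len[key] = length

    def remove_edge(self, u: int, v: int) -> tuple:
        self._adj[u].discard(v)
        self._adj[v].discard(u)
        key = frozenset((u, v))
        return self._sup.pop(key, None), self._len.pop(key, None)

    def delete_node(self, v: int) -> None:
        for u in list(self._adj[v]):
            self.remove_edge(u, v)
        del self._adj[v]
        self._leaf.pop(v, None)

    @classmethod
    def star(cls, labels: Iterable[str], *, mul: bool = False) -> "UnrootedTree":
        labels = list(labels)
        t = cls()
        t._allow_mul = mul
        if not mul and len(set(labels)) != len(labels):
            raise MulTreeError("duplicate leaf labels (pass mul=True to allow)")
        for lab in labels:
            validate_label(lab)
        if len(labels) == 0:
            raise TreeError("a tree needs at least one leaf")
        if len(labels) == 1:
            t._new_node(labels[0])
            return t
        if len(labels) == 2:
            a = t._new_node(labels[0])
            b = t._new_node(labels[1])
            t.add_edge(a, b)
            return t
        c = t._new_node()
        for lab in labels:
            t.add_edge(c, t._new_node(lab))
        return t

    @classmethod
    def from_bipartitions(cls, labels: Iterable[str],
                          bips: Iterable[Bipartition]) -> "UnrootedTree":
        """Build the unique tree displaying exactly the given compatible splits."""
        t = cls.star(labels)
        for pi in sorted(bips, key=Bipartition.sort_key):
            t = add_bipartition(t, pi)
        return t

    # ------------------------------------------------------------ inspection

    @property
    def nodes(self) -> list:
        return list(self._adj)

    def degree(self, v: int) -> int:
        return len(self._adj[v])

    def neighbors(self, v: int) -> set:
        return set(self._adj[v])

    def leaves(self) -> dict:
        return dict(self._leaf)

    @property
    def n_leaves(self) -> int:
        return len(self._leaf)

    @property
    def leaf_set(self) -> frozenset:
        return frozenset(self._leaf.values())

    @property
    def leaf_multiset(self) -> Counter:
        return Counter(self._leaf.values())

    @property
    def is_mul(self) -> bool:
        return len(self.leaf_set) != len(self._leaf)

    def find_leaf(self, label: str) -> int:
        if self.is_mul:
            raise MulTreeError("find_leaf is ambiguous on a multi-labeled tree")
        for nid, lab in self._leaf.items():
            if lab == label:
                return nid
        raise TreeError(f"no leaf labeled {label!r}")

    def edges(self) -> list:
        out = []
        for u, nbrs in self._adj.items():
            for v in nbrs:
                if u < v:
                    out.append(frozenset((u, v)))
        return out

    def internal_edges(self) -> list:
        return [e for e in self.edges()
                if all(n not in self._leaf for n in e)]

    @property
    def is_binary(self) -> bool:
        return all(len(nbrs) == 3 for v, nbrs in self._adj.items()
                   if v not in self._leaf)

    def support(self, u: int, v: int) -> Optional[float]:
        return self._sup.get(frozenset((u, v)))

    def set_support(self, u: int, v: int, value: float) -> None:
        self._sup[frozenset((u, v))] = value

    def length(self, u: int, v: int) -> Optional[float]:
        return self._len.get(frozenset((u, v)))

    def copy(self) -> "UnrootedTree":
        t = UnrootedTree()
        t._adj = {v: set(n) for v, n in self._adj.items()}
        t._leaf = dict(self._leaf)
        t._sup = dict(self._sup)
        t._len = dict(self._len)
        t._next = self._next
        t._allow_mul = self._allow_mul
        return t

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        try:
            return f"UnrootedTree({write_newick(self)!r})"
        except Exception:
            return f"UnrootedTree(<{len(self._adj)} nodes>)"

    # ----------------------------------------------------------- traversal

    def _postorder(self, root: int):
        """(postorder node list, parent map) by iterative DFS from root."""
        parent = {root: None}
        order = []
        stack = [root]
        while stack:
            v = stack.pop()
            order.append(v)
            for u in self._adj[v]:
                if u not in parent:
                    parent[u] = v
                    stack.append(u)
        order.reverse()
        return order, parent

    def _below_leafsets(self, root: int):
        """Per-node frozenset of leaf labels on the far side from root."""
        order, parent = self._postorder(root)
        below: dict[int, frozenset] = {}
        for v in order:
            acc = set()
            if v in self._leaf:
                acc.add(self._leaf[v])
            for u in self._adj[v]:
                if u != parent[v]:
                    acc |= below[u]
            below[v] = frozenset(acc)
        return below, parent

    # ------------------------------------------------------------- surgery

    def contract_edge(self, u: int, v: int) -> None:
        """Merge v into u; both endpoints must be internal."""
        if u in self._leaf or v in self._leaf:
            raise TreeError("cannot contract a pendant edge")
        self.remove_edge(u, v)
        for w in list(self._adj[v]):
            sup, ln = self.remove_edge(v, w)
            self.add_edge(u, w, support=sup, length=ln)
        del self._adj[v]

    def move_edge(self, old_u: int, old_v: int, new_u: int, new_v: int) -> None:
        sup, ln = self.remove_edge(old_u, old_v)
        self.add_edge(new_u, new_v, support=sup, length=ln)

    def subdivide_edge(self, u: int, v: int) -> int:
        """Insert and return a new node in the middle of edge (u, v)."""
        sup, ln = self.remove_edge(u, v)
        w = self._new_node()
        self.add_edge(u, w, support=sup, length=ln)
        self.add_edge(w, v)
        return w

    def _prune_dead(self) -> None:
        queue = [v for v in self._adj
                 if v not in self._leaf and len(self._adj[v]) <= 1]
        while queue:
            v = queue.pop()
            if v not in self._adj:
                continue
            nbrs = list(self._adj[v])
            self.delete_node(v)
            for u in nbrs:
                if u not in self._leaf and len(self._adj[u]) <= 1:
                    queue.append(u)

    def _suppress_degree_two(self) -> None:
        changed = True
        while changed:
            changed = False
            for v in list(self._adj):
                if v in self._leaf or len(self._adj[v]) != 2:
                    continue
                a, b = sorted(self._adj[v])
                sup1, ln1 = self.remove_edge(v, a)
                sup2, ln2 = self.remove_edge(v, b)
                del self._adj[v]
                sups = [s for s in (sup1, sup2) if s is not None]
                lens = [x for x in (ln1, ln2) if x is not None]
                # min-of-supports is the conservative merge: a low-support
                # (likely wrong) edge never gains confidence by suppression
                self.add_edge(a, b,
                              support=min(sups) if sups else None,
                              length=sum(lens) if lens else None)
                changed = True

    def canonicalize(self) -> None:
        self._prune_dead()
        self._suppress_degree_two()
        if not self._adj:
            raise TreeError("tree has no leaves")


# ======================================================================
# Newick I/O
# ======================================================================


class _PN:
    __slots__ = ("children", "label", "length")

    def __init__(self):
        self.children: list = []
        self.label: Optional[str] = None
        self.length: Optional[float] = None


def parse_newick(text: str, *, mul: bool = False) -> UnrootedTree:
    """Parse one newick tree.

    Numeric internal-node labels are read as the support of the edge above
    that node (bootstrap dialect).  ``mul=True`` allows duplicate leaf labels.
    """
    n = len(text)

    def skip_ws(i: int) -> int:
        while i < n:
            c = text[i]
            if c in " \t\r\n":
                i += 1
            elif c == "[":
                j = text.find("]", i)
                if j < 0:
                    raise NewickParseError("unterminated comment", i)
                i = j + 1
            else:
                break
        return i

    def read_label(i: int) -> tuple:
        if text[i] == "'":
            j = i + 1
            out = []
            while True:
                if j >= n:
                    raise NewickParseError("unterminated quoted label", i)
                ch = text[j]
                if ch == "'":
                    if j + 1 < n and text[j + 1] == "'":
                        out.append("'")
                        j += 2
                        continue
                    j += 1
                    break
                out.append(ch)
                j += 1
            return "".join(out), j
        j = i
        while j < n and text[j] not in "(),:;[' \t\r\n":
            j += 1
        return text[i:j], j

    root = _PN()
    current = root
    ancestors: list = []
    saw_semicolon = False
    i = skip_ws(0)
    if i >= n:
        raise NewickParseError("empty input", 0)
    while i < n:
        i = skip_ws(i)
        if i >= n:
            break
        c = text[i]
        if c == "(":
            child = _PN()
            current.children.append(child)
            ancestors.append(current)
            current = child
            i += 1
        elif c == ",":
            if not ancestors:
                raise NewickParseError("comma outside parentheses", i)
            parent = ancestors[-1]
            current = _PN()
            parent.children.append(current)
            i += 1
        elif c == ")":
            if not ancestors:
                raise NewickParseError("unbalanced ')'", i)
            current = ancestors.pop()
            i += 1
        elif c == ";":
            if ancestors:
                raise NewickParseError("unbalanced '(' before ';'", i)
            i += 1
            saw_semicolon = True
            break
        elif c == ":":
            i += 1
            j = i
            while j < n and text[j] not in "(),:;[' \t\r\n":
                j += 1
            try:
                current.length = float(text[i:j])
            except ValueError:
                raise NewickParseError(
                    f"invalid branch length {text[i:j]!r}", i) from None
            i = j
        else:
            label, j = read_label(i)
            if not label:
                raise NewickParseError(f"unexpected character {c!r}", i)
            if current.label is not None:
                raise NewickParseError("node has two labels", i)
            current.label = label
            i = j
    if not saw_semicolon:
        raise NewickParseError("missing ';' terminator", n)
    i = skip_ws(i)
    if i < n:
        raise NewickParseError("trailing characters after ';'", i)
    if root.label is None and root.length is None and len(root.children) == 1:
        root = root.children[0]

    t = UnrootedTree()
    t._allow_mul = mul
    stack = [(root, None)]
    while stack:
        pn, pid = stack.pop()
        if pn.children:
            nid = t._new_node()
            sup = None
            if pn.label is not None:
                try:
                    sup = float(pn.label)
                except ValueError:
                    sup = None  # non-numeric internal labels are dropped
        else:
            if pn.label is None:
                raise NewickParseError("leaf without a label")
            nid = t._new_node(validate_label(pn.label))
            sup = None
        if pid is not None:
            t.add_edge(pid, nid, support=sup, length=pn.length)
        for ch in pn.children:
            stack.append((ch, nid))
    if not mul and t.is_mul:
        dupes = sorted(lab for lab, k in t.leaf_multiset.items() if k > 1)
        raise MulTreeError(
            f"duplicate leaf labels {dupes} (pass mul=True for MUL-trees)")
    t.canonicalize()
    return t


def _fmt_num(x: float) -> str:
    if float(x) == int(x):
        return str(int(x))
    return format(x, "g")


def _quote_label(label: str) -> str:
    if set(label) & _NEEDS_QUOTE:
        return "'" + label.replace("'", "''") + "'"
    return label


def write_newick(tree: UnrootedTree) -> str:
    """Deterministic newick: children ordered by smallest descendant label,
    supports emitted as internal-node labels, lengths after ':'."""
    nodes = tree.nodes
    if not nodes:
        raise TreeError("cannot serialize an empty tree")
    if len(nodes) == 1:
        return f"{_quote_label(tree._leaf[nodes[0]])};"
    min_leaf = min(tree._leaf, key=lambda v: (tree._leaf[v], v))
    (anchor,) = tree._adj[min_leaf]
    if anchor in tree._leaf:  # two-leaf tree
        la, lb = sorted([tree._leaf[min_leaf], tree._leaf[anchor]])
        ln = tree.length(min_leaf, anchor)
        tail = f":{_fmt_num(ln)}" if ln is not None else ""
        return f"({_quote_label(la)},{_quote_label(lb)}{tail});"

    memo: dict[tuple, tuple] = {}  # (node, parent) -> (min_label, text)

    def annot(u: int, v: int) -> str:
        out = ""
        sup = tree.support(u, v)
        if sup is not None:
            out += _fmt_num(sup)
        ln = tree.length(u, v)
        if ln is not None:
            out += f":{_fmt_num(ln)}"
        return out

    stack = [(anchor, None, False)]
    while stack:
        v, p, expanded = stack.pop()
        if (v, p) in memo:
            continue
        if v in tree._leaf:
            lab = tree._leaf[v]
            text = _quote_label(lab)
            if p is not None:
                ln = tree.length(v, p)
                if ln is not None:
                    text += f":{_fmt_num(ln)}"
            memo[(v, p)] = (lab, text)
            continue
        kids = [u for u in tree._adj[v] if u != p]
        if not expanded:
            stack.append((v, p, True))
            for u in kids:
                stack.append((u, v, False))
            continue
        parts = sorted(memo[(u, v)] for u in kids)
        text = "(" + ",".join(t for _, t in parts) + ")"
        if p is not None:
            text += annot(v, p)
        memo[(v, p)] = (parts[0][0], text)
    return memo[(anchor, None)][1] + ";"


# ======================================================================
# Bipartition algebra
# ======================================================================


def _require_singly(tree: UnrootedTree, what: str = "operation") -> None:
    if tree.is_mul:
        raise MulTreeError(f"{what} requires a singly-labeled tree")


def bipartitions(tree: UnrootedTree) -> set:
    """The non-trivial split of every internal edge; empty for n <= 3."""
    _require_singly(tree, "bipartitions")
    all_leaves = tree.leaf_set
    if len(all_leaves) < 4:
        return set()
    root = min(tree._adj)
    below, parent = tree._below_leafsets(root)
    out = set()
    for v, p in parent.items():
        if p is None or v in tree._leaf or p in tree._leaf:
            continue
        s = below[v]
        if 1 < len(s) < len(all_leaves) - 1:
            out.add(Bipartition(s, all_leaves - s))
    return out


def restrict(tree: UnrootedTree, subset: Iterable[str]) -> UnrootedTree:
    """The induced subtree on ``subset`` with degree-2 nodes suppressed."""
    _require_singly(tree, "restrict")
    subset = frozenset(subset)
    missing = subset - tree.leaf_set
    if missing:
        raise TreeError(f"taxa not in tree: {sorted(missing)}")
    if len(subset) < 2:
        raise TreeError("restriction requires at least 2 taxa")
    if subset == tree.leaf_set:
        return tree.copy()
    t = tree.copy()
    for nid, lab in list(t._leaf.items()):
        if lab not in subset:
            del t._leaf[nid]  # demote to unlabeled; pruned next
    t.canonicalize()
    return t


def _check_same_leafset(t1: UnrootedTree, t2: UnrootedTree) -> None:
    if t1.leaf_set != t2.leaf_set:
        only1 = sorted(t1.leaf_set - t2.leaf_set)
        only2 = sorted(t2.leaf_set - t1.leaf_set)
        raise LeafSetMismatchError(
            f"leaf sets differ (only in first: {only1}, only in second: {only2})")


def _locate_bipartition(tree: UnrootedTree, pi: Bipartition):
    """Where pi sits relative to tree.

    Returns ("displayed", edge_key), ("vertex", v, a_side_neighbors) for the
    unique insertion point, or None if incompatible.  Assumes leaf sets match.
    """
    A, B = pi.sides
    nA, nB = len(A), len(B)
    root = min(tree._adj)
    order, parent = tree._postorder(root)
    cntA: dict[int, int] = {}
    cntB: dict[int, int] = {}
    for v in order:
        a = b = 0
        lab = tree._leaf.get(v)
        if lab is not None:
            if lab in A:
                a = 1
            else:
                b = 1
        for u in tree._adj[v]:
            if u != parent[v]:
                a += cntA[u]
                b += cntB[u]
        cntA[v] = a
        cntB[v] = b
    displayed = None
    span_a_vertices: set = set()
    span_b_vertices: set = set()
    for v, p in parent.items():
        if p is None:
            continue
        a, b = cntA[v], cntB[v]
        in_a = 0 < a < nA
        in_b = 0 < b < nB
        if in_a and in_b:
            return None
        if (a == nA and b == 0) or (b == nB and a == 0):
            displayed = frozenset((v, p))
        if in_a:
            span_a_vertices.update((v, p))
        if in_b:
            span_b_vertices.update((v, p))
    if displayed is not None:
        return ("displayed", displayed)
    common = span_a_vertices & span_b_vertices
    if len(common) != 1:
        return None
    v = common.pop()
    a_side = []
    for u in tree._adj[v]:
        if parent.get(u) == v:
            away_has_a = cntA[u] > 0
        else:  # u is v's parent: away side is the complement of below(v)
            away_has_a = (nA - cntA[v]) > 0
        if away_has_a:
            a_side.append(u)
    return ("vertex", v, tuple(sorted(a_side)))


def is_compatible(pi: Bipartition, tree: UnrootedTree) -> bool:
    """True iff some refinement of ``tree`` displays ``pi``."""
    _require_singly(tree, "compatibility check")
    if pi.leaf_set != tree.leaf_set:
        raise LeafSetMismatchError(
            "bipartition is not over the tree's leaf set")
    if pi.is_trivial:
        return True
    return _locate_bipartition(tree, pi) is not None


def add_bipartition(tree: UnrootedTree, pi: Bipartition) -> UnrootedTree:
    """The unique tree T' with C(T') = C(tree) | {pi}; errors if incompatible."""
    _require_singly(tree, "bipartition insertion")
    if pi.leaf_set != tree.leaf_set:
        raise LeafSetMismatchError(
            "bipartition is not over the tree's leaf set")
    if pi.is_trivial:
        return tree.copy()
    loc = _locate_bipartition(tree, pi)
    if loc is None:
        raise IncompatibleBipartitionError(
            f"bipartition {pi!r} is incompatible with the tree")
    if loc[0] == "displayed":
        return tree.copy()
    _, v, a_side = loc
    t = tree.copy()
    w = t._new_node()
    for u in a_side:
        t.move_edge(v, u, w, u)
    t.add_edge(v, w)
    return t


def rf_distance(t1: UnrootedTree, t2: UnrootedTree) -> int:
    """|C(t1) symmetric-difference C(t2)| for trees on the same leaf set."""
    _require_singly(t1, "RF distance")
    _require_singly(t2, "RF distance")
    _check_same_leafset(t1, t2)
    return len(bipartitions(t1) ^ bipartitions(t2))


def normalized_rf(t1: UnrootedTree, t2: UnrootedTree) -> float:
    n = t1.n_leaves
    if n < 4:
        raise TreeError("normalized RF needs at least 4 leaves")
    return rf_distance(t1, t2) / (2 * n - 6)


def collapse_low_support(tree: UnrootedTree, threshold: float) -> UnrootedTree:
    """Contract every internal edge whose support is strictly below threshold.

    Edges without a support value are retained.
    """
    t = tree.copy()
    targets = [sorted(e) for e in t.internal_edges()
               if t._sup.get(e) is not None and t._sup[e] < threshold]
    # earlier contractions merge nodes; chase each endpoint to its survivor
    merged: dict[int, int] = {}

    def find(v: int) -> int:
        while v in merged:
            v = merged[v]
        return v

    for u, v in targets:
        u, v = find(u), find(v)
        if u == v or v not in t._adj[u]:
            continue  # stale key (cannot happen, but cheap to guard)
        t.contract_edge(u, v)
        merged[v] = u
    return t


def random_binary_resolution(tree: UnrootedTree,
                             seed: Union[int, random.Random] = 0
                             ) -> UnrootedTree:
    """A seeded uniform-at-local-level binary refinement of ``tree``.

    Each polytomy of degree d is resolved by repeatedly pairing two of its
    incident subtrees chosen uniformly at random.
    """
    rng = seed if isinstance(seed, random.Random) else random.Random(seed)
    t = tree.copy()
    for v in sorted(t.nodes):
        if v in t._leaf:
            continue
        while t.degree(v) > 3:
            nbrs = sorted(t._adj[v])
            i, j = rng.sample(range(len(nbrs)), 2)
            a, b = nbrs[i], nbrs[j]
            w = t._new_node()
            t.move_edge(v, a, w, a)
            t.move_edge(v, b, w, b)
            t.add_edge(v, w)
    return t


def trees_isomorphic(t1: UnrootedTree, t2: UnrootedTree) -> bool:
    """Leaf-labeled isomorphism for singly-labeled trees."""
    if t1.leaf_set != t2.leaf_set:
        return False
    return bipartitions(t1) == bipartitions(t2)
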