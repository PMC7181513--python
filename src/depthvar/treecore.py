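"""Tree data model, Newick I/O, canonical constructors and shape enumeration.

The central object is the :class:`TreeShape`, an *unlabeled* rooted tree in
which no node has out-degree 1.  All the shape indices implemented in this
package (leaf-depth variance, Sackin index, total cophenetic index) depend on
a phylogenetic tree only through its shape, so labeled trees
(:class:`PhyloTree`) are thin wrappers that can always be projected down via
:func:`shape_of`.

Shapes are compared as *unordered* rooted trees: two shapes are equal iff they
are isomorphic.  Isomorphism is decided through a canonical key computed
bottom-up (children sorted by their own keys), which makes equality and
hashing O(1) after construction.

The module also provides the combinatorial machinery used as a verification
oracle elsewhere: exhaustive enumeration of bifurcating shapes
(Wedderburn-Etherington enumeration) together with the number of leaf
labelings of each shape, and construction of a tree realizing a prescribed
multiset of leaf depths (Kraft-feasible multisets only).
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Iterator, Mapping, Union

__all__ = [
    "NewickError",
    "UnaryNodeError",
    "DuplicateLabelError",
    "UnrealizableDepthsError",
    "TreeShape",
    "PhyloTree",
    "DepthMultiset",
    "CandidateType",
    "parse_newick",
    "parse_newick_many",
    "write_newick",
    "shape_of",
    "depth_multiset",
    "build_classic",
    "tree_from_depths",
    "enumerate_shapes",
    "count_shapes",
    "labeled_count",
    "random_tree",
    "classify_type",
    "balanced_class_predicates",
    "is_maximally_balanced",
    "odd_double_factorial",
]


class NewickError(ValueError):
    """Malformed Newick input."""


class UnaryNodeError(NewickError):
    """The tree contains a node with exactly one child, which the tree model excludes."""


class DuplicateLabelError(NewickError):
    """Two leaves carry the same label; leaf labeling must be a bijection."""


class UnrealizableDepthsError(ValueError):
    """No bifurcating tree realizes the requested multiset of leaf depths."""


# ---------------------------------------------------------------------------
# shapes


class TreeShape:
    """An unlabeled rooted tree with unordered children and no unary nodes.

    Instances are immutable.  ``children`` is a tuple sorted by canonical key;
    a node is a leaf iff the tuple is empty.  Equality and hashing follow tree
    isomorphism.
    """

    __slots__ = ("children", "n", "key", "_hash", "_depths", "_aut")

    def __init__(self, children: Iterable["TreeShape"] = ()):
        children = tuple(children)
        if len(children) == 1:
            raise UnaryNodeError("a tree node must have 0 or >= 2 children")
        self.children = tuple(sorted(children, key=lambda c: c.key))
        children = self.children
        if not children:
            self.n = 1
            self.key = "L"
        else:
            self.n = sum(c.n for c in children)
            self.key = "(" + "".join(c.key for c in children) + ")"
        self._hash = hash(self.key)
        self._depths = None
        self._aut = None

    # -- basic protocol ----------------------------------------------------
    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __eq__(self, other) -> bool:
        return isinstance(other, TreeShape) and self.key == other.key

    def __hash__(self) -> int:
        return self._hash

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"TreeShape(n={self.n})"

    # -- structural queries ------------------------------------------------
    def is_bifurcating(self) -> bool:
        stack = [self]
        while stack:
            v = stack.pop()
            if v.children:
                if len(v.children) != 2:
                    return False
                stack.extend(v.children)
        return True

    def iter_nodes(self) -> Iterator["TreeShape"]:
        """Preorder iteration over all nodes (as subtree shapes)."""
        stack = [self]
        while stack:
            v = stack.pop()
            yield v
            stack.extend(v.children)

    def subtree_leaf_counts(self) -> list[int]:
        """kappa(v) for every internal node v, in preorder."""
        return [v.n for v in self.iter_nodes() if v.children]

    def depth_counts(self) -> tuple[tuple[int, int], ...]:
        """Sorted (depth, multiplicity) pairs of the leaf-depth multiset.

        Computed once per node and cached; children's cached values are merged
        so that shared subtrees (as produced by the enumerator) pay only once.
        """
        if self._depths is None:
            stack = [self]
            while stack:
                v = stack[-1]
                if v._depths is not None:
                    stack.pop()
                    continue
                pending = [c for c in v.children if c._depths is None]
                if pending:
                    stack.extend(pending)
                    continue
                stack.pop()
                if not v.children:
                    v._depths = ((0, 1),)
                else:
                    acc: dict[int, int] = {}
                    for c in v.children:
                        for d, cnt in c._depths:
                            acc[d + 1] = acc.get(d + 1, 0) + cnt
                    v._depths = tuple(sorted(acc.items()))
        return self._depths

    def automorphism_count(self) -> int:
        """Order of the automorphism group of the shape.

        The number of leaf labelings of the shape is ``n! / automorphisms``;
        for a bifurcating shape the order equals ``2**q`` with q the number of
        internal nodes whose two child subtrees are isomorphic.
        """
        if self._aut is None:
            stack = [self]
            while stack:
                v = stack[-1]
                if v._aut is not None:
                    stack.pop()
                    continue
                pending = [c for c in v.children if c._aut is None]
                if pending:
                    stack.extend(pending)
                    continue
                stack.pop()
                aut = 1
                run = 1
                prev = None
                for c in v.children:  # sorted: equal children are adjacent
                    aut *= c._aut
                    if prev is not None and c.key == prev.key:
                        run += 1
                    else:
                        run = 1
                    aut *= run  # accumulates mult! over each run
                    prev = c
                v._aut = aut
        return self._aut


_LEAF = TreeShape()


# ---------------------------------------------------------------------------
# labeled trees


class _PNode:
    __slots__ = ("children", "label")

    def __init__(self, children: tuple["_PNode", ...] = (), label=None):
        self.children = children
        self.label = label


class PhyloTree:
    """A rooted tree with leaves bijectively labeled.

    Branch lengths are not part of the model; indices depend on a phylogenetic
    tree only through its (label-forgetting) shape.
    """

    __slots__ = ("root", "_shape", "_labels")

    def __init__(self, root: _PNode):
        self.root = root
        self._shape = None
        self._labels = None
        labels = self.labels
        if len(set(labels)) != len(labels):
            seen, dups = set(), set()
            for x in labels:
                if x in seen:
                    dups.add(x)
                seen.add(x)
            raise DuplicateLabelError(f"duplicate leaf labels: {sorted(map(str, dups))}")
        if any(lb is None for lb in labels):
            raise NewickError("every leaf must carry a label")

    @classmethod
    def from_nested(cls, nested) -> "PhyloTree":
        """Build from nested sequences, e.g. ``(("a", "b"), "c")``."""

        def build(x):
            if isinstance(x, (list, tuple)):
                return _PNode(tuple(build(c) for c in x))
            return _PNode(label=x)

        return cls(build(nested))

    @property
    def labels(self) -> list:
        if self._labels is None:
            out = []
            stack = [self.root]
            while stack:
                v = stack.pop()
                if v.children:
                    stack.extend(v.children)
                else:
                    out.append(v.label)
            self._labels = out
        return self._labels

    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def shape(self) -> TreeShape:
        if self._shape is None:
            self._shape = _shape_of_node(self.root)
        return self._shape


def _shape_of_node(node: _PNode) -> TreeShape:
    if not node.children:
        return _LEAF
    return TreeShape(_shape_of_node(c) for c in node.children)


def shape_of(tree: Union[PhyloTree, TreeShape]) -> TreeShape:
    """Forgetful projection: drop leaf labels, keep the shape."""
    if isinstance(tree, TreeShape):
        return tree
    return tree.shape


# ---------------------------------------------------------------------------
# depth multisets


class DepthMultiset(Mapping):
    """The multiset of leaf depths of a tree, as depth -> multiplicity.

    This is the sufficient statistic for the Sackin index, the mean depth,
    the sum of squared depths and the depth variance.  ``m`` and ``k`` are the
    decomposition n = 2**m + k with m = floor(log2 n), used throughout the
    extremal analysis.
    """

    __slots__ = ("_counts", "n", "delta")

    def __init__(self, counts):
        if isinstance(counts, Mapping):
            items = counts.items()
        else:
            acc: dict[int, int] = {}
            for d in counts:
                acc[d] = acc.get(d, 0) + 1
            items = acc.items()
        cleaned: dict[int, int] = {}
        for d, c in sorted(items):
            d, c = int(d), int(c)
            if d < 0:
                raise ValueError("depths must be non-negative")
            if c <= 0:
                raise ValueError("multiplicities must be positive")
            cleaned[d] = c
        if not cleaned:
            raise ValueError("a depth multiset cannot be empty")
        self._counts = cleaned
        self.n = sum(cleaned.values())
        self.delta = max(cleaned)

    @property
    def m(self) -> int:
        return self.n.bit_length() - 1

    @property
    def k(self) -> int:
        return self.n - (1 << self.m)

    def kraft_sum(self) -> Fraction:
        """Sum of 2**(-depth) over leaves; equals 1 iff realizable by a bifurcating tree."""
        return sum((Fraction(c, 1 << d) for d, c in self._counts.items()), Fraction(0))

    # Mapping protocol
    def __getitem__(self, d):
        return self._counts[d]

    def __iter__(self):
        return iter(self._counts)

    def __len__(self):
        return len(self._counts)

    def __eq__(self, other):
        if isinstance(other, DepthMultiset):
            return self._counts == other._counts
        return dict(self) == dict(other) if isinstance(other, Mapping) else NotImplemented

    def __hash__(self):
        return hash(tuple(self._counts.items()))

    def __repr__(self):
        inner = ", ".join(f"{d}: {c}" for d, c in self._counts.items())
        return f"DepthMultiset({{{inner}}})"


def depth_multiset(tree: Union[TreeShape, PhyloTree]) -> DepthMultiset:
    """Multiset of leaf depths of a tree."""
    return DepthMultiset(dict(shape_of(tree).depth_counts()))


# ---------------------------------------------------------------------------
# candidate types


@dataclass(frozen=True)
class CandidateType:
    """The depth-equivalence class named by (n; l_1 < ... < l_j).

    Trees of this type have a single leaf at depth delta - l_i for each i and
    all remaining leaves at depths delta or delta - 1.  The empty sequence
    names the class of trees depth-equivalent to the maximally balanced tree
    (the minimal-Sackin trees).
    """

    n: int
    ls: tuple[int, ...] = ()

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be positive")
        ls = tuple(int(x) for x in self.ls)
        object.__setattr__(self, "ls", ls)
        if ls:
            if ls[0] < 2:
                raise ValueError("l_1 must be at least 2")
            if any(a >= b for a, b in zip(ls, ls[1:])):
                raise ValueError("l-sequence must be strictly increasing")

    @property
    def j(self) -> int:
        return len(self.ls)


# ---------------------------------------------------------------------------
# Newick I/O (via dendropy)


def _convert_dendropy(node, collapse_unary: bool, fresh: Iterator[str]) -> _PNode:
    kids = node.child_nodes()
    if len(kids) == 1:
        if collapse_unary:
            return _convert_dendropy(kids[0], collapse_unary, fresh)
        name = node.label or (node.taxon.label if node.taxon else None)
        raise UnaryNodeError(
            f"out-degree-1 node {name!r} is not allowed (use collapse_unary to contract it)"
        )
    if not kids:
        label = node.taxon.label if node.taxon is not None else node.label
        if label is None:
            label = next(fresh)
        return _PNode(label=label)
    return _PNode(tuple(_convert_dendropy(c, collapse_unary, fresh) for c in kids))


def _fresh_labels() -> Iterator[str]:
    i = 0
    while True:
        i += 1
        yield f"_leaf{i}"


def parse_newick(text: str, collapse_unary: bool = False) -> PhyloTree:
    """Parse a single Newick tree.

    Branch lengths and internal-node labels are discarded; multifurcations are
    preserved.  Unlabeled leaves receive fresh synthetic labels.  Out-degree-1
    nodes are rejected unless ``collapse_unary`` is set, in which case they are
    contracted.

    Raises :class:`NewickError` (with the reader's position information) on
    malformed input, :class:`UnaryNodeError` on unary nodes, and
    :class:`DuplicateLabelError` on repeated leaf labels.
    """
    import dendropy

    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except DuplicateLabelError:
        raise
    except Exception as exc:  # dendropy's error hierarchy is broad
        msg = str(exc)
        if "Multiple occurrences" in msg or "duplicate" in msg.lower():
            raise DuplicateLabelError(msg) from exc
        raise NewickError(msg) from exc
    root = _convert_dendropy(dtree.seed_node, collapse_unary, _fresh_labels())
    return PhyloTree(root)


def parse_newick_many(text: str, collapse_unary: bool = False) -> list[PhyloTree]:
    """Parse a multi-tree Newick document (one tree per line / per semicolon).

    Lines starting with ``#`` are treated as metadata comments and skipped.
    """
    trees = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        trees.append(parse_newick(line, collapse_unary=collapse_unary))
    return trees


def _needs_quoting(label: str) -> bool:
    return any(ch in label for ch in "()[]{}/\\,;:=*'\"`<>^ \t\n")


def _render(node: _PNode) -> str:
    if not node.children:
        label = str(node.label)
        if _needs_quoting(label):
            return "'" + label.replace("'", "''") + "'"
        return label
    parts = sorted(_render(c) for c in node.children)
    return "(" + ",".join(parts) + ")"


def write_newick(tree: PhyloTree) -> str:
    """Serialize a labeled tree to Newick (labels only, no branch lengths).

    The rendering is canonical: children are ordered by their own rendered
    string, so two equal labeled trees always produce the same output and the
    string doubles as a canonical key for labeled-tree identity.
    """
    return _render(tree.root) + ";"


# ---------------------------------------------------------------------------
# classic constructors


def build_classic(kind: str, n: int) -> TreeShape:
    """Construct a named tree shape with n leaves.

    kind is one of:

    - ``comb``: the caterpillar K_n (every internal node has a leaf child);
    - ``star``: the rooted star RS_n (all leaves at depth 1);
    - ``max_balanced``: the unique maximally balanced bifurcating tree B_n,
      obtained by recursively splitting the leaves floor(n/2) / ceil(n/2);
    - ``fully_symmetric``: B_n for n a power of 2 (all leaves at equal depth);
    - ``f_type``: one representative of the minimal-Sackin class F_n, i.e. the
      fully symmetric tree on 2**m leaves with k = n - 2**m leaves replaced by
      cherries.
    """
    if n < 1:
        raise ValueError("n must be positive")
    if kind == "comb":
        t = _LEAF
        for _ in range(n - 1):
            t = TreeShape((_LEAF, t))
        return t
    if kind == "star":
        if n == 1:
            return _LEAF
        return TreeShape([_LEAF] * n)
    if kind == "max_balanced":
        return _max_balanced(n)
    if kind == "fully_symmetric":
        if n & (n - 1):
            raise ValueError("a fully symmetric tree needs a power-of-2 leaf count")
        return _max_balanced(n)
    if kind == "f_type":
        m = n.bit_length() - 1
        k = n - (1 << m)
        counts = {m + 1: 2 * k} if k else {}
        counts[m] = (1 << m) - k
        return tree_from_depths(DepthMultiset(counts))
    raise ValueError(f"unknown kind {kind!r}")


def _max_balanced(n: int) -> TreeShape:
    if n == 1:
        return _LEAF
    return TreeShape((_max_balanced(n // 2), _max_balanced(n - n // 2)))


def is_maximally_balanced(shape: TreeShape) -> bool:
    """True iff every internal node splits its leaves floor/ceil."""
    stack = [shape]
    while stack:
        v = stack.pop()
        if v.children:
            if len(v.children) != 2:
                return False
            a, b = v.children
            if abs(a.n - b.n) > 1:
                return False
            stack.extend(v.children)
    return True


def tree_from_depths(d: DepthMultiset) -> TreeShape:
    """Materialize a bifurcating shape whose leaf-depth multiset equals ``d``.

    The multiset must satisfy the Kraft equality sum 2**(-depth) = 1.  The
    construction repeatedly pairs two deepest pending nodes under a parent one
    level up (Huffman-style).  When more than two nodes share the maximum
    depth the pairing choice is arbitrary; the resulting depth multiset does
    not depend on it, only the returned representative does.
    """
    if not isinstance(d, DepthMultiset):
        d = DepthMultiset(d)
    ks = d.kraft_sum()
    if ks != 1:
        raise UnrealizableDepthsError(
            f"depth multiset is not realizable by a bifurcating tree: Kraft sum = {ks}"
        )
    # bucket queue keyed by depth, processed deepest first; merging at depth d
    # only ever creates nodes at depth d-1
    pending: dict[int, list[TreeShape]] = {depth: [_LEAF] * c for depth, c in d.items()}
    while True:
        depth = max(pending)
        nodes = pending.pop(depth)
        if depth == 0:
            assert len(nodes) == 1 and not pending
            return nodes[0]
        assert len(nodes) % 2 == 0, "Kraft-feasible multisets pair up at every level"
        merged = [TreeShape((nodes[i], nodes[i + 1])) for i in range(0, len(nodes), 2)]
        pending.setdefault(depth - 1, []).extend(merged)


# ---------------------------------------------------------------------------
# enumeration


_shape_lists: dict[int, list[TreeShape]] = {1: [_LEAF]}


def _shapes(n: int) -> list[TreeShape]:
    if n not in _shape_lists:
        out: list[TreeShape] = []
        for k in range(1, n // 2 + 1):
            left = _shapes(k)
            right = _shapes(n - k)
            if k < n - k:
                out.extend(TreeShape((a, b)) for a in left for b in right)
            else:
                out.extend(
                    TreeShape((left[i], right[j]))
                    for i in range(len(left))
                    for j in range(i, len(right))
                )
        _shape_lists[n] = out
    return _shape_lists[n]


def labeled_count(shape: TreeShape) -> int:
    """Number of phylogenetic trees (leaf labelings) with the given shape."""
    return math.factorial(shape.n) // shape.automorphism_count()


def enumerate_shapes(n: int) -> Iterator[tuple[TreeShape, int]]:
    """Yield every bifurcating shape with n leaves once, with its labeled count.

    The labeled counts sum to (2n-3)!!, the number of bifurcating phylogenetic
    trees with n leaves.  Sub-shapes are memoized across calls; the top level
    is streamed so that large n (around 20) do not pin the full list.
    """
    if n < 1:
        raise ValueError("n must be positive")
    if n == 1:
        yield _LEAF, 1
        return
    fact_n = math.factorial(n)
    for k in range(1, n // 2 + 1):
        left = _shapes(k)
        right = _shapes(n - k)
        if k < n - k:
            for a in left:
                for b in right:
                    s = TreeShape((a, b))
                    yield s, fact_n // s.automorphism_count()
        else:
            for i in range(len(left)):
                for j in range(i, len(right)):
                    s = TreeShape((left[i], right[j]))
                    yield s, fact_n // s.automorphism_count()


def count_shapes(n: int) -> int:
    """Wedderburn-Etherington count of bifurcating shapes with n leaves."""
    return len(_shapes(n)) if n > 1 else 1


def odd_double_factorial(j: int) -> int:
    """(j)!! for odd j, with the conventions (-1)!! = 1!! = 1."""
    out = 1
    while j > 1:
        out *= j
        j -= 2
    return out


# ---------------------------------------------------------------------------
# random fixtures


def random_tree(n: int, mode: str = "bifurcating", seed: int = 0) -> TreeShape:
    """A reproducible random shape with n leaves (test fixture generator).

    ``mode`` is ``bifurcating`` or ``multifurcating``; the latter draws the
    out-degree of each internal node uniformly from 2..min(n, 4), so nodes of
    out-degree >= 3 occur with positive probability.  The RNG stream is local
    to the call: the same (n, mode, seed) always gives the same shape.
    """
    if n < 1:
        raise ValueError("n must be positive")
    if mode not in ("bifurcating", "multifurcating"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = random.Random(f"{mode}:{n}:{seed}")
    return _random_split(n, mode, rng)


def _random_split(n: int, mode: str, rng: random.Random) -> TreeShape:
    if n == 1:
        return _LEAF
    if mode == "bifurcating" or n == 2:
        k = rng.randint(1, n - 1)
        return TreeShape((_random_split(k, mode, rng), _random_split(n - k, mode, rng)))
    parts = rng.randint(2, min(n, 4))
    cuts = sorted(rng.sample(range(1, n), parts - 1))
    sizes = [b - a for a, b in zip([0] + cuts, cuts + [n])]
    return TreeShape(_random_split(s, mode, rng) for s in sizes)


# ---------------------------------------------------------------------------
# classification


def classify_type(shape: Union[TreeShape, PhyloTree]) -> CandidateType | None:
    """Name the depth-equivalence class (n; l_1..l_j) of a bifurcating shape.

    Returns the empty-sequence type when all leaf depths lie in
    {delta, delta-1} (the minimal-Sackin class), a nonempty l-sequence when
    every other depth d is carried by a single leaf with 2 <= delta-d <=
    delta-2, and None when the shape fits neither pattern.
    """
    shape = shape_of(shape)
    if not shape.is_bifurcating():
        raise ValueError("classification is defined for bifurcating shapes only")
    d = depth_multiset(shape)
    delta = d.delta
    ls = []
    for depth, count in d.items():
        if depth in (delta, delta - 1):
            continue
        l = delta - depth
        if count != 1 or l < 2 or l > delta - 2:
            return None
        ls.append(l)
    return CandidateType(d.n, tuple(sorted(ls)))


def balanced_class_predicates(shape: Union[TreeShape, PhyloTree]) -> tuple[bool, bool, bool, bool]:
    """The four equivalent characterizations of the minimal-Sackin class.

    For every bifurcating shape these must agree:

    1. the shape classifies as the empty-sequence type F_n;
    2. all leaf depths lie in {d0, d0+1} for some d0;
    3. every leaf depth is within (strictly) 1 of the mean depth;
    4. the shape is depth-equivalent to the maximally balanced tree B_n.
    """
    shape = shape_of(shape)
    ct = classify_type(shape)
    p1 = ct is not None and ct.ls == ()
    d = depth_multiset(shape)
    p2 = d.delta - min(d) <= 1
    mean = Fraction(sum(depth * c for depth, c in d.items()), d.n)
    p3 = all(abs(Fraction(depth) - mean) < 1 for depth in d)
    p4 = d == depth_multiset(build_classic("max_balanced", d.n))
    return p1, p2, p3, p4
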