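"""Null models of bifurcating phylogenetic trees: Yule and uniform (PDA).

The Yule (Equal-Rate Markov) model grows a tree by repeatedly replacing a
uniformly chosen leaf with a cherry and then labels the leaves by a uniform
random bijection; a labeled tree T has probability

    P_Y(T) = 2**(n-1) / n! * prod over internal v of 1 / (kappa(v) - 1),

where kappa(v) is the number of leaves below v.  The uniform (Proportional to
Distinguishable Arrangements) model makes all (2n-3)!! labeled bifurcating
trees equiprobable; it is realized by inserting leaf k+1 on one of the 2k-1
equiprobable positions (every arc, plus a new root) of the current k-leaf tree.

Besides exact per-tree probabilities and seeded samplers, the module provides
an exhaustive-enumeration expectation oracle for small n, used to verify the
closed-form moments elsewhere in the package.
"""

from __future__ import annotations

import math
import random
from fractions import Fraction
from typing import Iterator, Union

from .indices import depth_statistics, total_cophenetic
from .treecore import (
    PhyloTree,
    TreeShape,
    _PNode,
    depth_multiset,
    enumerate_shapes,
    odd_double_factorial,
    shape_of,
)

__all__ = [
    "MODELS",
    "STATISTICS",
    "yule_probability",
    "uniform_probability",
    "sample_tree",
    "sample_trees",
    "sample_statistics",
    "write_sample_file",
    "expected_by_enumeration",
    "ENUMERATION_LIMIT",
]

MODELS = ("yule", "uniform")
STATISTICS = ("V", "S", "S2", "Ssq", "Phi", "PhiSq", "SPhi")

#: largest n accepted by the exhaustive-enumeration oracle (the number of
#: shapes grows like the Wedderburn-Etherington numbers; 12 leaves -> 451)
ENUMERATION_LIMIT = 12


def yule_probability(tree: Union[PhyloTree, TreeShape]) -> Fraction:
    """Probability of a labeled bifurcating tree under the Yule model.

    The value depends on the tree only through its shape, so a
    :class:`TreeShape` is accepted too (meaning: the probability of any single
    labeling of it).  Multifurcating input is rejected.
    """
    shape = shape_of(tree)
    if not shape.is_bifurcating():
        raise ValueError("the Yule model is defined on bifurcating trees")
    n = shape.n
    denom = math.factorial(n)
    for kappa in shape.subtree_leaf_counts():
        denom *= kappa - 1
    return Fraction(1 << (n - 1), denom)


def uniform_probability(n: int) -> Fraction:
    """Probability 1/(2n-3)!! of any labeled bifurcating tree under the uniform model."""
    if n < 1:
        raise ValueError("n must be positive")
    return Fraction(1, odd_double_factorial(2 * n - 3))


# ---------------------------------------------------------------------------
# samplers
#
# Both samplers grow the tree in flat arrays (children lists indexed by node
# id) and only materialize PhyloTree objects on demand, so that large sample
# counts stay cheap.


def _grow_yule(n: int, rng: random.Random) -> tuple[list[list[int]], int]:
    children: list[list[int]] = [[]]
    leaves = [0]
    for _ in range(n - 1):
        idx = rng.randrange(len(leaves))
        v = leaves[idx]
        a, b = len(children), len(children) + 1
        children.append([])
        children.append([])
        children[v] = [a, b]
        leaves[idx] = a
        leaves.append(b)
    return children, 0


def _grow_uniform(n: int, rng: random.Random) -> tuple[list[list[int]], int]:
    children: list[list[int]] = [[]]
    parent = [-1]
    root = 0
    nonroot: list[int] = []  # each non-root node stands for its parent arc
    for _ in range(n - 1):
        # 2k-1 insertion points for a k-leaf tree: its 2k-2 arcs plus a new root
        choice = rng.randrange(len(nonroot) + 1)
        u = len(children)
        w = len(children) + 1
        children.append([])
        children.append([])
        parent.extend([-1, -1])
        if choice == len(nonroot):  # new root above the old one
            children[u] = [root, w]
            parent[root] = u
            parent[w] = u
            nonroot.extend([root, w])
            root = u
        else:
            v = nonroot[choice]
            p = parent[v]
            children[p][children[p].index(v)] = u
            children[u] = [v, w]
            parent[u] = p
            parent[v] = u
            parent[w] = u
            nonroot.extend([u, w])
    return children, root


def _leaf_ids(children: list[list[int]], root: int) -> list[int]:
    order = []
    stack = [root]
    while stack:
        v = stack.pop()
        if children[v]:
            stack.extend(children[v])
        else:
            order.append(v)
    return order


def _to_phylo(children: list[list[int]], root: int, labels: dict[int, str]) -> PhyloTree:
    def build(v: int) -> _PNode:
        if not children[v]:
            return _PNode(label=labels[v])
        return _PNode(tuple(build(c) for c in children[v]))

    return PhyloTree(build(root))


def sample_trees(n: int, model: str, size: int, seed: int = 0) -> Iterator[PhyloTree]:
    """Yield ``size`` independent labeled trees from the given model, seeded.

    Labels are "1".."n".  Under Yule the labels are a uniform random
    bijection, as the model prescribes; under the uniform model the leaf
    created at step k is labeled k+1.
    """
    if n < 1:
        raise ValueError("n must be positive")
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}")
    rng = random.Random(f"{model}:{n}:{seed}")
    for _ in range(size):
        if model == "yule":
            children, root = _grow_yule(n, rng)
            leaves = _leaf_ids(children, root)
            perm = list(range(1, n + 1))
            rng.shuffle(perm)
            labels = {v: str(p) for v, p in zip(leaves, perm)}
        else:
            children, root = _grow_uniform(n, rng)
            leaves = _leaf_ids(children, root)
            # uniform growth labels leaves in creation order: node ids of
            # leaves increase with creation (the first leaf is node 0)
            labels = {v: str(i + 1) for i, v in enumerate(sorted(leaves))}
        yield _to_phylo(children, root, labels)


def sample_tree(n: int, model: str, seed: int = 0) -> PhyloTree:
    """A single seeded draw from the given model."""
    return next(sample_trees(n, model, 1, seed))


def _stats_of_arrays(children: list[list[int]], root: int) -> tuple[float, int, int]:
    """(V, S, Phi) of a grown tree, computed directly on the arrays."""
    depth = [0] * len(children)
    order = []
    stack = [root]
    while stack:
        v = stack.pop()
        order.append(v)
        for c in children[v]:
            depth[c] = depth[v] + 1
            stack.append(c)
    kappa = [1] * len(children)
    S = 0
    S2 = 0
    nleaves = 0
    phi = 0
    for v in reversed(order):
        if children[v]:
            kappa[v] = sum(kappa[c] for c in children[v])
            if v != root:
                phi += kappa[v] * (kappa[v] - 1) // 2
        else:
            d = depth[v]
            S += d
            S2 += d * d
            nleaves += 1
    V = S2 / nleaves - (S / nleaves) ** 2
    return V, S, phi


def sample_statistics(n: int, model: str, size: int, seed: int = 0) -> dict[str, list[float]]:
    """Seeded Monte-Carlo draws of (V, S, Phi) under a model, shape-level fast path.

    Returns lists of length ``size`` keyed by "V", "S", "Phi".  The label
    assignment step is skipped (the three statistics are shape functions), so
    this is the sampler to use for moment estimation.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}")
    rng = random.Random(f"stats:{model}:{n}:{seed}")
    grow = _grow_yule if model == "yule" else _grow_uniform
    out = {"V": [], "S": [], "Phi": []}
    for _ in range(size):
        children, root = grow(n, rng)
        V, S, phi = _stats_of_arrays(children, root)
        out["V"].append(V)
        out["S"].append(float(S))
        out["Phi"].append(float(phi))
    return out


def write_sample_file(path, n: int, model: str, size: int, seed: int = 0) -> None:
    """Write sampled trees as a multi-tree Newick file with a metadata header."""
    from .treecore import write_newick

    with open(path, "w") as fh:
        fh.write(f"# depthvar sample n={n} model={model} count={size} seed={seed}\n")
        for t in sample_trees(n, model, size, seed):
            fh.write(write_newick(t) + "\n")


# ---------------------------------------------------------------------------
# enumeration oracle


def _statistic_value(shape: TreeShape, statistic: str) -> int | Fraction:
    st = depth_statistics(depth_multiset(shape))
    if statistic == "V":
        return st.V
    if statistic == "S":
        return st.S
    if statistic == "S2":
        return st.S2
    if statistic == "Ssq":
        return st.S * st.S
    phi = total_cophenetic(shape)
    if statistic == "Phi":
        return phi
    if statistic == "PhiSq":
        return phi * phi
    if statistic == "SPhi":
        return st.S * phi
    raise ValueError(f"unknown statistic {statistic!r}")


def expected_by_enumeration(n: int, statistic: str, model: str) -> Fraction:
    """Exact model expectation of a shape statistic by exhaustive enumeration.

    Sums statistic(shape) * (labeled count of shape) * (per-tree probability)
    over every bifurcating shape with n leaves.  Available statistics: V, S,
    S2 (sum of squared depths), Ssq (S squared), Phi, PhiSq, SPhi.  Refuses
    n beyond :data:`ENUMERATION_LIMIT`.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}")
    if statistic not in STATISTICS:
        raise ValueError(f"unknown statistic {statistic!r}")
    if n > ENUMERATION_LIMIT:
        raise ValueError(
            f"enumeration oracle limited to n <= {ENUMERATION_LIMIT} (requested n={n})"
        )
    total = Fraction(0)
    unif = uniform_probability(n)
    for shape, count in enumerate_shapes(n):
        p = yule_probability(shape) if model == "yule" else unif
        total += Fraction(_statistic_value(shape, statistic)) * count * p
    return total
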