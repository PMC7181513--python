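"""Shape indices on rooted trees: S, mean depth, S^(2), V and Phi.

All values are exact: integers for S, S^(2) and Phi, ``fractions.Fraction``
for the mean depth and the variance.  Floating point appears only at output
boundaries.  The depth-based statistics are functions of the leaf-depth
multiset alone, so depth-equivalent trees always receive identical values.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Union

import pandas as pd

from .treecore import DepthMultiset, PhyloTree, TreeShape, depth_multiset, shape_of

__all__ = [
    "DepthStatistics",
    "depth_statistics",
    "variance_of_depths",
    "total_cophenetic",
    "total_cophenetic_pairwise",
    "indices_table",
]


@dataclass(frozen=True)
class DepthStatistics:
    """Exact depth-based statistics of a tree with n leaves.

    S is the Sackin index (sum of leaf depths), Shat the mean depth S/n,
    S2 the sum of squared depths, and V the population variance of the depth
    multiset, V = S2/n - (S/n)^2.  n^2 * V is always a non-negative integer.
    """

    n: int
    S: int
    Shat: Fraction
    S2: int
    V: Fraction


def depth_statistics(d: Union[DepthMultiset, TreeShape, PhyloTree]) -> DepthStatistics:
    """Compute S, mean depth, S^(2) and V from a depth multiset (or a tree)."""
    if not isinstance(d, DepthMultiset):
        d = depth_multiset(d)
    n = d.n
    S = sum(depth * c for depth, c in d.items())
    S2 = sum(depth * depth * c for depth, c in d.items())
    V = Fraction(n * S2 - S * S, n * n)
    assert V >= 0
    return DepthStatistics(n=n, S=S, Shat=Fraction(S, n), S2=S2, V=V)


def variance_of_depths(tree: Union[DepthMultiset, TreeShape, PhyloTree]) -> Fraction:
    """The variance of the leaves' depths, as an exact rational."""
    return depth_statistics(tree).V


def total_cophenetic(tree: Union[TreeShape, PhyloTree]) -> int:
    """Total cophenetic index: sum over leaf pairs of the depth of their LCA.

    Computed in O(n) by aggregation: a pair of leaves has LCA depth equal to
    its number of non-root common ancestors, so Phi equals the sum of
    C(kappa(v), 2) over all non-root internal nodes v.
    """
    shape = shape_of(tree)
    total = 0
    for child in shape.children:
        for v in child.iter_nodes():
            if v.children:
                total += v.n * (v.n - 1) // 2
    return total


def total_cophenetic_pairwise(tree: Union[TreeShape, PhyloTree]) -> int:
    """Total cophenetic index by brute force over all leaf pairs.

    Quadratic in n; serves as the independent cross-check of the aggregated
    computation.
    """
    shape = shape_of(tree)
    # root-to-leaf ancestor paths as tuples of positional node ids (subtree
    # objects may be shared between positions, so ids are per visit, not per object)
    paths: list[tuple[int, ...]] = []
    counter = iter(range(10**9))

    def walk(v: TreeShape, prefix: tuple[int, ...]):
        vid = next(counter)
        if not v.children:
            paths.append(prefix + (vid,))
            return
        for c in v.children:
            walk(c, prefix + (vid,))

    walk(shape, ())
    total = 0
    for i in range(len(paths)):
        for j in range(i + 1, len(paths)):
            a, b = paths[i], paths[j]
            common = 0
            for x, y in zip(a, b):
                if x != y:
                    break
                common += 1
            total += common - 1  # LCA depth = common ancestors - 1 (root at depth 0)
    return total


def indices_table(trees, precision: int = 4, exact: bool = False) -> pd.DataFrame:
    """One row of shape statistics per input tree.

    Columns: n, depth, S, Shat, S2, V, Phi.  With ``exact`` the rational
    columns are rendered as p/q strings instead of rounded floats.
    """
    rows = []
    for t in trees:
        d = depth_multiset(t)
        st = depth_statistics(d)
        phi = total_cophenetic(t)
        if exact:
            shat, v = str(st.Shat), str(st.V)
        else:
            shat, v = round(float(st.Shat), precision), round(float(st.V), precision)
        rows.append(
            {"n": st.n, "depth": d.delta, "S": st.S, "Shat": shat, "S2": st.S2, "V": v, "Phi": phi}
        )
    return pd.DataFrame(rows, columns=["n", "depth", "S", "Shat", "S2", "V", "Phi"])
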