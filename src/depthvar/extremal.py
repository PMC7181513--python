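"""Extremal values of the leaf-depth variance V over bifurcating trees.

The maximum of V on n-leaf trees is attained exactly at the comb K_n and has
the closed form (n-1)(n-2)(n^2+3n-6)/(12 n^2).

The minimum over bifurcating trees is subtler.  Minimizers always belong to a
small family of depth-equivalence classes named (n; l_1 < ... < l_j): trees
with a single leaf at depth delta - l_i for each i and all other leaves at
depths delta or delta - 1.  Writing n = 2**m + k with m = floor(log2 n), a
candidate class is feasible or not according to a four-case rule on
k + sum(2**l_i - 1), and its variance has an exact rational closed form, so
the minimum can be found by scanning the subsets of {5, ..., m} as the
l-sequence - O(n log n) work overall - with no tree ever materialized.
Comparisons use the integer numerator n*(p1 + sum l^2) - (p1 + sum l)^2 scaled
to n^2, so ties are exact and every co-minimizing class is reported.

For n <= 183 the minimum sits at the maximally balanced class (empty
l-sequence); the first leaf count where that fails is n = 184, and the
pattern of optimal l-sequences over each dyadic block [2**m, 2**(m+1)) shows
striking regularities that :func:`scan_min_variance` exposes via run-length
summaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from functools import lru_cache
from itertools import combinations

import pandas as pd

from .treecore import CandidateType, DepthMultiset

__all__ = [
    "InfeasibleTypeError",
    "TypeProfile",
    "ExtremalResult",
    "ScanResult",
    "max_variance",
    "type_profile",
    "type_depth_multiset",
    "type_variance",
    "min_variance",
    "scan_min_variance",
]


class InfeasibleTypeError(ValueError):
    """No bifurcating tree belongs to the requested candidate type."""


@dataclass(frozen=True)
class TypeProfile:
    """Leaf-depth profile of a candidate type (n; l_1..l_j).

    p0 and p1 are the numbers of leaves at depths delta and delta-1; together
    with the j single leaves at depths delta - l_i they account for all n
    leaves.  ``feasible`` is False when no bifurcating tree has this profile,
    in which case the other fields are None.
    """

    n: int
    ls: tuple[int, ...]
    feasible: bool
    p0: int | None = None
    p1: int | None = None
    delta: int | None = None


@dataclass(frozen=True)
class ExtremalResult:
    """Minimum variance over bifurcating trees with n leaves, with all argmin types."""

    n: int
    min_value: Fraction
    argmin_types: tuple[CandidateType, ...]

    @property
    def at_max_balanced(self) -> bool:
        """True iff the maximally balanced class attains the minimum."""
        return any(t.ls == () for t in self.argmin_types)


def max_variance(n: int) -> Fraction:
    """Maximum of V over all rooted trees with n leaves (attained at the comb)."""
    if n < 1:
        raise ValueError("n must be positive")
    return Fraction((n - 1) * (n - 2) * (n * n + 3 * n - 6), 12 * n * n)


def _validate_ls(ls) -> tuple[int, ...]:
    ls = tuple(int(x) for x in ls)
    if ls and (ls[0] < 2 or any(a >= b for a, b in zip(ls, ls[1:]))):
        raise ValueError("l-sequence must be strictly increasing with l_1 >= 2")
    return ls


def type_profile(n: int, ls=()) -> TypeProfile:
    """Feasibility and depth profile of the candidate type (n; l_1..l_j).

    With m = floor(log2 n), k = n - 2**m, A = k + sum(2**l_i - 1) and
    B = k + sum(2**(l_i - 1) - 1):

    - A == 0: the fully symmetric tree (p1 = 0, depth m);
    - 0 < A <= 2**m: p1 = 2**m - A, depth m + 1;
    - B > 2**m: p1 = 3 * 2**m - A, depth m + 2;
    - otherwise (B <= 2**m < A): no such tree exists.
    """
    if n < 1:
        raise ValueError("n must be positive")
    ls = _validate_ls(ls)
    m = n.bit_length() - 1
    k = n - (1 << m)
    A = k + sum((1 << l) - 1 for l in ls)
    B = k + sum((1 << (l - 1)) - 1 for l in ls)
    pow2m = 1 << m
    if A == 0:
        return TypeProfile(n, ls, True, p0=n - len(ls), p1=0, delta=m)
    if A <= pow2m:
        p1 = pow2m - A
        return TypeProfile(n, ls, True, p0=n - p1 - len(ls), p1=p1, delta=m + 1)
    if B > pow2m:
        p1 = 3 * pow2m - A
        return TypeProfile(n, ls, True, p0=n - p1 - len(ls), p1=p1, delta=m + 2)
    return TypeProfile(n, ls, False)


def type_depth_multiset(n: int, ls=()) -> DepthMultiset:
    """The leaf-depth multiset shared by all trees of type (n; l_1..l_j)."""
    prof = type_profile(n, ls)
    if not prof.feasible:
        raise InfeasibleTypeError(f"no bifurcating tree of type ({n}; {ls})")
    counts: dict[int, int] = {}
    if prof.p0:
        counts[prof.delta] = prof.p0
    if prof.p1:
        counts[prof.delta - 1] = prof.p1
    for l in prof.ls:
        counts[prof.delta - l] = counts.get(prof.delta - l, 0) + 1
    return DepthMultiset(counts)


def type_variance(n: int, ls=()) -> Fraction:
    """Exact variance of the leaves' depths for trees of type (n; l_1..l_j).

    Equals (n*(p1 + sum l_i^2) - (p1 + sum l_i)^2) / n^2; for the empty
    sequence this reduces to 2k(2**m - k)/n^2, the variance of the
    minimal-Sackin (maximally balanced) class.
    """
    prof = type_profile(n, ls)
    if not prof.feasible:
        raise InfeasibleTypeError(f"no bifurcating tree of type ({n}; {ls})")
    sl = sum(prof.ls)
    sl2 = sum(l * l for l in prof.ls)
    num = n * (prof.p1 + sl2) - (prof.p1 + sl) ** 2
    return Fraction(num, n * n)


# ---------------------------------------------------------------------------
# minimum search


@lru_cache(maxsize=None)
def _subset_table(m: int) -> tuple[tuple[tuple[int, ...], int, int, int, int], ...]:
    """Per-subset data for l-sequences drawn from {5..m}.

    Entries are (ls, sum(2**l - 1), sum(2**(l-1) - 1), sum l, sum l^2),
    enumerated in lexicographic order starting with the empty sequence.
    """
    values = range(5, m + 1)
    out = []
    for j in range(0, max(0, m - 4) + 1):
        for ls in combinations(values, j):
            a0 = sum((1 << l) - 1 for l in ls)
            b0 = sum((1 << (l - 1)) - 1 for l in ls)
            out.append((ls, a0, b0, sum(ls), sum(l * l for l in ls)))
    return tuple(out)


def min_variance(n: int) -> ExtremalResult:
    """Minimum of V over bifurcating trees with n leaves, with all argmin types.

    Scans every candidate l-sequence with 5 <= l_1 < ... < l_j <= floor(log2 n)
    (including the empty one), skipping infeasible types, and compares exact
    integer numerators - no floating point, so ties are reported exactly.
    """
    if n < 1:
        raise ValueError("n must be positive")
    m = n.bit_length() - 1
    k = n - (1 << m)
    pow2m = 1 << m
    best_num = None
    argmin: list[tuple[int, ...]] = []
    for ls, a0, b0, sl, sl2 in _subset_table(m):
        A = k + a0
        if A == 0:
            p1 = 0
        elif A <= pow2m:
            p1 = pow2m - A
        elif k + b0 > pow2m:
            p1 = 3 * pow2m - A
        else:
            continue  # infeasible band
        num = n * (p1 + sl2) - (p1 + sl) ** 2
        if best_num is None or num < best_num:
            best_num = num
            argmin = [ls]
        elif num == best_num:
            argmin.append(ls)
    return ExtremalResult(
        n=n,
        min_value=Fraction(best_num, n * n),
        argmin_types=tuple(CandidateType(n, ls) for ls in argmin),
    )


# ---------------------------------------------------------------------------
# range scans


@dataclass(frozen=True)
class ScanResult:
    """Per-n minimum-variance results over a range, with summary views."""

    results: tuple[ExtremalResult, ...]

    def to_frame(self, precision: int = 4) -> pd.DataFrame:
        """Tabular view: n, m, k, exact and float minimum, argmin l-sequences."""
        rows = []
        for r in self.results:
            m = r.n.bit_length() - 1
            rows.append(
                {
                    "n": r.n,
                    "m": m,
                    "k": r.n - (1 << m),
                    "min_V_exact": f"{r.min_value.numerator}/{r.min_value.denominator}",
                    "min_V_float": round(float(r.min_value), precision),
                    "argmin_ls": ";".join(",".join(map(str, t.ls)) or "-" for t in r.argmin_types),
                    "is_max_balanced": r.at_max_balanced,
                }
            )
        return pd.DataFrame(rows)

    def balanced_ns(self) -> list[int]:
        """Leaf counts whose minimum is attained at the maximally balanced class."""
        return [r.n for r in self.results if r.at_max_balanced]

    def balanced_fraction(self) -> float:
        """Fraction of scanned n whose minimum sits at the maximally balanced class."""
        return len(self.balanced_ns()) / len(self.results)

    def first_unbalanced_n(self) -> int | None:
        """Smallest scanned n whose argmin set excludes the empty l-sequence."""
        for r in sorted(self.results, key=lambda r: r.n):
            if not r.at_max_balanced:
                return r.n
        return None

    def run_lengths(self) -> dict[int, list[tuple[int, tuple[tuple[int, ...], ...]]]]:
        """Run-length encoding of the argmin l-sequences, per dyadic block.

        Within each block [2**m, 2**(m+1)) the scanned n are taken in
        descending order and consecutive n sharing the same argmin set are
        grouped; the value is a list of (run length, argmin l-sequences).
        """
        by_block: dict[int, list[ExtremalResult]] = {}
        for r in self.results:
            by_block.setdefault(r.n.bit_length() - 1, []).append(r)
        out: dict[int, list[tuple[int, tuple[tuple[int, ...], ...]]]] = {}
        for m, rs in by_block.items():
            rs = sorted(rs, key=lambda r: -r.n)
            runs: list[tuple[int, tuple[tuple[int, ...], ...]]] = []
            for r in rs:
                key = tuple(sorted(t.ls for t in r.argmin_types))
                if runs and runs[-1][1] == key:
                    runs[-1] = (runs[-1][0] + 1, key)
                else:
                    runs.append((1, key))
            out[m] = runs
        return out


def scan_min_variance(n_lo: int, n_hi: int) -> ScanResult:
    """Run the minimum-variance search for every n in [n_lo, n_hi]."""
    if not (2 <= n_lo <= n_hi):
        raise ValueError("need 2 <= n_lo <= n_hi")
    return ScanResult(tuple(min_variance(n) for n in range(n_lo, n_hi + 1)))
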