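"""Exact moments of tree-shape indices under the Yule and uniform models.

Everything here is closed-form and exact (``fractions.Fraction`` over big
integers); floating point appears only in the asymptotic helpers and display
paths.  The key special quantities are the harmonic numbers H_n and
H_n^(2), the odd double factorial (2n-3)!! (the number of labeled
bifurcating trees), the ratio r_n = (2n-2)!!/(2n-3)!! ~ sqrt(pi n), and the
splitting weights

    C_{k,n-k} = (1/2) C(n,k) (2k-3)!! (2(n-k)-3)!! / (2n-3)!!,

which give the probability that the root of a uniform tree splits its n
leaves into a given k / n-k bipartition.  Uniform-model expectations satisfy
recurrences X_n = 2 sum_k C_{k,n-k} X_k + forcing(n) whose forcing term is a
polynomial plus a polynomial multiple of r_n; :func:`solve_recurrence` turns
such a recurrence into its closed form in the binomial basis, and
:func:`iterate_recurrence` provides the independent direct iteration.

Headline formulas (verified against exhaustive enumeration in the tests):

- Yule:    E(V_n) = 2(n+1)/n * H_n + 1/n - 5
- uniform: E(V_n) = (2n-1)(n-1)/(3n) - (n-1)/(2n) * r_n
- uniform variance of the Sackin index, variance of the total cophenetic
  index, and their covariance (with limiting Pearson correlation
  ((52-15pi)/60) / sqrt((10-3pi)/3 * (56-15pi)/240) ~ 0.965).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

import pandas as pd

from .treecore import odd_double_factorial

__all__ = [
    "SpecialNumbers",
    "RecurrenceSpec",
    "special_numbers",
    "harmonic",
    "harmonic2",
    "dfact_ratio",
    "dfact_ratio_float",
    "splitting_weights",
    "poly_to_binomial",
    "solve_recurrence",
    "iterate_recurrence",
    "eval_closed_form",
    "yule_moments",
    "uniform_moments",
    "uniform_covariances",
    "limit_correlation",
    "moment_table",
    "PROP2_SPEC",
    "PROP3_SPEC",
]


# ---------------------------------------------------------------------------
# special numbers


def harmonic(n: int) -> Fraction:
    """H_n = sum_{i<=n} 1/i, exact."""
    return sum((Fraction(1, i) for i in range(1, n + 1)), Fraction(0))


def harmonic2(n: int) -> Fraction:
    """H_n^(2) = sum_{i<=n} 1/i^2, exact."""
    return sum((Fraction(1, i * i) for i in range(1, n + 1)), Fraction(0))


def dfact_ratio(n: int) -> Fraction:
    """r_n = (2n-2)!!/(2n-3)!!, exact ((2n-2)!! = 2**(n-1) (n-1)!)."""
    if n < 1:
        raise ValueError("n must be positive")
    return Fraction((1 << (n - 1)) * math.factorial(n - 1), odd_double_factorial(2 * n - 3))


_EULER_GAMMA = 0.5772156649015329


def harmonic_float(n: int) -> float:
    """H_n in floating point (asymptotic expansion for large n)."""
    if n < 100:
        return float(harmonic(n))
    inv = 1.0 / n
    return math.log(n) + _EULER_GAMMA + inv / 2 - inv * inv / 12


def dfact_ratio_float(n: int) -> float:
    """r_n in floating point via log-gamma; r_n ~ sqrt(pi n)."""
    if n < 2:
        return 1.0
    return math.exp(
        (n - 1) * math.log(4.0) + 2 * math.lgamma(n) - math.lgamma(2 * n - 1)
    )


def splitting_weights(n: int) -> tuple[Fraction, ...]:
    """The row (C_{k,n-k})_{k=1..n-1}; symmetric and summing to 1 for n >= 2."""
    if n < 2:
        raise ValueError("splitting weights need n >= 2")
    dn = odd_double_factorial(2 * n - 3)
    return tuple(
        Fraction(
            math.comb(n, k)
            * odd_double_factorial(2 * k - 3)
            * odd_double_factorial(2 * (n - k) - 3),
            2 * dn,
        )
        for k in range(1, n)
    )


@dataclass(frozen=True)
class SpecialNumbers:
    """H_n, H_n^(2), (2n-3)!!, r_n and the splitting-weight row for one n."""

    n: int
    H: Fraction
    H2: Fraction
    dfact_odd: int
    r: Fraction
    C_row: tuple[Fraction, ...]


def special_numbers(n: int) -> SpecialNumbers:
    if n < 1:
        raise ValueError("n must be positive")
    return SpecialNumbers(
        n=n,
        H=harmonic(n),
        H2=harmonic2(n),
        dfact_odd=odd_double_factorial(2 * n - 3),
        r=dfact_ratio(n),
        C_row=splitting_weights(n) if n >= 2 else (),
    )


# ---------------------------------------------------------------------------
# recurrence machinery


@dataclass(frozen=True)
class RecurrenceSpec:
    """A uniform-model recurrence X_n = 2 sum_k C_{k,n-k} X_k + forcing(n).

    The forcing term is sum_l a_l C(n,l) + r_n sum_l b_l C(n,l), expressed in
    the binomial basis with no constant term; ``a`` and ``b`` are the
    coefficient tuples (indices starting at l = 1) and ``X1`` the initial
    condition.  Empty coefficient lists are padded with a single zero.
    """

    a: tuple[Fraction, ...]
    b: tuple[Fraction, ...]
    X1: Fraction

    def __post_init__(self):
        object.__setattr__(self, "a", tuple(Fraction(x) for x in self.a) or (Fraction(0),))
        object.__setattr__(self, "b", tuple(Fraction(x) for x in self.b) or (Fraction(0),))
        object.__setattr__(self, "X1", Fraction(self.X1))

    def forcing(self, n: int) -> Fraction:
        poly = sum((c * math.comb(n, l + 1) for l, c in enumerate(self.a)), Fraction(0))
        rpoly = sum((c * math.comb(n, l + 1) for l, c in enumerate(self.b)), Fraction(0))
        return poly + dfact_ratio(n) * rpoly


def _stirling2_table(p: int) -> list[list[int]]:
    S = [[0] * (p + 1) for _ in range(p + 1)]
    S[0][0] = 1
    for i in range(1, p + 1):
        for j in range(1, i + 1):
            S[i][j] = j * S[i - 1][j] + S[i - 1][j - 1]
    return S


def poly_to_binomial(coeffs: Sequence) -> tuple[Fraction, ...]:
    """Convert a polynomial with no constant term from the power basis to the
    binomial basis: sum_p c_p n**p = sum_l out_l C(n, l).

    ``coeffs[p-1]`` is the coefficient of n**p.  Uses n**p =
    sum_l S(p,l) l! C(n,l) with S the Stirling numbers of the second kind.
    """
    coeffs = [Fraction(c) for c in coeffs]
    p = len(coeffs)
    S = _stirling2_table(p)
    out = [Fraction(0)] * p
    for power, c in enumerate(coeffs, start=1):
        for l in range(1, power + 1):
            out[l - 1] += c * S[power][l] * math.factorial(l)
    return tuple(out)


def solve_recurrence(spec: RecurrenceSpec) -> tuple[tuple[Fraction, ...], tuple[Fraction, ...]]:
    """Closed form of a splitting-weight recurrence.

    Returns (a_hat, b_hat) such that the solution is

        X_n = sum_{l=1}^{s+1} a_hat_l C(n,l) + r_n sum_{l=1}^{r} b_hat_l C(n,l)

    where r = len(spec.a) and s = len(spec.b).  The coefficient maps are

        a_hat_1   = X_1 - a_1
        a_hat_l   = l (2l-2)!!/(2l-3)!! (b_l / l + b_{l-1} / (l-1)),  2 <= l <= s
        a_hat_s+1 = (s+1) (2s)!! / (s (2s-1)!!) b_s
        b_hat_l   = (2l-3)!!/(2l-2)!! a_l.
    """
    a, b, X1 = spec.a, spec.b, spec.X1
    s = len(b)
    a_hat = [Fraction(0)] * (s + 1)
    a_hat[0] = X1 - a[0]
    for l in range(2, s + 1):
        a_hat[l - 1] = l * dfact_ratio(l) * (b[l - 1] / l + b[l - 2] / (l - 1))
    even = (1 << s) * math.factorial(s)  # (2s)!!
    a_hat[s] = Fraction((s + 1) * even, s * odd_double_factorial(2 * s - 1)) * b[s - 1]
    b_hat = tuple(al / dfact_ratio(l + 1) for l, al in enumerate(a))
    return tuple(a_hat), b_hat


def eval_closed_form(
    coeffs: tuple[tuple[Fraction, ...], tuple[Fraction, ...]], n: int
) -> Fraction:
    """Evaluate the closed form returned by :func:`solve_recurrence` at n."""
    a_hat, b_hat = coeffs
    poly = sum((c * math.comb(n, l + 1) for l, c in enumerate(a_hat)), Fraction(0))
    rpoly = sum((c * math.comb(n, l + 1) for l, c in enumerate(b_hat)), Fraction(0))
    return poly + dfact_ratio(n) * rpoly


def iterate_recurrence(spec: RecurrenceSpec, n_max: int) -> list[Fraction]:
    """Direct exact iteration of the recurrence: [X_1, ..., X_{n_max}].

    Quadratic cost; the independent check of :func:`solve_recurrence`.
    """
    if n_max < 1:
        raise ValueError("n_max must be positive")
    xs = [spec.X1]
    for n in range(2, n_max + 1):
        C = splitting_weights(n)
        xs.append(2 * sum(C[k - 1] * xs[k - 1] for k in range(1, n)) + spec.forcing(n))
    return xs


#: recurrence satisfied by E_U(S^(2)_n): forcing 2n r_n - 3n, X_1 = 0
PROP2_SPEC = RecurrenceSpec(a=(-3,), b=(2,), X1=0)
#: recurrence satisfied by E_U(S^2_n): forcing (5/2 n^2) r_n - n(5n-2), i.e.
#: a = (-3, -10), b = (5/2, 5) in the binomial basis, X_1 = 0
PROP3_SPEC = RecurrenceSpec(a=(-3, -10), b=(Fraction(5, 2), 5), X1=0)


# ---------------------------------------------------------------------------
# closed-form moments


@dataclass(frozen=True)
class YuleMoments:
    """Yule-model expectations: E(S), E(S^(2)), E(S^2), E(V), exact."""

    n: int
    ES: Fraction
    ES2sum: Fraction  # E(S^(2)): expected sum of squared depths
    ESsq: Fraction  # E(S^2)
    EV: Fraction


@dataclass(frozen=True)
class UniformMoments:
    """Uniform-model expectations: E(S), E(S^(2)), E(S^2), E(V), exact."""

    n: int
    ES: Fraction
    ES2sum: Fraction
    ESsq: Fraction
    EV: Fraction


@dataclass(frozen=True)
class UniformCovariances:
    """Theorem-level uniform-model second moments of S and Phi."""

    n: int
    var_S: Fraction
    var_Phi: Fraction
    cov_S_Phi: Fraction


def yule_moments(n: int) -> YuleMoments:
    """Exact Yule-model moments of the depth statistics.

    E(V_n) = 2(n+1)/n H_n + 1/n - 5; internally consistent with
    E(V) = E(S^(2))/n - E(S^2)/n^2.
    """
    if n < 1:
        raise ValueError("n must be positive")
    H = harmonic(n)
    H2 = harmonic2(n)
    ES = 2 * n * (H - 1)
    ES2sum = 2 * n * (2 * H * H - 3 * H - 2 * H2 + 3)
    ESsq = 4 * n * n * (H * H - H2 - 2 * H) - 2 * n * H + 11 * n * n - n
    EV = Fraction(2 * (n + 1), n) * H + Fraction(1, n) - 5
    assert EV == ES2sum / n - ESsq / Fraction(n * n)
    return YuleMoments(n=n, ES=Fraction(ES), ES2sum=Fraction(ES2sum), ESsq=Fraction(ESsq), EV=EV)


def uniform_moments(n: int) -> UniformMoments:
    """Exact uniform-model moments of the depth statistics.

    E(V_n) = (2n-1)(n-1)/(3n) - (n-1)/(2n) r_n, with
    E(S) = n (r_n - 1), E(S^(2)) = (4n-1)n - 3n r_n and
    E(S^2) = n(10n^2-1)/3 - n(5n+1)/2 r_n.
    """
    if n < 1:
        raise ValueError("n must be positive")
    r = dfact_ratio(n)
    ES = n * (r - 1)
    ES2sum = (4 * n - 1) * n - 3 * n * r
    ESsq = Fraction(n * (10 * n * n - 1), 3) - Fraction(n * (5 * n + 1), 2) * r
    EV = Fraction((2 * n - 1) * (n - 1), 3 * n) - Fraction(n - 1, 2 * n) * r
    assert EV == ES2sum / n - ESsq / Fraction(n * n)
    return UniformMoments(n=n, ES=Fraction(ES), ES2sum=Fraction(ES2sum), ESsq=ESsq, EV=EV)


def uniform_covariances(n: int) -> UniformCovariances:
    """Exact uniform-model variances of S and Phi and their covariance."""
    if n < 1:
        raise ValueError("n must be positive")
    r = dfact_ratio(n)
    c2 = Fraction(n * (n - 1), 2)
    var_S = (
        Fraction(n * (10 * n * n - 3 * n - 1), 3)
        - Fraction((n + 1) * n, 2) * r
        - n * n * r * r
    )
    var_Phi = (
        c2 * Fraction((2 * n - 1) * (7 * n * n - 3 * n - 2), 30)
        - c2 * Fraction(5 * n * n - n - 2, 32) * r
        - Fraction(1, 4) * c2 * c2 * r * r
    )
    cov = (
        c2 * Fraction(26 * n * n - 5 * n - 4, 15)
        - Fraction(3 * n + 2, 8) * c2 * r
        - Fraction(n, 2) * c2 * r * r
    )
    return UniformCovariances(n=n, var_S=var_S, var_Phi=var_Phi, cov_S_Phi=cov)


#: leading asymptotic constants: var_U(S_n)/n^3, var_U(Phi_n)/n^5, Cov_U/n^4
ASYMPTOTIC_VAR_S = (10 - 3 * math.pi) / 3
ASYMPTOTIC_VAR_PHI = (56 - 15 * math.pi) / 240
ASYMPTOTIC_COV = (52 - 15 * math.pi) / 60


def limit_correlation() -> float:
    """Limiting uniform-model Pearson correlation of S_n and Phi_n (~0.965)."""
    return ASYMPTOTIC_COV / math.sqrt(ASYMPTOTIC_VAR_S * ASYMPTOTIC_VAR_PHI)


def moment_table(ns, precision: int = 4, exact: bool = False) -> pd.DataFrame:
    """One row per n with every closed-form quantity, float or p/q rendering."""
    rows = []
    for n in ns:
        y = yule_moments(n)
        u = uniform_moments(n)
        c = uniform_covariances(n)
        vals = {
            "E_Y_S": y.ES,
            "E_Y_S2sum": y.ES2sum,
            "E_Y_Ssq": y.ESsq,
            "E_Y_V": y.EV,
            "E_U_S": u.ES,
            "E_U_S2sum": u.ES2sum,
            "E_U_Ssq": u.ESsq,
            "E_U_V": u.EV,
            "Var_U_S": c.var_S,
            "Var_U_Phi": c.var_Phi,
            "Cov_U_S_Phi": c.cov_S_Phi,
        }
        row = {"n": n}
        for key, v in vals.items():
            row[key] = str(v) if exact else round(float(v), precision)
        rows.append(row)
    return pd.DataFrame(rows)
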