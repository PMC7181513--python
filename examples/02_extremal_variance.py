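"""Find the bifurcating trees with extremal depth variance.

The maximum of V is always attained at the comb.  The minimum is attained at
the maximally balanced class for every n up to 183, but from n = 184 on that
almost always fails: the search over candidate types (n; l_1 < ... < l_j)
finds the true minimizers.  Here n = 184 is dissected, then a scan shows how
rare balanced minimizers become in a whole dyadic block.
"""

from depthvar import max_variance, min_variance, scan_min_variance, type_variance

n = 184
res = min_variance(n)
print(f"n = {n}")
print(f"  max V (comb)      = {float(max_variance(n)):.4f}")
print(f"  V of balanced B_n = {float(type_variance(n, ())):.4f}")
print(f"  min V             = {float(res.min_value):.4f}  ({res.min_value})")
print(f"  attained at types : {[t.ls for t in res.argmin_types]}")
print()

scan = scan_min_variance(256, 511)
frac = scan.balanced_fraction()
print(f"block [256, 512): balanced class optimal for {len(scan.balanced_ns())} of 256 "
      f"leaf counts ({100 * frac:.1f}%)")
print("the minimum-V tree is maximally balanced only in a small window around 2^m.")
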