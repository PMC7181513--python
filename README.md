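# depthvar

**The variance of leaf depths as a phylogenetic tree shape index.**

The balance of a rooted phylogenetic tree — how evenly internal nodes split
their descendant taxa — is usually quantified with indices such as the Sackin
index *S(T)* (the sum of the depths of the leaves).  A natural alternative is
the *variance* of the leaves' depths,

    V(T) = (1/n) Σ_x (δ_T(x) − Ŝ(T))²  =  S⁽²⁾(T)/n − S(T)²/n²,

where δ_T(x) is the depth of leaf *x*, Ŝ(T) = S(T)/n the mean depth and
S⁽²⁾(T) the sum of squared depths.  `depthvar` implements this index and the
machinery needed to use it rigorously:

- **Exact indices** on rooted trees (bifurcating or not): S, Ŝ, S⁽²⁾, V and
  the total cophenetic index Φ(T) (sum over leaf pairs of the depth of their
  lowest common ancestor), all in exact integer/rational arithmetic.
- **Extremal trees.** The maximum of V is attained exactly at the comb
  (caterpillar), with closed form V(K_n) = (n−1)(n−2)(n²+3n−6)/(12n²).  The
  minimum over bifurcating trees is attained at the maximally balanced tree
  B_n for every n ≤ 183 — but from n = 184 on this almost always fails.  The
  package implements the O(n log n) search over the candidate depth-equivalence
  classes T_{n; l₁<…<l_j} that finds the true minimizers for any n, plus range
  scans with run-length summaries of the optimal types.
- **Null models.** Exact per-tree probabilities and seeded samplers for the
  Yule (Equal-Rate Markov) and uniform (PDA) models, and closed-form moments:
  E_Y(V_n) = 2(n+1)/n·H_n + 1/n − 5, E_U(V_n) = (2n−1)(n−1)/(3n) − (n−1)/(2n)·r_n
  with r_n = (2n−2)!!/(2n−3)!!, and the uniform-model variances of S and Φ and
  their covariance (limiting Pearson correlation ≈ 0.965).
- **Verification oracles.** Exhaustive Wedderburn–Etherington enumeration of
  tree shapes with labeled counts, an exact enumeration-based expectation
  oracle, and a solver for the splitting-weight recurrences behind the
  uniform-model closed forms, each cross-checked against independent routes in
  the test suite.

Intended users: researchers in phylogenetics and tree combinatorics who want
exact balance-index values, calibrated null-model expectations, or the
extremal trees of V for any number of leaves.

## Worked example

```python
>>> from depthvar import min_variance, max_variance, type_variance
>>> res = min_variance(184)
>>> float(res.min_value), [t.ls for t in res.argmin_types]
(0.2379194234404537, [(6,)])
>>> float(type_variance(184, ()))   # the maximally balanced class
0.2381852551984877
>>> float(max_variance(184))        # the comb
2820.2608400283552
```

For n = 184 the minimum-variance tree is *not* maximally balanced: the class
T_{184;6} — 174 leaves at depth 8, 9 at depth 7 and a single leaf at depth 2 —
achieves V ≈ 0.2379, below V(B_184) ≈ 0.2382.  184 is the first leaf count
where this happens, and as n grows the balanced tree is optimal only in small
windows around powers of 2.

Null-model moments, exactly and by brute force:

```python
>>> from depthvar import uniform_moments, expected_by_enumeration
>>> float(uniform_moments(8).EV)
2.2864219114219115
>>> float(expected_by_enumeration(8, "V", "uniform"))   # all 23 shapes
2.2864219114219115
```

The `examples/` directory contains four short narrative scripts (indices from
Newick input, extremal search, moment tables, sampler calibration); each
prints the numbers it computes together with a line on what they mean.  A thin
command line is also included:

```sh
depthvar minvar -n 184
depthvar scan 4 200 -o scan.tsv
depthvar expected --range 3 8
depthvar sample -n 8 --model yule --count 100 --seed 1 -o trees.nwk
```

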