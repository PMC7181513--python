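# Methods

## The index and its domain

`depthvar` works on rooted trees without out-degree-1 nodes, compared as
unordered trees (two trees are the same iff isomorphic).  A phylogenetic tree
is such a tree with leaves bijectively labeled; every index here is a *shape*
index, i.e. it is defined on the label-forgetting projection.  The central
statistic is the population variance of the multiset Δ(T) of leaf depths,

    V(T) = S⁽²⁾(T)/n − S(T)²/n²,

with S the Sackin index (sum of depths) and S⁽²⁾ the sum of squared depths.
Since n²·V = n·S⁽²⁾ − S² is an integer, V is represented exactly as a
`fractions.Fraction`; the package never compares index values in floating
point.  The total cophenetic index Φ (sum over unordered leaf pairs of the
depth of the pair's lowest common ancestor) is computed in O(n) via the
identity Φ = Σ C(κ(v), 2) over non-root internal nodes v, where κ(v) is the
number of leaves below v; a quadratic pairwise computation is kept as an
independent cross-check and the two must agree on every input tested.

Degenerate inputs: a single-leaf tree has S = S⁽²⁾ = V = Φ = 0 (empty pair
sum); the rooted star has V = 0 (all depths 1).  Multifurcating trees are
accepted by all indices; only the model probabilities and the candidate-type
classification require bifurcating input and raise otherwise.

## Tree containers and Newick conventions

Shapes are canonicalized bottom-up: children are stored sorted by a recursive
canonical key, so isomorphism checks are O(n log n) at construction and O(1)
afterwards.  Newick parsing is delegated to `dendropy` and then projected into
the package's containers; branch lengths and internal labels are discarded
(the indices ignore them), unlabeled leaves receive fresh synthetic labels,
duplicate leaf labels are an error (labeling must be a bijection), and
out-degree-1 nodes are rejected by default because the tree model excludes
them — the `collapse_unary` option contracts them instead.  The Newick writer
emits labels only and orders children canonically, so its output doubles as a
canonical key for labeled trees; `parse ∘ write` is the identity up to
isomorphism.

## Depth multisets and realizability

Δ(T) is the sufficient statistic for S, Ŝ, S⁽²⁾ and V, so the package
manipulates depth multisets directly wherever possible.  A multiset of depths
is realizable by a bifurcating tree iff it satisfies the Kraft equality
Σ_x 2^(−δ(x)) = 1; this criterion is validated against exhaustive enumeration
for small n in the tests.  `tree_from_depths` materializes a representative by
repeatedly merging two deepest pending nodes into a parent one level up
(Huffman-style).  When more than two nodes share the maximum depth the pairing
is arbitrary: the depth multiset of the result is invariant under that choice,
but the returned *tree* is only one representative of the depth-equivalence
class — classes such as T_{n;l₁..l_j} generally contain many trees, and the
package makes no attempt to pick a distinguished one.

## Extremal values

The maximum of V over all n-leaf trees is attained exactly at the comb, giving
the closed form (n−1)(n−2)(n²+3n−6)/(12n²); the function evaluates the formula
and the test suite checks both the value (against direct summation) and the
maximality/uniqueness claim exhaustively for n ≤ 12 and statistically on
random multifurcating trees.

Minimizers over bifurcating trees always lie in candidate classes
(n; l₁<…<l_j): trees with a single leaf at depth δ−l_i for each i and all
remaining leaves at depths δ or δ−1.  Writing n = 2^m + k, the feasibility and
depth profile of a class follow a four-case rule on A = k + Σ(2^{l_i}−1) and
B = k + Σ(2^{l_i−1}−1):

- A = 0: the fully symmetric tree, depth m, no sub-maximal leaves;
- 0 < A ≤ 2^m: p₁ = 2^m − A leaves at depth δ−1 with δ = m+1;
- B > 2^m: p₁ = 3·2^m − A with δ = m+2;
- otherwise no tree of the class exists.

All feasibility decisions are routed through this single authority
(`type_profile`).  The variance of a feasible class is
(n(p₁+Σl_i²) − (p₁+Σl_i)²)/n², which for the empty sequence reduces to
2k(2^m−k)/n², the value of the maximally balanced class.

The minimum search enumerates every l-sequence with 5 ≤ l₁ < … < l_j ≤ m as a
subset of {5,…,m} (the classification of arbitrary trees uses the looser bound
l₁ ≥ 2; the tighter one is a property of minimizers only).  Candidates are
ranked by the integer numerator n(p₁+Σl²) − (p₁+Σl)², so comparisons are exact,
ties are detected exactly, and *all* co-minimizing classes are reported — the
uniqueness of the minimizer is an open conjecture, not an assumption of the
code.  Per-subset sums are cached per m, so scanning a whole dyadic block
[2^m, 2^(m+1)) costs O(2^(m−4)) integer operations per n.  The search is
verified against the brute-force minimum over every enumerated shape for all
n ≤ 20 (up to 293,547 shapes).

Range scans expose three summaries: the set of n whose minimum sits at the
balanced class, their fraction (which decays as the range grows), and the
run-length encoding of the optimal l-sequences taken in descending n within
each dyadic block, where the first run below 2^(m+1) always has length 29 (the
window [2^m − 29, 2^m] belongs to the balanced class; at 2^m − 30 type (6)
takes over).

## Null models

The Yule (Equal-Rate Markov) model grows a tree by replacing a uniformly
random leaf with a cherry and labels the leaves by a uniform bijection at the
end; a labeled bifurcating tree has probability
2^(n−1)/n! · Π_v 1/(κ(v)−1) over internal nodes v.  The uniform (PDA) model
makes all (2n−3)!! labeled trees equiprobable (convention (−1)!! = 1!! = 1)
and is realized sequentially by inserting leaf k+1 at one of 2k−1 equiprobable
positions: each of the 2k−2 arcs, plus a virtual arc above the root.

Samplers grow trees in flat arrays and are seeded per call with an isolated
RNG stream keyed by (model, n, seed), so a fixed tuple reproduces the same
draw sequence on any machine running the same Python generator.  The labeled
sampler exists because the model probabilities are per labeled tree; a
shape-level fast path (`sample_statistics`) skips labeling when only shape
statistics are needed, which leaves their distribution unchanged.  Sampler
correctness is tested three ways: chi-square uniformity of the 15 labeled
4-leaf trees under the uniform model (α = 0.01, fixed seed), binomial
frequency of the two 4-leaf shapes under Yule, and agreement of Monte-Carlo
means of V, S, Φ with exact expectations to within four standard errors at
10⁵ draws — chosen so the checks are sharp but run in seconds.

The enumeration oracle computes exact model expectations by summing
statistic × labeled count × per-tree probability over every shape; labeled
counts are n!/|Aut(shape)|, with the automorphism order computed recursively
(for bifurcating shapes it is 2^q with q the number of internal nodes whose
child subtrees are isomorphic).  The oracle refuses n > 12: the shape count
grows like the Wedderburn–Etherington numbers and 12 (451 shapes) keeps every
oracle-backed test instantaneous while covering all moment identities.

## Closed-form moments and the recurrence solver

All moments are exact rationals built from the harmonic numbers H_n, H_n^(2),
the odd double factorial (2n−3)!! and the ratio r_n = (2n−2)!!/(2n−3)!! ~
√(πn).  Under Yule, E(V_n) = 2(n+1)/n·H_n + 1/n − 5; under the uniform model,
E(V_n) = (2n−1)(n−1)/(3n) − (n−1)/(2n)·r_n; the module also carries
E(S), E(S⁽²⁾), E(S²) under both models, the uniform-model variances of S and
Φ, their covariance, and the asymptotic constants (10−3π)/3, (56−15π)/240 and
(52−15π)/60 whose combination gives the limiting S–Φ correlation ≈ 0.965.
Internal consistency (E(V) = E(S⁽²⁾)/n − E(S²)/n²) is asserted in the
constructors, and every closed form is compared exactly with the enumeration
oracle for n ≤ 8 in the tests.

Uniform-model expectations satisfy recurrences
X_n = 2Σ_k C_{k,n−k} X_k + forcing(n) with splitting weights
C_{k,n−k} = ½·C(n,k)·(2k−3)!!(2(n−k)−3)!!/(2n−3)!! and a forcing term that is
a polynomial plus a polynomial multiple of r_n, both expressed in the binomial
basis with no constant term (a Stirling-number conversion from the power basis
is provided).  `solve_recurrence` maps the forcing coefficients to the closed
form; `iterate_recurrence` iterates the recurrence directly (quadratic cost)
as the independent check, and the two agree termwise on the shipped specs and
on randomized ones.  One convention: an empty coefficient list is padded with
a single zero, which reproduces all verified instances; the solver's formulas
are stated for r, s ≥ 1 and the padding extends them to degenerate specs.

For very large n the exact path would carry huge integers, so the asymptotic
checks use a log-gamma evaluation of r_n and an asymptotic expansion of H_n;
these float paths agree with the exact ones to 12 digits where both run, and
exactness is guaranteed only on the rational path.

## Problem sizes used in the shipped checks

The test suite enumerates shapes exhaustively up to n = 12 for invariants and
up to n = 20 for the search-vs-brute-force equivalence; scans cover n ≤ 200
for the boundary at 184 and the block [2¹², 2¹³) for run-length structure;
samplers are calibrated with 10⁵ draws at n ∈ {5, 8}.  These sizes were chosen
as the smallest that exercise every regime of the algorithms (both feasibility
cases, both δ values, the first balanced/unbalanced boundary, a full dyadic
block); the library itself has no such limits — `min_variance` is practical
far beyond 2²⁰ leaves.

## What the generators emulate, and limits

The random-tree fixture (`random_tree`) is a seeded recursive splitting
process, *not* a sampler of any biological null model; it exists to exercise
structural invariants (Kraft tightness, index bounds, round-trips) on varied
shapes, including multifurcating ones.  Statements about the Yule and uniform
models are tested with their own samplers.  None of the generators produce
branch lengths, extinct lineages or label-dependent structure, so passing
tests say nothing about branch-length-aware statistics or about fit to real
phylogenies; they certify the combinatorial and probabilistic machinery on the
tree-shape level at which the index is defined.

## Known limitations

- The minimum-V search reports classes of trees (depth multisets), not all
  trees in a class; materializing *every* tree of a class is intentionally out
  of scope.
- No closed-form predictor of the optimal l-sequence is known; the search is
  the method.
- Yule-model second moments of Φ (and the Yule S–Φ covariance) are not
  implemented; only the uniform-model versions have closed forms here.
- Other balance indices (Colless, cherries, rooted quartet index) are out of
  scope.
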