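# Methods

## Model

The M statistic operationalises the standard definition of phylogenetic
signal — related species resemble each other more than species drawn at
random from the tree — as a monotonicity constraint between two pairwise
distances: if species *i* and *j* are phylogenetically closer than *i* and
*k*, their trait distance should also be smaller. Rather than enumerating
all species triples (quadratic-times-permutations cost), the tree is
decomposed into subtrees: every internal node with ≥ 3 descendant tips
contributes one comparison between its two child branches. With d̄₁, d̄₂ the
mean within-branch trait distances (defined as 0 for a single-tip branch)
and d̄ₓ the mean cross-branch distance, the subtree scores
m = ½[d̄₁ ≤ d̄ₓ] + ½[d̄₂ ≤ d̄ₓ], and M is the mean of m over subtrees.
Ties count in favour of the constraint (the comparison is non-strict);
two-tip cherries carry no contrast and are excluded. M depends only on the
topology: rescaling or perturbing branch lengths never changes it.

Assumptions: the tree is rooted and strictly bifurcating (polytomies are
rejected with an error — resolving them is the user's modelling decision,
not ours), has ≥ 3 tips, and every tip has a row in the trait table.
The branch order within a subtree ("first"/"second") follows Newick child
order; it is arbitrary and irrelevant because the score weighs branches
equally.

## Trait distances

Gower's coefficient with the Podani conventions: continuous traits
contribute |xᵢ − xⱼ| / range, nominal traits a 0/1 mismatch, and ordinal
traits are converted to midranks (ties averaged) and then range-normalised
like continuous ones. A configuration switch (`ordinal_as_continuous`)
treats integer-coded ordinal traits directly as continuous instead. Per
pair, the distance is the weighted mean over traits observed in both
species (pairwise deletion with weight renormalisation); a pair sharing no
observed trait raises an error rather than propagating an NA into the
permutation machinery. A continuous column with zero range contributes
distance 0 with a warning (the convention of the widely used R
implementations). Trait combinations are the equal-weight Gower distance
over the group; per-trait weights are exposed but default to 1, and the
documentation warns that weights change M.

This implementation was verified against hand-computed values (to 1e-12)
and against R's `cluster::daisy` on a mixed-type fixture.

## Permutation test

Null hypothesis: trait values are exchangeable across tips. Each of the
`n_perm` replicates reassigns whole trait rows to tips uniformly at random
(Fisher–Yates via numpy's Generator), preserving trait–trait correlations
in the multi-trait case, and recomputes M against the fixed topology. The
p-value is the add-one right-tail rank, p = (1 + #{M_null ≥ M_obs}) /
(n_perm + 1); `significant` means p ≤ α. Defaults: n_perm = 999, α = 0.05.
A constant trait (all pairwise distances equal) yields M = 1, p = 1 with a
warning rather than an error. Advisory warnings (not errors) are emitted
below 25 tips for continuous and 50 tips for discrete traits, where the
test has little power.

### Known property: mild conservatism

M takes values on the grid {k/(2n) : k = 0..2n}, so exact ties between the
observed M and null replicates are common (≈ 8 % of null mass at 50 tips in
our measurements). Ties count toward the right tail, so the realised
type-I error sits slightly below the nominal level: measured at 2000
null simulations (50-tip trees, 199 permutations), the rejection rate at
α = 0.05 was 0.039 (continuous) and 0.045 (discrete). The test is therefore
valid (never anti-conservative) but not exactly sized; the effect shrinks
as trees grow and the grid refines. This is the same discreteness mechanism
that limits power for few-state traits.

## Fast evaluation

The permutation loop is the hot path: each replicate needs all subtree
means. We assign every unordered tip pair to its most recent common
ancestor once per tree; the pairs owned by node v are exactly the cross
pairs of v's subtree, so one `bincount` over the C(n,2) permuted distances
yields every cross-branch sum, and a single postorder accumulation
(T(v) = T(left) + T(right) + S_cross(v)) yields every within-branch sum.
Each evaluation of M is then O(n²) numpy work with no per-subtree Python
loops. The naive per-subtree enumeration is retained as
`m_statistic_naive` and the two routes are asserted exactly equal on
random trees in the test suite. Comparisons use exact floating-point
`≤`; both routes compute branch means as (sum / count), and genuine ties
(identical distances) compare equal in either route.

## Simulation framework

The generators mirror the validation study's conditions and their defaults
are those conditions:

- **Trees**: pure-birth (Yule) with birth rate 0.05 per lineage per unit
  time and no extinction. Starting from the root's two daughters, the
  waiting time while k lineages exist is Exponential(0.05·k) and the
  splitting lineage is uniform; after reaching the target tip count one
  more waiting time is drawn and all tips are cut at that epoch, making
  the tree exactly ultrametric. The mean root-to-tip depth is
  Σ_{k=2..n} 1/(0.05k), which the tests check against simulation.
- **Continuous traits**: Brownian motion from root value 0 with increment
  standard deviation 0.01·√t over a branch of length t (σ is per unit
  square-root branch length, the convention of the common R simulators).
  Signal intensity w ∈ [0, 1] mixes the Brownian trait with a uniform
  random permutation of its own values:
  trait = w·trait_BM + (1 − w)·trait_rand. The shuffle is drawn fresh per
  replicate.
- **Discrete traits**: equal-rates Mk with off-diagonal rate 0.01 between
  every ordered pair of the k states, root state uniform. Transitions over
  a branch use the closed form: keep the parent state with probability
  e^(−kqt), otherwise draw uniformly from all k states (this reproduces
  the matrix exponential of the equal-rates generator exactly). Signal is
  degraded by keeping a uniformly chosen round(w·n) species fixed and
  applying a plain uniform permutation (fixed points allowed) to the rest.

What the generators do **not** emulate: extinction, diversified or biased
sampling, measurement error, rate heterogeneity across lineages or traits,
correlated trait evolution, and missing data. Passing power tests on these
simulations therefore demonstrates behaviour under the idealised
Yule + BM/Mk regime, not performance on real datasets with those
complications.

## Power experiments

Detection rate = fraction of replicates with p ≤ α (α = 0.05). Curves scan
w for one trait; surfaces scan (w₁, w₂) for two independently simulated
traits on the same tree, tested jointly through their equal-weight Gower
combination. A fresh tree is drawn for every replicate in every cell.
Per-cell random streams derive from `SeedSequence(master, cell
coordinates)` and replicates spawn from the cell stream, so any cell is
reproducible in isolation and results do not depend on execution order.

Default scale is 20 replicates × 199 permutations per cell — desk-scale
settings chosen so a full curve runs in seconds while leaving Monte-Carlo
noise of at most ~11 percentage points (binomial SE at rate 0.5); the
replicate and permutation counts are plain arguments for larger studies.
The acceptance script uses 20–50 replicates per setting for the same
reason, and its detection rates at w = 0.7/500 tips, w = 0.9/50 tips and
w = 1.0/100 tips land at 100 %, 90–94 % and 100 % across seeds.

## Numerical and design choices

- p-value: add-one rank estimator, right tail only; the observed
  arrangement is never counted among the permutations.
- Permutation unit: whole species rows, so multi-trait nulls preserve
  inter-trait correlation.
- Subset rounding in the discrete degrade step: round-half-even via
  Python's `round` on w·n.
- Zero-length and missing branch lengths parse fine and are irrelevant to
  M; simulators require lengths and error without them.
- Unrooted trees (basal trifurcation) are treated as polytomies and
  rejected.
- Pruning: `permutation_test(..., prune=True)` drops table species absent
  from the tree with a warning; tree tips missing from the table are
  always an error (dropping tips silently would change the topology under
  test).

## Limitations

- Restricted to strictly bifurcating trees; no polytomy resolution is
  provided.
- No comparison indices (C_mean, Moran's I, K, λ, D, δ) are implemented;
  power results here characterise M alone.
- Gower extensions for fuzzy-coded or multi-column characteristics are out
  of scope.
- The permutation test's realised size is slightly below nominal on small
  trees (see above); reported p-values are conservative, never liberal.
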