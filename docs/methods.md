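# Methods

## Automata and look-up tables

A rule of arity `k` is stored as its full look-up table (LUT): `2^k`
output bits indexed lexicographically over input tuples with the first
listed input most significant. This dialect is fixed once and used by
every serialization format; expressions in `.bnet` files are compiled to
LUTs over their variables in order of first appearance. Network input
nodes (external factors) are modelled as `k = 1` self-loop copies, the
standard convention for logical models. Arity-0 rules are allowed as
values but not as network nodes. Updating is synchronous only.

## Effective connectivity

For each LUT row, the *enput count* is the minimal number of inputs
whose fixation to the row's states forces the output; effective
connectivity `k_e` is the mean enput count over rows. Equivalently, a
row's enput count is `k` minus the wildcard count of the most
compressed schema (prime implicant of the row's output class) covering
it. Two implementations coexist deliberately:

- `prime_schemata` performs Quine-McCluskey merging on the ON-set and
  OFF-set separately and returns the maximal wildcard schemata
  themselves (used for inspection, serialization and `.bnet` writing).
  Tie-breaking among equally wild covering schemata is irrelevant for
  `k_e` — only the wildcard count enters.
- `effective_connectivity_batch` computes, per row, the largest
  dimension of a constant subcube through that row by a dynamic
  programme over input subsets, with LUTs bit-packed into uint64 words
  (subcube flips become delta-swaps, coverage counts use popcounts).
  A subcube over `W + {j}` is constant iff both `W`-halves are constant
  and agree, so each subset costs a few word operations. This is the
  production path (a 10^4-rule catalogue at `k = 8` takes ~0.1 s) and is
  verified exact against a brute-force minimal-subset oracle in the test
  suite (all rules with `k <= 3`; 10^3 random `k = 4` rules).

Constant rules have `k_e = 0`; parity rules (and only they, for
`k >= 2`) attain `k_e = k`. `k_e` is invariant under input permutation,
input negation and output complementation (property-tested). Average
sensitivity `s = sum_j Pr[f(x) != f(x ^ e_j)]` is provided for
comparison; it aggregates inputs independently and cannot see collective
canalization (e.g. `s(AND2) = s(copy) = 1` while `k_e` separates them).
Two-symbol (input-permutation) schemata and c-sensitivity are out of
scope.

## Rule catalogues

Ensembles draw rules from catalogues indexed by `(k, p, k_e bin)`.
Bins have half-width `eps = 0.25` and centres on multiples of 0.5 over
`[1, k]`. A rule is *eligible* for a bin when `|k_e - centre| <= eps`
(closed interval): since `k_e` is always a multiple of `1/2^k`, values
land exactly on bin edges frequently, and an edge rule serves both
adjacent bins. Each entry also records a primary bin (nearest centre,
ties upward) for reporting. Catalogues are exhaustive for `k <= 4` (or
whenever `C(2^k, p*2^k)` is below the cap) and otherwise hold 10^4
distinct uniformly sampled rules.

Bins essentially inaccessible to uniform sampling (the `k_e` of random
`k = 8` tables concentrates near 6) are filled by a genetic algorithm
over output vectors at fixed ON count: tournament selection (size 3),
bias-preserving swap mutation (exchange one ON and one OFF row), no
crossover (it would break the ON-count constraint), population 100, up
to 2000 generations with a 250-generation stagnation stop. Half of
generation 0 consists of *canalizing seeds* — tables generated from a
random subfunction of ~`round(target)` inputs and repaired to the exact
ON count — because the fitness landscape toward low `k_e` is a needle
that uniform starts never reach. Bins the search cannot fill are
reported as unreachable, never fabricated; some are provably empty
(at `p = 0.5` any rule with a 1-enput row must be the copy rule, so
`k_e in (1, 2)` is impossible at that bias for every `k`).

## Ensemble design

The generator emulates homogeneous random BN ensembles: every node has
exactly `k` distinct random inputs (self-input permitted) and a rule
drawn uniformly from the requested catalogue bin, so `k` and `p` are
exact and per-node `k_e` stays within the bin. Default study
conditions: `N = 100` nodes, `k in {2, 3, 4, 6, 8}`, biases on the
attainable grid `i/2^k` clipped to `[0.01, 0.5]` (tautologies and
contradictions never occur), bin centres `1.0, 1.5, ..., k`,
10 replicates per viable cell. The *reduced* conditions used by the
test suite and the acceptance script are `N = 50`, bias steps coarsened
to at least 1/16, and 100 Derrida pairs — chosen as the smallest sweep
that still exercises every arity and the full bin range. Non-viable
cells (no admissible rule) are recorded and skipped.

Randomness is hierarchical: a master seed spawns independent
`SeedSequence` streams per stage, cell and replicate, so any single
network can be regenerated without rerunning the sweep and reruns are
byte-identical.

What the generator does *not* emulate: heterogeneous in-degree
distributions, asynchronous updating, and correlations between a node's
rule and its wiring — all properties of real regulatory networks.
Passing tests therefore certify the method on the homogeneous ensemble
design, not on arbitrary biological models (the `empirical` module
applies the same measurements to user-supplied heterogeneous models,
using node means of `k`, `p`, `k_e`).

## Derrida parameter

For `I` pairs (default 250; 100 at reduced scale) a uniform random
configuration and a copy with `m` distinct nodes flipped — `m` uniform
on `[1, floor(N/10)]` (floor chosen for non-divisible `N`) — are
advanced `t = 1` synchronous step; Hamming distances are averaged per
`m` and `zeta` is the least-squares slope through the origin of the
`(m, mean divergence)` points. All nodes, including self-loop input
nodes, are equally likely to be perturbed. `zeta > 1` (strictly) labels
chaos; ties at 1 are stable/critical. An optional stratified mode
allocates pairs evenly over `m` for variance control but is off by
default. At `t = 1` the map is near-linear in `m`; the finite-`m`
saturation biases `zeta` slightly below the network's mean sensitivity
(a few percent at criticality), identically across the ensemble, so the
regime boundary is unaffected in practice. Longer horizons (`t > 1`)
are supported by the engine but not used for labels.

## Criticality models and scoring

Each network contributes a record `(k, p, <k_e>, zeta, R)` with
`R = 1{zeta > 1}`; `<k_e>` is the realized node mean (slightly more
informative than the bin centre, which is also supported). Six logistic
model classes of increasing complexity are fitted by maximum likelihood
(statsmodels `Logit`, lbfgs, no regularization — the coefficients are
interpreted as theory constants), with the connectivity term `kappa`
either `k` or `<k_e>` and bias entering only through the dual-symmetric
compound `p(1-p)`. An intercept is always included; the printed
boundary form follows from the 0.5-probability locus:
`beta0 + sum_i beta_i t_i = 0  <=>  sum_i (-beta_i/beta0) t_i = 1`.
Perfect separation does not abort a fit; optimizer warnings are folded
into a `converged` flag. Ties at the 0.5 threshold predict chaotic,
mirroring the strict `zeta > 1` labelling on the other side.

Scores: MCC from the explicit confusion-count formula (0 when any
denominator factor vanishes), AUC as the rank statistic, McFadden
`R2 = 1 - LL(model)/LL(intercept-only)` with the intercept-only
reference fitted on the same training split. Generalization is
estimated by nested fourfold cross-validation — 4 outer folds, each
outer training split itself split 4 ways, models fitted on the inner
training parts and scored on the inner held-out parts, 16 train/test
pairs in total — and model instances are compared by one-sided paired
t-tests over the 16 fold scores (zero-variance differences are flagged
degenerate). Pareto selection returns the lowest-complexity class
within `delta = 0.01` of the best mean score.

On the reduced sweep the regime labels themselves are noisy near the
critical surface (within-cell `zeta` spread ~0.07 at `N = 50`,
`I = 100`; the cell-majority classifier tops out near MCC 0.90), so
cross-validated scores of the canalization boundary sit several points
below the values attained at full scale; the fitted boundary constants
are insensitive to this noise. The marginal critical value of `<k_e>`
from the bias-free class-1 model depends on the bias-grid composition
(low-bias cells, mostly removed by the reduced grid's coarsening, push
it upward); the class-2 constants do not share this sensitivity.

## Empirical statistics

For user model collections: tautologies/contradictions are removed
first, then single-input rules (`k_e = k = 1` trivially); the retained
set is summarized by mean, median, hinge quartiles (median of halves,
excluding the median at odd sizes; the IQR is reported as the (Q3, Q1)
pair), Pearson moment skewness and excess kurtosis (undefined, hence
NaN, for degenerate samples). Per-network features are node means, the
regime comes from the same Derrida procedure (heterogeneity and all),
and class-2 boundaries are refitted in both the structural and
effective spaces when both regimes are present — otherwise skipped with
a notice. No external model corpus is bundled; the examples generate
small synthetic stand-ins.

## Known limitations

- The genetic bin-filler is heuristic: an unreachable bin is only
  provably empty where exhaustive enumeration or a structural argument
  applies.
- `prime_schemata` is practical to `k ~ 10`; beyond that only the
  packed `k_e` path scales.
- The Derrida slope at `t = 1` with `m <= N/10` mildly underestimates
  the origin slope for strongly chaotic networks (saturation); regime
  labels near `zeta = 1` are unaffected in expectation but noisy at
  small `N` and `I`.
- Heterogeneous-degree ensemble theory, attractor/basin analysis and
  symbolic-regression boundary search are out of scope.
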