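# Methods

## Model

A design instance is a set of k target secondary structures over a common
length n — each a set of base pairs (i, j), crossing pairs allowed — plus a
collection of features F₀..F_m with positive weights π₀..π_m. Sequences over
{A, C, G, U} are drawn from

P(S | π) = (1/Z_π) ∏_ℓ π_ℓ^(−F_ℓ(S)),  Z_π = Σ_S ∏_ℓ π_ℓ^(−F_ℓ(S)).

Every feature decomposes into *contributions*: local terms over small
position sets (the contribution's dependencies) with values in ℝ ∪ {+∞}.
+∞ is a hard constraint — its Boltzmann factor is exactly 0 for every
positive weight, so invalid sequences never carry probability mass. The
shipped features are:

* **GC** — one unary contribution per position, −1 on G/C and 0 otherwise;
  F_GC(S) = −(#G + #C), always in [−n, 0]. A user-facing GC *fraction*
  g ∈ [0,1] maps to the feature target −g·n.
* **Validity** — one binary contribution per distinct base pair of any
  target: 0 if the pair is canonical ({AU, GC, GU}, either orientation),
  +∞ otherwise. Emitted for *all* pairs regardless of the energy model, so
  validity never depends on the model choice.
* **Base-pair energy** — per structure, ΔG(S_i, S_j) summed over its pairs
  (kcal/mol table; non-canonical pairs +∞).
* **Stacking energy** — per structure, ΔG(S_i, S_{i+1}, S_{j−1}, S_j)
  summed over its stacks (both (i,j) and (i+1,j−1) pairs of the structure);
  +∞ if either pair is non-canonical; a structure without stacks has energy
  0. The stacking model is the tractable stand-in for the full
  nearest-neighbor model: it keeps contribution arity at 4, hence the
  treewidth low, while correlating tightly with richer models.

Weights are folded into the contributions by f → ln(π)·f (with +∞
preserved), so the whole weighted network is evaluated as exp(−Σ f′(S)).

Parameter tables are JSON configs keyed by flattened nucleotide tuples in
dependency order ("GC": −3.0; "GCGC": −2.1). No symmetry folding is applied;
symmetric parameterizations must be written out. Missing canonical tuples
default to 0, non-canonical tuples to +∞. The shipped tables
(`src/rnadesign/data/`) are *illustrative defaults* with the structure of
fitted tables — base-pair strengths ordered GC < AU < GU, stacking bonuses
per GC pair — not fitted values; tests use explicitly constructed toy
tables only.

## Tree decomposition

The dependency hypergraph has one vertex per position and one hyperedge per
distinct contribution dependency set; positions touched by no contribution
get singleton hyperedges so the sampler still assigns them (uniformly).
Decompositions are computed by min-fill elimination on the primal graph
(each hyperedge a clique): repeatedly eliminate the vertex needing the
fewest fill-in edges, ties broken by smallest position index, which makes
the decomposition — and everything downstream — reproducible. Bags are the
elimination cliques; bags contained in an adjacent bag are merged away.
`validate_decomposition` checks the three defining conditions (vertex
coverage, running intersection, hyperedge coverage) and is run on every
decomposition the package builds. Exact treewidth for cross-checks at ≤ 16
vertices is computed by memoized elimination over vertex subsets (the graph
after eliminating a set is order-independent), equivalent to minimizing
over all elimination orders.

For the DP the decomposition is converted to a *cluster tree*: a dedicated
empty root adjacent to one node per connected component, edges oriented to
the root, and chains of intermediate bags inserted (new positions in
ascending order) so each parent→child step introduces exactly one position.
The expansion only adds subsets of existing bags, so the width never grows.
Each contribution is assigned to the first bag containing its dependencies
in breadth-first order from the root — any consistent assignment is
correct; the fixed order is for determinism.

## Message passing and sampling

For each node u, the joint table A_u over assignments of its bag is the
product of the factors exp(−f) of contributions assigned to u with all
incoming child messages; the message to the parent marginalizes A_u over
the positions absent from the separator. The partition function is the
product of the 0-ary messages reaching the root. Tables hold Boltzmann
factors (not logs) in double precision; each A_u is rescaled by its maximum
with the log of the scale accumulated, so Z is reported as
(mantissa, log-scale) and never over- or underflows — exercised up to
n = 200 at weight 10⁶ against the closed form.

Sampling retraverses the tree root-to-leaves: at each node the single
introduced position is drawn from A_u sliced at the already-fixed separator
assignment, by inverse CDF in fixed A, C, G, U order — this pins the sample
stream to the seed (a single numpy PCG64 generator; no global state). All
requested samples are drawn in one vectorized pass per node. Zero-weight
branches are skipped exactly (their factor is exactly 0), never by
thresholding; a rounding guard reassigns the (measure-zero) draws that land
on a zero-probability cell. A dense-table note: assignments forbidden by
base-pairing carry factor 0 inside the vectorized products, so no separate
compatible-assignment enumeration or pruning pass exists — the arithmetic
already does the pruning.

## Calibration

Initial weights are e^β for all targeted features, β = 1/(RT) with
R = 1.98717·10⁻³ kcal/(mol·K), T = 310.15 K, so e^(−βE) is dimensionless
for kcal/mol energies. Each iteration draws `samples_per_iter` sequences
(default 100; the loop recomputes messages since weights enter the
contributions), estimates per-feature means over *that iteration's sample
only*, and updates π_ℓ ← π_ℓ·γ^(μ̂_ℓ−E*_ℓ), γ = 1.2. Iteration stops when
every |μ̂_ℓ − E*_ℓ| is within its tolerance (defaults: 0.5 kcal/mol for
energies, 0.01·n counts for GC; `max_iters` 100); on non-convergence the
best-seen weights are returned with a flag.

**Stability.** The expected feature value responds to the log-weight with
local slope −Var(F_ℓ), so the plain update multiplies deviations by
(1 − ln γ·Var(F_ℓ)) near the fixed point: for ln(1.2)·Var > 2 the iteration
is locally unstable and enters a limit cycle around the target instead of
converging. GC counts of ~50 nt instances already have Var ≈ 20. The loop
therefore bounds the update exponent per feature and adapts the bound by
sign-based step control: halved when the deviation changes sign (down to
`min_step`), regrown by γ while the sign persists (up to `max_step`,
default 5). This preserves the fixed point, reduces to the raw update in
the stable regime, and converges in ~30–45 iterations on the two-structure
test instance. `update_weights` itself implements the raw rule (with an
optional clamp) for callers who want it.

The final rejection step keeps samples whose every targeted value lies in
[E*(1−ε), E*(1+ε)] (endpoints sorted, so negative targets behave
symmetrically); the GC feature uses the absolute window ±ε·n, because a
relative window around a near-zero target is meaningless. The filter is
idempotent.

Energies of a richer model enter through a pluggable path: given paired
observations (E_simple, E_full) for sequences sampled at homogeneous
weights, `affine_fit` estimates E_full ≈ slope·E_simple + intercept by least
squares and `adjust_target` maps a full-model target to
(E* − intercept)/slope in the simple model. The full-model evaluator itself
(e.g. an external folding engine) is outside the package; tests drive the
fit with synthetic linear data. `multidefect` scores a design from supplied
energies: mean distance of the per-structure energies from the ensemble
free energy plus mean pairwise dispersion — nonnegative whenever the
ensemble energy lower-bounds the per-structure energies, zero iff all
coincide.

## Synthetic instances and what the tests show

`oracle.random_instance` draws k structures of length n by repeatedly
sampling disjoint pairs with j − i ≥ 3 (configurable to 1 for adversarial
dependency graphs) until a pair density of 0.3 of positions is reached;
20% of draws ignore the nesting constraint, producing pseudoknots at a
realistic rate. It emulates the combinatorics of multi-target instances —
overlapping pairings, crossing pairs, disconnected components — but not the
length distribution of real loops, sequence motifs, or fitted energy
surfaces; a sampler correct on these instances is correct as an algorithm,
while biological quality of designs additionally depends on the energy
tables supplied.

The brute-force oracles are independent of the engine by construction:
partition functions and distributions by full 4ⁿ enumeration (n ≤ 10),
valid-sequence counts by per-component constraint backtracking,
independent-set counts by branch recursion. Problem sizes in the test
suite: 200 random instances at n ≤ 8, k ≤ 3 with weights in [0.1, 10] for
exactness (agreement to 10⁻⁹ relative); 10⁵ samples against exact
distributions on five instances with supports 6–216 chosen so sampling
noise alone stays well under the 0.02 total-variation bound (predicted
noise ≤ 0.015) with all χ² expected counts ≥ 5; the calibration check uses
two hand-built length-50 structures (a 21-bp hairpin vs. two 10-bp
hairpins, 20 and 18 stacks) with the toy stacking table
ΔG = −1.0 − 0.25·(#GC pairs in the stack) and targets E*₁ = −26,
E*₂ = −23 kcal/mol, GC 0.6 — chosen a priori to be mutually consistent
(sequences at 60% GC realize all three in expectation); linear scaling is
measured on concatenated 10-nt hairpins at n = 50..400, where the width is
constant.

## Known limitations

* Energy models are limited to base-pair and stacking terms; loop-based
  nearest-neighbor contributions (bulges, multiloops, dangles) are not
  generated, only approachable via the affine re-targeting path.
* Min-fill is a heuristic: widths are optimal on forests and cycles (and
  checked ≥ optimal on small random instances) but can exceed the true
  treewidth on dense pseudoknotted instances, with exponential cost in the
  gap.
* The calibration is a stochastic heuristic: targets outside the achievable
  range (or on its boundary) yield a flagged non-convergence, not an error
  diagnosis; feasibility is not checked up front.
* Positive design only: nothing disfavors competing structures; the sampler
  provides seeds (or null models), not finished negative designs.
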