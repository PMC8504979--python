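# Methods

`bnimpute` learns Bayesian network structures from mixed
discrete/continuous data by score-based search, and — its central
contribution — imputes missing data with a *network-guided
nearest-neighbour* procedure designed to maximise the accuracy of the
final learned structure rather than of the filled-in values themselves.

## Model

A Bayesian network is a DAG `M` over the observed variables together
with local distributions: multinomial for discrete nodes, Gaussian
linear regressions for continuous nodes.  A continuous node with
discrete parents is handled conditionally — one regression on its
continuous parents per configuration of its discrete parents.  Two
structural restrictions apply throughout: a discrete node may not have a
continuous parent (the conditional-Gaussian factorisation does not admit
it), and variables flagged *genetic* (SNPs, coded either as factors or
as continuous allele dosages) admit no incoming edges.  Genetic
variables are fixed at conception, so they act as causal anchors that
orient edges among the non-genetic variables and break observational
equivalence.

Under causal Markov/faithfulness/sufficiency assumptions the best-fit
DAG is read as a map of *candidate* causal relationships; DAGs in the
same Markov equivalence class cannot be distinguished by fit, which is
why all structure-recovery metrics here either count exact directed
edges (recall/precision) or compare CPDAGs (correct-or-equivalent).

## Scores

The network score is decomposable: the sum over nodes of the maximised
local log likelihood, penalised as

- `loglik`: log L̂
- `aic`: log L̂ − d
- `bic`: log L̂ − (d/2)·ln n  (default)

with `d` the count of free parameters: `(r−1)·q` for a discrete node
with `r` levels and `q` parent configurations, `q·(c+2)` for a
continuous node with `c` continuous parents (coefficients, intercept,
variance, per configuration).  Variance estimates use the maximum-
likelihood denominator `n`, so the score is exactly a maximised
likelihood.  Scores are negative on non-degenerate continuous data and
larger is better.  A local fit is *degenerate* — and the candidate
structure inadmissible, without aborting the run — when a discrete-
parent configuration has fewer rows than parameters or a regression
residual has zero variance (relative tolerance 1e−12).

**Soft constraints.** A directed edge `e` may carry a prior probability
`p(e)`, the reverse direction automatically carrying `1 − p(e)`.  The
weighted score is `BIC + Σ_e ln p(e)` over prior-carrying edges present
in the network.  A present edge with prior 0 rejects the network
(score −∞); `p = 0.5` expresses no directional preference (it shifts
both orientations by the same constant).  The penalty count in this
package is the free-parameter count everywhere — the "usual" BIC — and
the per-edge prior term is exactly `Σ ln p(e)`; a prior edge *absent*
from the network contributes nothing, which mildly penalises presence of
prior-flagged edges (ln p < 0).  That is accepted as the literal reading
of the weighted score.  Priors are only defined for the BIC; combining
them with other scores is a configuration error.

## Search

Greedy hill climbing over single-arc additions, deletions and reversals,
best-improvement steps, starting from the whitelist-only graph.
Whitelist edges are never removed (a pair whitelisted in both directions
must stay connected but may reverse); blacklisted, cycle-forming,
genetic-in-edge and continuous-into-discrete moves are never applied.
Restart policy: 12 random restarts (random topological order, each
valid order-respecting edge included with probability 0.25) and 4
jitter restarts (4 random valid moves away from the incumbent).  The
counts are sized to the hardest catalogued landscape: collider
structures admit strict local maxima (a spurious triangle replacing the
v-structure, with no improving single-arc move), and on the 5-node
collider benchmark at n = 2000 a 2-restart policy strands the climber
in ≈ 18% of replicates whereas the default policy recovers the
exhaustive optimum in essentially all of them, at a few milliseconds
per fit.  The *inner* searches of the imputation procedure instead
default to a light 2 random + 2 jitter policy: they only steer
neighbour selection, run once per index individual, and their
occasional local maxima perturb distances rather than the reported
structure.  Both policies are overridable.  Ties between equal-gain
moves break on a fixed
(move-type, from, to) ordering and improvements must exceed 1e−9, so
results are deterministic given the seed.  For ≤ 5 nodes an exhaustive
enumerator scores every admissible DAG and serves as the global-optimum
oracle; on the catalogued 4-node scenario the greedy search with default
restarts attains its optimum in ≈ 95% of replicates (and can never
exceed it).

All-continuous data uses a Gram-matrix scoring engine: the residual
cross-product matrix for a parent set is a Schur complement whose
diagonal prices every child at once, and for ≤ 6 variables the full
(child, parent-set) score table is precomputed by sweeping the subset
lattice.  The generic per-node path used for mixed data produces the
same numbers (unit-tested to 1e−7).

## Bootstrap averaging

The data are resampled with replacement `B` times (default 1000) and the
best-fit network refitted per resample.  Per unordered pair, *strength*
= share of resamples containing the edge, *direction* = share of those
appearances in the reference orientation (undefined, reported blank,
when the pair never appears); the probability of a directed edge is
strength × direction.  One master seed spawns one substream per
resample, so raising `B` extends rather than reshuffles the sequence,
and rows are processed in canonical identifier order so the result is
invariant to physical row order.  The default plotting threshold on
strengths minimises the L1 distance between the empirical strength CDF
and an idealised two-point CDF (noise arcs at 0, significant arcs at 1)
over candidate thresholds at observed strengths, smallest threshold on
ties.  Per-edge significance is a likelihood-ratio χ² (network log
likelihood with and without the edge; df = the child's parameter-count
difference), used to scale plot line widths only — no multiplicity
correction is applied.

## Imputation

Missingness is assumed MAR: the probability an entry is missing may
depend on observed values of other variables but not on the missing
value itself.  Each index individual with missing data is handled
independently:

1. Draw a 90% subset of individuals without replacement (possibly
   including the index case).  Default variant: from all individuals,
   filling the subset's remaining holes with values sampled with
   replacement from the variable's observed values; `complete_training`
   (CT): from fully observed individuals only, no filling needed.
2. Learn an inner best-fit network on the subset (greedy search, BIC).
   A fresh subset — hence a fresh network — per individual propagates
   model uncertainty into the imputation.
3. For each missing variable `z`, the *nearby variables* are the
   variables adjacent to `z` in the inner network and observed for the
   index individual.  A continuous child `y` of a continuous `z` with
   other continuous parents `x` is replaced by the adjusted variable
   `v = y − Σ β_x x` (β from OLS of `y` on all its continuous parents
   including `z`), which tracks `z` more specifically than `y`;
   parents missing for the index individual are simply not subtracted,
   and a discrete `z` gets no adjustment (the regression partition is
   unknown).  Distances sum squared differences divided by the
   variable's variance (continuous; variance over all observed values,
   for adjusted variables over rows where `v` is computable) and 0/1
   mismatches (discrete).
4. The candidate observing `z` and every nearby variable at minimal
   distance donates its observed value; exact ties break uniformly at
   random, and with no nearby variables or no candidate a random
   observer of `z` donates.

Observed entries are never altered; donor pools contain only originally
observed values, never freshly imputed ones; consequently imputed values
are always genuine data values (donor-copy), which is what protects the
joint structure.  The `all_nn` variant replaces step 3's selected set
with *all* observed variables (plain nearest neighbour) and therefore
skips steps 1–2; it is kept as a comparison method.

Design choices where the procedure was genuinely open, all documented
here as the package's own: one inner network per index individual shared
across that individual's missing variables; adjustment regressions
fitted on originally observed rows (not on the randomly filled subset,
to keep fill noise out of the coefficients); subset size
`max(2, floor(0.9·n))`; step-1 fills drawn from the variable's observed
values in the full data; the random-donor rule reused when a nonempty
nearby set leaves no eligible candidate; constraints applied uniformly
in inner searches; inner searches run the lighter restart policy noted
above.  Per-individual random streams are keyed to row identifiers, so
processing order and physical row order cannot change any imputed value.

The goal is downstream structure accuracy, not reconstruction error —
the method is *not* tuned to minimise per-value imputation error and no
multiple imputation is performed.

## Synthetic data

Continuous nodes follow linear-Gaussian structural equations
(`child = Σ β·parent + N(0,1)`; roots N(0,1)); the shared coefficient β
is each scenario's difficulty dial, with β = 0 giving exact
independence.  SNP nodes are Binomial(2, 0.5) allele dosages coded
continuous and flagged genetic.  Discrete networks load from BIF files.
The catalogue reproduces the benchmark layouts:

- `fig1A`–`fig1F`: six 3-variable structures, 1800 of 2000 individuals
  missing exactly one value (one starred column, or split alternately
  across a starred pair).
- `fig2` / `fig2_ae`: `A→B←C→D←E` with the 1800/2000 pattern split
  across B,D (or A,E); `chain5` the analogous 5-chain.
- `omics31`: 20 SNPs → 10 expression nodes (2 SNP parents each, round
  robin) → 1 trait; expression entries missing with probability 0.2.
  Default n = 300, chosen a priori so that the complete-case subset
  (≈ 0.8¹⁰ ≈ 11% of rows) is small enough to show the documented
  contrast while each true edge (partial R² ≈ 4% at β = 0.3) remains
  detectable from the imputed sample.
- `prior4`, `prior6`: fully observed networks for the soft-prior sweeps
  (`prior6`: hub B with branches B→C→D and B→E→F).

The exact 3-variable structures, the "complex" two-variable missingness
pattern (realised as a 50/50 alternating split) and the 31-variable
wiring are stand-ins reconstructed from the benchmark descriptions —
they preserve the qualitative shapes (SNPs → expression → trait;
one-variable-per-individual missingness) but are not exact replications,
and results on them are qualitative orderings, not curve reproductions.
The generators make no attempt to mimic measurement error, batch
effects, linkage disequilibrium between SNPs, or MNAR missingness, so
passing tests demonstrate correctness of the algorithms under their own
assumptions, not performance on any particular real data set.

Missingness injectors: exact fixed-count (one variable, or split across
a set), per-entry Bernoulli, and a MAR mechanism with a logistic link on
a fully observed covariate.  MNAR is deliberately out of scope.

## Evaluation harness

Per replicate: simulate → inject missingness → apply a handling method
(`full`, `reduced`, `random`, `mean`, `all_nn`, `imputed`,
`imputed_ct`) → greedy search → metrics.  Recall is the share of true
directed edges recovered exactly; precision the share of recovered edges
that are true; reversed edges count for neither.  Precision is undefined
for an empty estimate and is excluded from averages (with the exclusion
count reported) rather than scored as zero.  Whole-network correctness
is CPDAG equality.  Replicate counts default well below
publication scale (tens rather than hundreds to thousands) and are
plain arguments to scale up.  `em` and `mice` columns are reserved names
only, so externally computed results can be merged for plotting.

## Numerical notes and limitations

- Score comparisons use strict improvement with tolerance 1e−9;
  exhaustive ties resolve to the lexicographically smallest edge set.
- Zero-variance nearby variables contribute zero distance (with a
  warning); underdetermined adjustment regressions fall back to the
  unadjusted child.
- CPDAGs are computed as skeleton + v-structures closed under the Meek
  rules (R1–R3), validated against brute-force d-separation enumeration
  on all 4-node DAGs.
- The hill climber is exact best-improvement; no tabu list, MCMC or
  constraint-based (PC/FCI) search is provided.
- Purely discrete data is supported but not the design focus; on
  discrete benchmarks plain nearest-neighbour or chained-equation
  imputation can outperform the network-guided variants.
- Row identifiers are 0-based internally and 1-based in user-facing
  reports (provenance logs).
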