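# bnimpute

Bayesian network structure learning for mixed discrete/continuous data,
built for multi-omics causal exploration: SNPs, methylation, expression
and trait variables in one graph, with genetic variables acting as
causal anchors.  Its distinctive feature is a **network-guided
nearest-neighbour imputation** of missing data that targets the accuracy
of the *learned network*, not of the filled-in values — complete-case
analysis throws away every individual with any missing entry, which in
typical omics cohorts is most of them.

For whom: statistical geneticists and systems biologists who would
otherwise reach for score-based structure learning (bnlearn-style hill
climbing) but whose data has substantial, scattered missingness.

## The model and scores

A network is a DAG `M`; discrete nodes are multinomial, continuous
nodes are Gaussian regressions on their continuous parents fitted
separately per discrete-parent configuration.  Discrete nodes cannot
have continuous parents, and *genetic* variables admit no incoming
edges.  Fit is judged by decomposable scores

```
loglik = ln L̂      aic = ln L̂ − d      bic = ln L̂ − (d/2)·ln n
```

(`d` = free parameters; larger is better).  Structures are found by
greedy hill climbing with random and jitter restarts, or exhaustively
for ≤ 5 nodes.  Uncertainty is quantified by bootstrap model averaging:
per node pair, the *strength* (share of resamples containing the edge)
and *direction* (share of appearances in a given orientation), with
directed-edge probability = strength × direction.  Prior knowledge
enters as hard white/black lists or as *soft constraints*: a directed
edge prior `p(e)` adds `ln p(e)` to the BIC when the edge is present
(reverse direction: `ln(1 − p(e))`).

Imputation, per individual with missing data: learn a best-fit network
on a fresh 90% subsample, read off the variables adjacent to each
missing variable (regression-adjusting children for their other
parents), and copy the missing value from the nearest neighbour under a
variance-normalised distance on those variables.  See
`docs/methods.md` for the full procedure and its design choices.

## Worked example

```python
from bnimpute import (BayesianNetwork, ImputationConfig, SearchConfig,
                      builtin_scenario, recall_precision, run_comparison)

# collider benchmark A→B←C→D←E: 2000 individuals, 1800 of them missing
# one of B or D, effect strength beta = 0.3
sc = builtin_scenario("fig2", beta=0.3, n=2000, seed=7)

model = BayesianNetwork(sc.data)                 # data still has holes
reduced = model.reduce().fit(config=SearchConfig(seed=1))
imputed = model.impute(ImputationConfig(seed=1)).fit(config=SearchConfig(seed=1))
print(imputed.summary())
```

```
Bayesian network structure fit
  individuals: 2000
  variables:   5
  score (bic): -14218.1287
  search:      greedy
  edges:       4

from            to                    chi2  df           p
A               B                  230.394   1    4.89e-52
C               B                  144.608   1    2.62e-33
C               D                  123.375   1    1.15e-28
E               D                  111.560   1    4.46e-26
```

The imputed fit uses all 2000 individuals and recovers the generating
DAG exactly; the reduced fit (200 complete cases) reverses the A—B edge
on this replicate.  The χ² column is the likelihood-ratio statistic for
removing each edge.  Single replicates are noisy, so the harness
averages over many:

```python
results, summary = run_comparison("fig2", ["reduced", "imputed"],
                                  replicates=10, betas=(0.3,), seed=0)
print(summary[["method", "recall_mean", "precision_mean", "correct_prop"]].round(3))
```

```
 method  recall_mean  precision_mean  correct_prop
imputed          1.0           0.940           0.7
reduced          0.7           0.657           0.2
```

Over 10 replicates at β = 0.3, imputation recovers every true directed
edge at 94% precision versus 70%/66% for complete-case analysis, and
raises the share of replicates whose network is correct up to
observational equivalence from 0.2 to 0.7.

The same objects drive bootstrap averaging:

```python
avg = model.impute(ImputationConfig(seed=1)).fit_average(B=1000, seed=1)
avg.table                      # node1, node2, strength, direction, edge prob
avg.strength_threshold()       # data-driven cutoff for plotting
avg.to_dot()                   # Graphviz export, weak edges omitted
```

A `bnimpute` command-line tool wraps the same library
(`simulate`, `search`, `average`, `impute` subcommands); run
`bnimpute --help`.

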