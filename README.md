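# epiforest

Benchmarking random-forest feature-importance metrics on genotype/phenotype
data with non-additive (epistatic) interactions.

## Why

Random forests are widely used for case/control genetic association because
their tree structure can model statistical epistasis — interactions among
loci whose joint effect deviates from the sum of their marginal effects.
Interpreting a fitted forest, however, depends on which global
feature-importance metric you trust:

* **BIC** — the built-in impurity-decrease (Gini) importances,
* **PFI** — permutation feature importance, the relative drop in held-out
  balanced accuracy after permuting a feature (or a feature pair/trio),
* **SHAP** — mean absolute Shapley attribution per feature.

These frequently disagree on real SNP panels, and without ground truth
there is no way to say which one is right.  `epiforest` settles the
question on simulated data: it evolves expression-tree genotype→phenotype
models by genetic programming under an information-gain fitness (so the
planted signal is genuinely non-additive), derives *true* per-feature
importances from the known generating program by permutation sensitivity
analysis, and scores each metric's ability to recover the true ranks.

The interaction signal is measured in bits by entropy-based information
gain, e.g. for a feature pair (X, Y) and phenotype Z:

    IG(X;Y;Z) = I(X,Y;Z) − I(X;Z) − I(Y;Z)

with positive IG indicating synergy.  The three-way analogue subtracts all
embedded pairwise gains and main effects.

## Worked example

```python
import numpy as np
from epiforest import (
    SimulationConfig, evolve_dataset, sensitivity_scores, rank_features,
    permutation_feature_importance, cv_balanced_accuracy,
    builtin_gini_importance,
)

# one replicate: n=1000 samples, 5 SNP-style features, 25% cases,
# fitness = sum of two-way IG over all feature pairs
rep = evolve_dataset(SimulationConfig(
    n_samples=1000, case_fraction=0.25, ig_order=2, seed=7))
print(rep.tree.to_prefix_str())
print("aggregate IG (bits):", round(rep.fitness_at_end[0], 3))

truth = sensitivity_scores(rep.tree, rep.dataset, n_reps=100, rng=7)
print("true scores:", np.round(truth.scores, 3), rank_features(truth))

X, y = rep.dataset.genotypes, rep.dataset.phenotype
pfi = permutation_feature_importance(X, y, feature_ids=rep.dataset.feature_ids, rng=7)
fit = cv_balanced_accuracy(X, y, folds=10, rng=7)
bic = builtin_gini_importance(fit, feature_ids=rep.dataset.feature_ids)
print("cv balanced accuracy:", round(fit.cv_balanced_accuracy, 3))
print("PFI :", np.round(pfi.scores, 3), rank_features(pfi))
print("BIC :", np.round(bic.scores, 3), rank_features(bic))
```

Output:

```
(MUL (EQ (MUL (DIV X2 X1) (NOT X4)) (MUL X2 (MIN X5 0))) (EQ (OR (LT X1 X1) 1) (NOT (SUB X4 X3))))
aggregate IG (bits): 0.715
true scores: [0.    0.072 0.463 0.464 0.   ] ['f4', 'f3', 'f2', 'f1', 'f5']
cv balanced accuracy: 0.977
PFI : [0.    0.07  0.451 0.479 0.   ] ['f4', 'f3', 'f2', 'f1', 'f5']
BIC : [0.027 0.096 0.441 0.411 0.025] ['f3', 'f4', 'f2', 'f1', 'f5']
```

The evolved program's phenotype depends on an interaction between
features 3 and 4 (true scores near-tied at 0.46) with a weaker
contribution from feature 2; features 1 and 5 appear in the program text
but in dead subexpressions (`LT X1 X1` is always false, `MIN X5 0` always
zero), and the sensitivity analysis correctly scores them exactly zero.
PFI reproduces the true profile to a few hundredths and matches all five
ranks, including the near-tie at the top; the impurity importances assign
spurious mass to the functionally inert features and swap the top pair.
Aggregated over replicated simulations this becomes the benchmark's
headline: PFI recovers true ranks about twice as reliably as the built-in
importances on interaction-driven data.

A benchmark cell end to end (simulate → ground truth → metrics → tables):

```bash
epiforest run --seed 1 --replicates 20 --out-dir results/cell
epiforest simulate --n-samples 1000 --replicates 5 --seed 2 --out-dir sims/
epiforest network sims/rep_000.tsv --out net.tsv
```

User-supplied SNP matrices (TSV/CSV with `sample_id`, feature columns in
{0,1,2}, binary `phenotype`) run through the same `importance` and
`network` commands; a minimal VCF import shim is included.

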