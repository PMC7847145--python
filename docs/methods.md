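# Methods

## The problem

Random forests are popular in genetic-association analysis because their
hierarchical splits can capture statistical epistasis — phenotype effects
that deviate from the sum of single-locus effects.  But a fitted forest is
only as useful as its interpretation, and the field uses at least three
competing global feature-importance metrics: the built-in impurity-decrease
(Gini) scores, permutation feature importance, and mean absolute SHAP
values.  This package benchmarks the three against a known ground truth on
synthetic case/control genotype data whose phenotype depends on planted
two- or three-way interactions.

## Information-theoretic core

All interaction measures are plug-in estimates over discrete contingency
tables, log base 2 (bits).  For features X, Y and phenotype Z:

    I(X;Z)    = H(Z) − H(Z|X),            H(Z|X) = H(Z,X) − H(X)
    IG(X;Y;Z) = I(X,Y;Z) − I(X;Z) − I(Y;Z)

and for trios, with outcome N:

    IG(X;Y;Z;N) = I(X,Y,Z;N) − IG(X;Y;N) − IG(X;Z;N) − IG(Y;Z;N)
                  − I(X;N) − I(Y;N) − I(Z;N)

A positive IG is synergy (non-additivity); a negative one redundancy.  MI
values are clipped at zero after floating-point roundoff; IG values keep
their sign.  No small-sample bias correction is applied — the plug-in
estimator is the quantity of interest throughout, and the test suite
verifies the decomposition against direct summation over the full joint
table to 1e-12 on thousands of random tables.

## Synthetic-data generator

Genotypes are n x m tables (default m = 5) drawn i.i.d. uniform over
{0, 1, 2}; allele-frequency structure, linkage disequilibrium and
population structure are deliberately out of scope.  A genotype→phenotype
map is an expression tree over the operator set

    ADD SUB MUL DIV* MIN MAX MOD* EQ GT LT AND OR XOR NOT

(* protected: DIV returns the numerator and MOD returns 0 when the divisor
is 0; boolean operators coerce nonzero to true and emit 0/1), with feature
references and the constants 0, 1, 2 as terminals.  The raw tree output is
thresholded at the (1 − case fraction) quantile; threshold ties are broken
uniformly at random so the realized case count is exactly
round(n · case_fraction).  A constant raw output admits no such phenotype
and marks the tree degenerate.

Trees are evolved by genetic programming under a two-objective fitness,
both maximized with NSGA-II selection:

1. the sum of two-way IG over all C(m,2) feature pairs (or three-way IG
   over all C(m,3) trios) between the genotypes and the derived phenotype —
   summing over all combinations encourages multiple simultaneous
   interactions rather than one isolated pair (a per-best-pair objective is
   available via `ig_aggregate="max"`);
2. the expression-tree length (node count).

Defaults: population 100, 50 generations, ramped half-and-half
initialization (depth 2–4), one-point subtree crossover p = 0.5, uniform
subtree mutation p = 0.2, binary tournament on (front rank, crowding
distance).  Degenerate trees receive worst fitness rather than raising.
The overall best individual (highest IG, ties to the longer tree) defines
the emitted dataset.

**Depth cap.**  The tree-depth cap is 4.  This is the one generator
parameter that materially shapes the emitted data: deep programs entangle
four or five features with near-tied importances, while a cap of 4 keeps
the phenotype's effect concentrated on two to three features — the regime
the reference experiments report, where the rank-4 and rank-5 features have
exactly zero effect in roughly 70–90% of replicates.  We calibrated the cap
against that per-rank zero-effect structure.

**Reproducibility.**  Each replicate seed spawns three independent child
streams (genotype sampling, GP loop, final phenotype tie-break), so a
serialized (tree, seed, config) triple reconstructs the identical dataset.
Replicate seeds derive from the master seed via
`SeedSequence([master, index])`, stable across platforms.

**Cost.**  Fitness evaluation exploits that genotypes are fixed within a
replicate: row-configuration codes and genotype-only marginal entropies are
precomputed, so each candidate tree costs one program evaluation over the
unique genotype rows, one quantile cut, and one bincount into a 3^m x 2
tensor.  A replicate at n = 1000 takes about a second on one core.

## Sensitivity-analysis ground truth

Because the generating program is known exactly, true importances are
measured directly on it: per replicate, each genotype column in turn is
permuted, the tree re-evaluated, and phenotype mismatches against the
unperturbed phenotype counted; mismatch counts are normalized across
features by their total, averaged over 100 permutation replicates, and
renormalized to sum to 1.

The perturbed outputs are compared against the dataset's *frozen*
binarization threshold rather than re-quantiled: samples whose raw output
did not change keep their original (tie-broken) label, so a column the
program never reads scores exactly zero — not merely zero in expectation —
and the score isolates the tree's functional dependence on the column.
Re-thresholding per perturbation is available behind a flag
(`frozen_threshold=False`) but changes the interpretation: it measures
rank-order dependence rather than output dependence.  All-zero profiles
(possible for degenerate models) are left all-zero and flagged, never
replaced by a uniform vector.

Ranking is by descending score with ties — including the zero block —
broken by ascending feature index.  This deterministic tie rule means
matches at the zero-block ranks are decided by index coincidence, which is
why every metric's tail-rank success is near chance level; we document
rather than "fix" this, since any tie rule has the same property.

## Importance metrics under comparison

* **PFI** — per repeat: stratified 75/25 shuffle/split, forest fitted on
  the training part, balanced accuracy BA0 on the held-out part; each
  feature's test column permuted and the relative decrease
  (BA0 − BAp)/BA0 recorded; means over repeats are clipped at zero and
  normalized to sum to 1 (raw means retained).  Repeats default to m − 1.
  Per repeat, ranking is invariant to whether the decrease is divided by
  BA0, since BA0 is a repeat-wide constant.  Multi-feature PFI (pairs /
  trios) permutes each column of a tuple *independently*, destroying the
  joint signal, and enumerates all C(m,2) or C(m,3) tuples.
* **BIC** — the forest's impurity-decrease importances, renormalized.
* **SHAP** — exact path-dependent tree-Shapley attributions of the
  positive-class probability, computed in-package by subset enumeration
  over each tree's split features (exact for the small panels analysed
  here; a guard rejects m > 14).  The global score is the per-feature mean
  of absolute per-sample attributions; a signed-mean variant sits behind a
  flag.  Local additivity (attributions + base value = prediction) is
  asserted in tests to machine precision.

The reference classifier is a 100-tree Gini random forest with sqrt
features per split; optional grid-search tuning covers tree count, depth
and leaf size.  Model quality is stratified 10-fold cross-validated
balanced accuracy, with a label-permutation significance test
(p = (1 + #{null ≥ observed}) / (B + 1)).

## Evaluation

Rank success is per-rank feature-identity match between a metric's ranking
and the ground truth, aggregated over replicates as a percentage — not a
whole-permutation match.  The zero-effect table reports how often the
rank-r feature has exactly zero true effect.  Interaction detection
compares two strategies per replicate against the dataset's strongest IG
pair (or trio): the top-2 (top-3) features of single-feature PFI as a set,
versus the arg-max tuple of PFI2/PFI3; IG values of the top three
interactions are stratified by detection status.  Spearman correlations
among feature columns are reported with constant columns flagged and set
to 0.

## What the simulations do and do not show

The generator emulates SNP-panel data in coding and class structure but
not in allele-frequency spectrum, missingness, linkage disequilibrium, or
covariate structure.  Passing benchmarks here show that a metric can
recover functional importance ranks when features are independent and the
signal is a planted non-additive interaction; they do not certify behaviour
under correlated predictors — where permutation importance is known to
have its own pathologies — or under weak polygenic signal.  The
hierarchical-clustering preprocessing suggested for correlated features is
out of scope; only the raw correlation matrix is provided.

## Problem sizes and numerical choices

The default benchmark cell is 100 replicates; the shipped test suite runs
scaled-down cells (25–50 replicates at n = 1000, 25 at n = 10,000) chosen
so the whole suite completes in minutes on one core, and the acceptance
script runs the full 100-replicate primary cell.  Tolerances: profile
normalization asserts sums within 1e-9; exact-zero comparisons are exact
(no epsilon) because the quantities are counts; stochastic comparisons use
binomial confidence intervals at the realized replicate count.  Tie-breaks
are deterministic everywhere except phenotype threshold ties, which are
seeded.  Degenerate inputs (constant phenotype, constant tree output,
single-class folds) raise typed errors or worst-fitness sentinels as
documented per function.
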