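"""Ground-truth feature importances from the generating expression tree.

Because the simulator emits the exact program that produced each phenotype,
true importances can be measured by permutation sensitivity analysis: shuffle
one genotype column at a time, push the perturbed matrix back through the
generating tree, and count how many samples flip phenotype.  Features the
program never reads score exactly zero; features carrying interaction or
main effects score in proportion to how often perturbing them flips the
outcome.

The perturbed raw outputs are compared against the dataset's *frozen*
binarization threshold rather than re-quantiled, so the mismatch count
reflects the tree's functional dependence on the column and an untouched
column reproduces the original phenotype exactly (samples whose raw output
is unchanged keep their original tie-broken label).  Re-thresholding per
perturbation is available behind ``frozen_threshold=False``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datatypes import GenotypeMatrix
from .errors import InvalidArgumentError
from .trees import ExpressionTree, evaluate_tree


@dataclass
class TrueImportanceProfile:
    """Sensitivity-analysis scores: non-negative, summing to 1 (or all zero
    for a null model, flagged via ``all_zero``)."""

    feature_ids: list[str]
    scores: np.ndarray
    n_permutation_reps: int
    seed: int | None = None
    all_zero: bool = False
    per_replicate: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.size != len(self.feature_ids):
            raise InvalidArgumentError("scores/feature_ids length mismatch")
        if (self.scores < 0).any() or not np.isfinite(self.scores).all():
            raise InvalidArgumentError("scores must be finite and >= 0")
        total = self.scores.sum()
        if self.all_zero:
            if total != 0.0:
                raise InvalidArgumentError("all_zero profile with nonzero scores")
        elif abs(total - 1.0) > 1e-9:
            raise InvalidArgumentError(f"scores sum to {total}, expected 1")

    def ranking(self) -> list[str]:
        return rank_features(self)


def rank_features(profile) -> list:
    """Features by descending score; ties broken by ascending position.

    Accepts any object with ``scores`` and either ``feature_ids`` or
    ``units``.  With all-zero scores the ranking degenerates to input order.
    """
    ids = getattr(profile, "feature_ids", None) or getattr(profile, "units")
    scores = np.asarray(profile.scores, dtype=float)
    if not np.isfinite(scores).all():
        raise InvalidArgumentError("scores must be finite")
    order = np.lexsort((np.arange(scores.size), -scores))
    return [ids[i] for i in order]


def _frozen_threshold(raw: np.ndarray, phenotype: np.ndarray) -> float:
    """Recover the case/control cut applied to the original raw output.

    The threshold is the largest raw value carrying a control label; values
    strictly above it were labelled case (tie samples at the threshold may
    carry either label from the randomized exact-count tie-break).
    """
    controls = raw[phenotype == 0]
    if controls.size == 0:
        raise InvalidArgumentError("phenotype has no controls")
    return float(np.nan_to_num(controls, posinf=1e300, neginf=-1e300).max())


def sensitivity_scores(
    tree: ExpressionTree,
    dataset: GenotypeMatrix,
    n_reps: int = 100,
    rng: np.random.Generator | int | None = None,
    frozen_threshold: bool = True,
    keep_replicates: bool = False,
) -> TrueImportanceProfile:
    """Permutation sensitivity analysis of a generating tree on its dataset.

    Per replicate, each feature column in turn is permuted (rows shuffled
    within the column), the tree re-evaluated, and phenotype mismatches
    against the unperturbed phenotype counted; mismatch counts are
    normalized across features by their total (all-zero replicates
    contribute a zero vector).  The final score is the across-replicate
    mean, renormalized to sum to 1.
    """
    if n_reps < 1:
        raise InvalidArgumentError("n_reps must be >= 1")
    if dataset.phenotype is None:
        raise InvalidArgumentError("dataset has no phenotype")
    m = dataset.n_features
    feats = tree.feature_indices()
    if feats and max(feats) >= m:
        raise InvalidArgumentError(
            f"tree references feature X{max(feats) + 1}; dataset has m={m}"
        )
    seed = rng if isinstance(rng, (int, np.integer)) else None
    rng = np.random.default_rng(rng)

    G = dataset.genotypes
    y0 = dataset.phenotype
    raw0 = np.nan_to_num(
        evaluate_tree(tree, G), posinf=1e300, neginf=-1e300
    )
    thr = _frozen_threshold(raw0, y0)
    n = dataset.n_samples
    k_cases = int(y0.sum())

    per_rep = np.zeros((n_reps, m))
    for r in range(n_reps):
        mismatches = np.zeros(m)
        for j in range(m):
            if j not in feats:
                continue  # program never reads this column: zero mismatches
            Gp = G.copy()
            Gp[:, j] = G[rng.permutation(n), j]
            raw_p = np.nan_to_num(
                evaluate_tree(tree, Gp), posinf=1e300, neginf=-1e300
            )
            if frozen_threshold:
                # samples whose raw output did not change keep their original
                # (possibly tie-broken) label; changed outputs are re-cut at
                # the frozen threshold
                y_p = np.where(raw_p == raw0, y0, (raw_p > thr).astype(np.int64))
            else:
                order = np.argsort(raw_p, kind="stable")
                y_p = np.zeros(n, dtype=np.int64)
                y_p[order[n - k_cases:]] = 1
            mismatches[j] = int((y_p != y0).sum())
        total = mismatches.sum()
        if total > 0:
            per_rep[r] = mismatches / total
    mean = per_rep.mean(axis=0)
    total = mean.sum()
    all_zero = total <= 0.0
    scores = mean / total if not all_zero else np.zeros(m)
    return TrueImportanceProfile(
        feature_ids=list(dataset.feature_ids),
        scores=scores,
        n_permutation_reps=n_reps,
        seed=seed,
        all_zero=all_zero,
        per_replicate=per_rep if keep_replicates else None,
        metadata={"frozen_threshold": frozen_threshold},
    )
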