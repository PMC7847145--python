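"""Scoring importance metrics against the sensitivity-analysis ground truth.

The central question of the benchmark: across replicated simulations, how
often does each interpretation metric place the same feature at rank r as
the ground-truth ranking?  Rank matching is by feature identity at each
rank independently, with the shared deterministic tie rule (descending
score, ties by ascending feature position) applied to both sides.  Note
that truth profiles routinely carry blocks of exactly-zero scores (features
the generating program never reads), so matches in the zero block are
decided by the index tie-break — which is why tail ranks show near-chance
success for every metric.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .errors import InvalidArgumentError
from .infotheory import InteractionNetwork
from .sensitivity import rank_features

RANK_METRICS = ("PFI", "BIC", "SHAP")


@dataclass
class RankSuccessTable:
    """Per-rank, per-metric match percentage against ground truth."""

    cell: dict
    n_replicates: int
    success: dict[str, list[float]]  # metric -> percentage per rank F1..Fm
    feature_count: int

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"metric": metric, "rank": f"F{r + 1}", "success_pct": pct, **self.cell}
            for metric, per_rank in self.success.items()
            for r, pct in enumerate(per_rank)
        ]
        return pd.DataFrame(rows)

    def wide(self) -> pd.DataFrame:
        """Table-1-shaped layout: ranks as rows, metrics as columns."""
        return pd.DataFrame(
            {m: self.success[m] for m in self.success},
            index=[f"F{r + 1}" for r in range(self.feature_count)],
        )


@dataclass
class ZeroEffectTable:
    """Percentage of replicates whose rank-r feature has exactly zero
    ground-truth effect size."""

    cell: dict
    n_replicates: int
    zero_pct: list[float]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": [f"F{r + 1}" for r in range(len(self.zero_pct))],
                "zero_effect_pct": self.zero_pct,
                **{k: [v] * len(self.zero_pct) for k, v in self.cell.items()},
            }
        )


@dataclass
class DetectionSummary:
    """Interaction-detection success of one detection mode."""

    cell: dict
    mode: str  # "single_top_k" | "multi_pfi"
    order: int
    n_replicates: int
    success_pct: float
    # top-3 interaction IG values, stratified by per-replicate success
    ig_by_status: dict[str, list[list[float]]] = field(default_factory=dict)


def rank_success_table(
    estimated: dict[str, Sequence],
    truth: Sequence,
    cell: dict | None = None,
) -> RankSuccessTable:
    """Per-rank identity-match percentages for each metric's profiles.

    ``estimated`` maps metric name to a list of profiles aligned with
    ``truth`` by replicate index.
    """
    if not truth:
        raise InvalidArgumentError("empty truth list")
    n_rep = len(truth)
    m = len(truth[0].feature_ids)
    truth_ranks = [rank_features(t) for t in truth]
    success: dict[str, list[float]] = {}
    for metric, profiles in estimated.items():
        if len(profiles) != n_rep:
            raise InvalidArgumentError(
                f"metric {metric!r} has {len(profiles)} profiles for "
                f"{n_rep} truth replicates"
            )
        counts = np.zeros(m)
        for prof, t_rank in zip(profiles, truth_ranks):
            e_rank = rank_features(prof)
            if len(e_rank) != m:
                raise InvalidArgumentError("profile/truth feature count mismatch")
            for r in range(m):
                if e_rank[r] == t_rank[r]:
                    counts[r] += 1
        success[metric] = (100.0 * counts / n_rep).tolist()
    return RankSuccessTable(
        cell=cell or {}, n_replicates=n_rep, success=success, feature_count=m
    )


def zero_effect_table(truth: Sequence, cell: dict | None = None) -> ZeroEffectTable:
    """Fraction of replicates with an exactly-zero score at each rank."""
    if not truth:
        raise InvalidArgumentError("empty truth list")
    m = len(truth[0].feature_ids)
    counts = np.zeros(m)
    for t in truth:
        ranked = rank_features(t)
        pos = {f: i for i, f in enumerate(t.feature_ids)}
        for r, f in enumerate(ranked):
            if t.scores[pos[f]] == 0.0:
                counts[r] += 1
    return ZeroEffectTable(
        cell=cell or {},
        n_replicates=len(truth),
        zero_pct=(100.0 * counts / len(truth)).tolist(),
    )


def strongest_interaction(
    network: InteractionNetwork, order: int = 2
) -> tuple[tuple, float]:
    """Arg-max IG tuple at the requested order; ties go to the
    lexicographically smallest tuple."""
    if order == 2:
        table = network.pairwise_ig
    elif order == 3:
        table = network.threeway_ig
    else:
        raise InvalidArgumentError("order must be 2 or 3")
    if not table:
        raise InvalidArgumentError(f"network has no order-{order} values")
    best = max(sorted(table), key=lambda k: (table[k], ))
    # max() keeps the first of equal keys; sorted() makes that the
    # lexicographically smallest tuple
    return best, table[best]


def _top_interactions(network: InteractionNetwork, order: int, k: int = 3) -> list[float]:
    table = network.pairwise_ig if order == 2 else network.threeway_ig
    return sorted(table.values(), reverse=True)[:k]


def interaction_detection_success(
    profiles: Sequence,
    networks: Sequence[InteractionNetwork],
    mode: str,
    order: int = 2,
    cell: dict | None = None,
) -> DetectionSummary:
    """Did the metric's top features recover the strongest interaction?

    ``single_top_k``: success when the top-``order`` features of a
    single-feature PFI profile equal (as a set) the strongest IG tuple.
    ``multi_pfi``: success when the top unit of a PFI2/PFI3 profile equals
    it.  Top-3 interaction IG values are stratified by detection status.
    """
    if mode not in ("single_top_k", "multi_pfi"):
        raise InvalidArgumentError(f"unknown mode {mode!r}")
    if order not in (2, 3):
        raise InvalidArgumentError("order must be 2 or 3")
    if len(profiles) != len(networks):
        raise InvalidArgumentError("profiles/networks length mismatch")
    expected_metric = "PFI" if mode == "single_top_k" else f"PFI{order}"
    hits = 0
    ig_by_status: dict[str, list[list[float]]] = {"detected": [], "missed": []}
    for prof, net in zip(profiles, networks):
        if prof.metric != expected_metric:
            raise InvalidArgumentError(
                f"mode {mode!r} at order {order} needs {expected_metric} "
                f"profiles, got {prof.metric}"
            )
        target, _ = strongest_interaction(net, order)
        ranked = rank_features(prof)
        if mode == "single_top_k":
            found = set(ranked[:order]) == set(target)
        else:
            found = set(ranked[0]) == set(target)
        hits += found
        ig_by_status["detected" if found else "missed"].append(
            _top_interactions(net, order)
        )
    return DetectionSummary(
        cell=cell or {},
        mode=mode,
        order=order,
        n_replicates=len(profiles),
        success_pct=100.0 * hits / len(profiles),
        ig_by_status=ig_by_status,
    )


def feature_correlation_matrix(X: np.ndarray) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Spearman rank correlations among feature columns.

    Returns the symmetric unit-diagonal matrix and a list of (i, j) pairs
    whose correlation was undefined (constant column) and reported as 0.
    """
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] < 2:
        raise InvalidArgumentError("need a 2-D matrix with m >= 2")
    m = X.shape[1]
    with warnings.catch_warnings():
        # constant columns make the rank correlation undefined; reported as 0
        warnings.simplefilter("ignore")
        rho = spearmanr(X).statistic
    rho = np.atleast_2d(np.asarray(rho, dtype=float))
    flagged: list[tuple[int, int]] = []
    for i in range(m):
        for j in range(m):
            if np.isnan(rho[i, j]):
                rho[i, j] = 1.0 if i == j else 0.0
                if i < j:
                    flagged.append((i, j))
    np.fill_diagonal(rho, 1.0)
    return rho, flagged


def effect_size_quantiles(
    profiles_by_metric: dict[str, Sequence],
    quantiles: Sequence[float] = (0.05, 0.25, 0.5, 0.75, 0.95),
    cell: dict | None = None,
) -> pd.DataFrame:
    """Per-rank score distribution summaries across replicates.

    One row per metric x rank x quantile: the distribution of the score of
    the rank-r feature over replicates, the tabular backbone of the
    effect-size-per-rank comparison between metrics and ground truth.
    """
    rows = []
    for metric, profiles in profiles_by_metric.items():
        if not profiles:
            continue
        m = len(np.asarray(profiles[0].scores))
        ranked_scores = np.array(
            [np.sort(np.asarray(p.scores))[::-1] for p in profiles]
        )
        for r in range(m):
            qs = np.quantile(ranked_scores[:, r], quantiles)
            for q, v in zip(quantiles, qs):
                rows.append(
                    {"metric": metric, "rank": f"F{r + 1}", "quantile": q,
                     "score": float(v), **(cell or {})}
                )
    return pd.DataFrame(rows)
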