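"""Shared dataset and importance-profile containers.

The universal currency of the pipeline is the :class:`GenotypeMatrix`: an
``n x m`` table of discrete genotype codes (0, 1, 2 — the number of copies of
the minor allele at a SNP-style locus) together with a binary case/control
phenotype.  Importance metrics of every flavour (permutation, impurity,
Shapley, sensitivity-analysis ground truth) are exchanged as
:class:`ImportanceProfile` objects whose normalized scores sum to one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError

VALID_GENOTYPES = (0, 1, 2)


@dataclass
class GenotypeMatrix:
    """n samples x m features of genotype codes plus an optional phenotype.

    Parameters
    ----------
    genotypes
        Integer array of shape ``(n, m)`` with entries in ``{0, 1, 2}``.
    phenotype
        Binary vector of length ``n`` (1 = case), or ``None`` while the
        phenotype has not yet been generated.
    feature_ids, sample_ids
        Unique identifiers; defaults are ``f1..fm`` and ``s1..sn``.
    """

    genotypes: np.ndarray
    phenotype: np.ndarray | None = None
    feature_ids: list[str] = field(default_factory=list)
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int64)
        if self.genotypes.ndim != 2:
            raise InvalidArgumentError("genotypes must be a 2-D array")
        n, m = self.genotypes.shape
        if n < 1 or m < 2:
            raise InvalidArgumentError(
                f"need n >= 1 samples and m >= 2 features, got n={n}, m={m}"
            )
        if not np.isin(self.genotypes, VALID_GENOTYPES).all():
            bad = np.argwhere(~np.isin(self.genotypes, VALID_GENOTYPES))[0]
            raise InvalidArgumentError(
                f"genotype value {self.genotypes[tuple(bad)]} at row {bad[0]}, "
                f"column {bad[1]} is not in {{0,1,2}}"
            )
        if self.phenotype is not None:
            self.phenotype = np.asarray(self.phenotype, dtype=np.int64)
            if self.phenotype.shape != (n,):
                raise InvalidArgumentError(
                    f"phenotype length {self.phenotype.shape} does not match n={n}"
                )
            if not np.isin(self.phenotype, (0, 1)).all():
                raise InvalidArgumentError("phenotype entries must be 0/1")
        if not self.feature_ids:
            self.feature_ids = [f"f{j + 1}" for j in range(m)]
        if not self.sample_ids:
            self.sample_ids = [f"s{i + 1}" for i in range(n)]
        if len(self.feature_ids) != m:
            raise InvalidArgumentError("feature_ids length mismatch")
        if len(self.sample_ids) != n:
            raise InvalidArgumentError("sample_ids length mismatch")
        if len(set(self.feature_ids)) != m or len(set(self.sample_ids)) != n:
            raise InvalidArgumentError("feature/sample ids must be unique")

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_features(self) -> int:
        return self.genotypes.shape[1]

    @property
    def case_count(self) -> int:
        if self.phenotype is None:
            raise InvalidArgumentError("phenotype not set")
        return int(self.phenotype.sum())

    def to_frame(self) -> pd.DataFrame:
        """Tidy frame: sample_id, one column per feature, phenotype."""
        df = pd.DataFrame(self.genotypes, columns=self.feature_ids)
        df.insert(0, "sample_id", self.sample_ids)
        if self.phenotype is not None:
            df["phenotype"] = self.phenotype
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GenotypeMatrix":
        cols = list(df.columns)
        if "sample_id" not in cols or "phenotype" not in cols:
            raise InvalidArgumentError(
                "frame must have 'sample_id' and 'phenotype' columns"
            )
        feats = [c for c in cols if c not in ("sample_id", "phenotype")]
        return cls(
            genotypes=df[feats].to_numpy(),
            phenotype=df["phenotype"].to_numpy(),
            feature_ids=feats,
            sample_ids=[str(s) for s in df["sample_id"]],
        )


def _normalize_scores(raw: np.ndarray) -> tuple[np.ndarray, bool]:
    """Clip negatives to zero and normalize to sum 1.

    Returns (normalized, all_zero_flag); an all-nonpositive input yields the
    zero vector with the flag set, never NaN.
    """
    clipped = np.clip(np.asarray(raw, dtype=float), 0.0, None)
    total = clipped.sum()
    if total <= 0.0:
        return np.zeros_like(clipped), True
    return clipped / total, False


@dataclass
class ImportanceProfile:
    """One metric's per-unit importance scores for one dataset.

    ``units`` are single feature ids for PFI/BIC/SHAP and 2- or 3-tuples of
    feature ids for the multi-feature permutation importances (PFI2/PFI3).
    ``scores`` are non-negative and sum to 1 unless ``all_zero`` is set.
    """

    metric: str
    units: list
    scores: np.ndarray
    raw_scores: np.ndarray
    model_descriptor: str = ""
    seed: int | None = None
    all_zero: bool = False
    metadata: dict = field(default_factory=dict)

    VALID_METRICS = ("PFI", "BIC", "SHAP", "PFI2", "PFI3", "sensitivity")

    def __post_init__(self) -> None:
        if self.metric not in self.VALID_METRICS:
            raise InvalidArgumentError(f"unknown metric {self.metric!r}")
        self.scores = np.asarray(self.scores, dtype=float)
        self.raw_scores = np.asarray(self.raw_scores, dtype=float)
        if len(self.units) != self.scores.size:
            raise InvalidArgumentError("units/scores length mismatch")
        if not np.isfinite(self.scores).all():
            raise InvalidArgumentError("scores must be finite")
        total = self.scores.sum()
        if not self.all_zero and abs(total - 1.0) > 1e-9:
            raise InvalidArgumentError(f"scores sum to {total}, expected 1")

    @classmethod
    def from_raw(cls, metric: str, units: list, raw: np.ndarray, **kw) -> "ImportanceProfile":
        scores, all_zero = _normalize_scores(raw)
        return cls(metric=metric, units=units, scores=scores,
                   raw_scores=np.asarray(raw, dtype=float), all_zero=all_zero, **kw)

    def ranking(self) -> list:
        """Units sorted by descending score, ties by ascending position."""
        order = np.lexsort((np.arange(self.scores.size), -self.scores))
        return [self.units[i] for i in order]

    def to_frame(self) -> pd.DataFrame:
        unit_labels = [
            u if isinstance(u, str) else "+".join(map(str, u)) for u in self.units
        ]
        order = np.lexsort((np.arange(self.scores.size), -self.scores))
        ranks = np.empty(self.scores.size, dtype=int)
        ranks[order] = np.arange(1, self.scores.size + 1)
        return pd.DataFrame(
            {"unit": unit_labels, "score": self.scores,
             "raw_score": self.raw_scores, "rank": ranks}
        )
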