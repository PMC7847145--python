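"""Plug-in entropy, mutual information and interaction information gain.

All quantities are computed from contingency counts with maximum-likelihood
(plug-in) probability estimates and log base 2, so every value is in bits.
Unobserved category combinations contribute zero to entropy sums.

The two-way interaction information gain between features X, Y and a
phenotype Z is

    IG(X;Y;Z) = I(X,Y;Z) - I(X;Z) - I(Y;Z),

the synergy left after subtracting both main effects; a positive value
indicates a non-additive (epistatic) effect, a negative one redundancy.
The three-way gain additionally subtracts all embedded two-way gains:

    IG(X;Y;Z;N) = I(X,Y,Z;N) - IG(X;Y;N) - IG(X;Z;N) - IG(Y;Z;N)
                  - I(X;N) - I(Y;N) - I(Z;N).

Mutual information is computed through the standard conditional-entropy
identity H(Z|X) = H(Z,X) - H(X).  MI values are clipped at zero after
floating-point roundoff; IG values are NOT clipped because their sign is
meaningful.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Hashable, Iterable, Mapping, Sequence

import numpy as np

from .errors import DegenerateInputError, InvalidArgumentError


@dataclass
class ContingencyCounts:
    """Joint counts over an ordered set of discrete variables.

    ``counts`` maps joint category tuples (one entry per variable, in
    ``variables`` order) to non-negative integer counts; ``total`` is their
    sum.
    """

    variables: list[Hashable]
    counts: dict[tuple, int]
    total: int = 0

    def __post_init__(self) -> None:
        if not self.variables:
            raise InvalidArgumentError("at least one variable required")
        if len(set(self.variables)) != len(self.variables):
            raise InvalidArgumentError("variable names must be unique")
        k = len(self.variables)
        s = 0
        for cell, c in self.counts.items():
            if len(cell) != k:
                raise InvalidArgumentError(
                    f"cell {cell!r} has arity {len(cell)}, expected {k}"
                )
            if c < 0:
                raise InvalidArgumentError("counts must be non-negative")
            s += c
        if self.total == 0:
            self.total = s
        elif self.total != s:
            raise InvalidArgumentError(
                f"total {self.total} != sum of counts {s}"
            )

    @classmethod
    def from_columns(
        cls, columns: Mapping[Hashable, np.ndarray]
    ) -> "ContingencyCounts":
        """Tabulate joint counts from aligned sample columns."""
        names = list(columns)
        mat = np.column_stack([np.asarray(columns[v]) for v in names])
        uniq, cnt = np.unique(mat, axis=0, return_counts=True)
        counts = {tuple(row): int(c) for row, c in zip(uniq, cnt)}
        return cls(variables=names, counts=counts)

    def _index(self, subset: Sequence[Hashable]) -> list[int]:
        if not subset:
            raise InvalidArgumentError("variable subset must be non-empty")
        if len(set(subset)) != len(subset):
            raise InvalidArgumentError("variable subset has duplicates")
        try:
            return [self.variables.index(v) for v in subset]
        except ValueError as exc:
            raise InvalidArgumentError(f"unknown variable in {subset!r}") from exc

    def marginal(self, subset: Sequence[Hashable]) -> dict[tuple, int]:
        """Joint counts marginalized onto ``subset`` (in the given order)."""
        idx = self._index(subset)
        out: dict[tuple, int] = {}
        for cell, c in self.counts.items():
            key = tuple(cell[i] for i in idx)
            out[key] = out.get(key, 0) + c
        return out


def entropy(counts: ContingencyCounts, subset: Sequence[Hashable]) -> float:
    """Plug-in Shannon entropy (bits) of the marginal over ``subset``.

    0 log 0 is treated as 0; the result is always >= 0.
    """
    if counts.total == 0:
        raise DegenerateInputError("entropy undefined for zero total count")
    marg = counts.marginal(subset)
    p = np.array([c for c in marg.values() if c > 0], dtype=float)
    p /= counts.total
    return float(-(p * np.log2(p)).sum()) if p.size else 0.0


def mutual_information(
    counts: ContingencyCounts,
    lhs: Sequence[Hashable],
    rhs: Sequence[Hashable],
) -> float:
    """I(lhs; rhs) = H(rhs) - H(rhs | lhs), in bits, clipped at 0."""
    if set(lhs) & set(rhs):
        raise InvalidArgumentError("lhs and rhs must be disjoint")
    h_rhs = entropy(counts, rhs)
    h_lhs = entropy(counts, lhs)
    h_joint = entropy(counts, list(lhs) + list(rhs))
    # plug-in MI is mathematically >= 0; anything below is roundoff
    return max(h_rhs - (h_joint - h_lhs), 0.0)


def two_way_ig(
    counts: ContingencyCounts, x: Hashable, y: Hashable, z: Hashable
) -> float:
    """IG(X;Y;Z) = I(X,Y;Z) - I(X;Z) - I(Y;Z) (bits, sign preserved)."""
    if len({x, y, z}) != 3:
        raise InvalidArgumentError("x, y, z must be distinct")
    return (
        mutual_information(counts, [x, y], [z])
        - mutual_information(counts, [x], [z])
        - mutual_information(counts, [y], [z])
    )


def three_way_ig(
    counts: ContingencyCounts,
    x: Hashable,
    y: Hashable,
    z: Hashable,
    n: Hashable,
) -> float:
    """Three-way interaction gain of (X, Y, Z) with outcome N.

    Subtracts all embedded two-way gains and main effects from the joint
    mutual information I(X,Y,Z;N).
    """
    if len({x, y, z, n}) != 4:
        raise InvalidArgumentError("variables must be distinct")
    return (
        mutual_information(counts, [x, y, z], [n])
        - two_way_ig(counts, x, y, n)
        - two_way_ig(counts, x, z, n)
        - two_way_ig(counts, y, z, n)
        - mutual_information(counts, [x], [n])
        - mutual_information(counts, [y], [n])
        - mutual_information(counts, [z], [n])
    )


@dataclass
class InteractionNetwork:
    """Main effects plus all pairwise and three-way interaction gains.

    The value layout mirrors a ViSEN-style analysis: per-feature mutual
    information with the phenotype, IG for every unordered feature pair, and
    IG for every unordered trio (empty when the dataset has < 3 features).
    All values in bits.
    """

    feature_ids: list[str]
    main_effects: dict[str, float]
    pairwise_ig: dict[tuple[str, str], float]
    threeway_ig: dict[tuple[str, str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        valid = set(self.feature_ids)
        for key in itertools.chain(self.pairwise_ig, self.threeway_ig):
            if not set(key) <= valid:
                raise InvalidArgumentError(f"unknown feature in key {key!r}")

    def to_tsv(self) -> str:
        lines = ["# main effects (MI with phenotype, bits)"]
        for f in self.feature_ids:
            lines.append(f"{f}\t{self.main_effects[f]:.10g}")
        lines.append("# pairwise IG (bits)")
        for (a, b), v in sorted(self.pairwise_ig.items()):
            lines.append(f"{a}\t{b}\t{v:.10g}")
        lines.append("# three-way IG (bits)")
        for (a, b, c), v in sorted(self.threeway_ig.items()):
            lines.append(f"{a}\t{b}\t{c}\t{v:.10g}")
        return "\n".join(lines) + "\n"

    def to_json(self) -> str:
        return json.dumps(
            {
                "feature_ids": self.feature_ids,
                "main_effects": self.main_effects,
                "pairwise_ig": {"|".join(k): v for k, v in self.pairwise_ig.items()},
                "threeway_ig": {"|".join(k): v for k, v in self.threeway_ig.items()},
            },
            indent=1,
        )


def interaction_network(dataset) -> InteractionNetwork:
    """Compute the full main-effect / IG2 / IG3 value network of a dataset.

    Deterministic given the dataset.  Raises
    :class:`~epiforest.errors.DegenerateInputError` for a constant phenotype
    (every information measure against it would be trivially zero).
    """
    if dataset.phenotype is None:
        raise InvalidArgumentError("dataset has no phenotype")
    y = dataset.phenotype
    if np.unique(y).size < 2:
        raise DegenerateInputError("phenotype is constant")
    feats = dataset.feature_ids
    cols = {f: dataset.genotypes[:, j] for j, f in enumerate(feats)}
    cols["__phenotype__"] = y
    counts = ContingencyCounts.from_columns(cols)
    ph = "__phenotype__"
    main = {f: mutual_information(counts, [f], [ph]) for f in feats}
    pairs = {
        (a, b): two_way_ig(counts, a, b, ph)
        for a, b in itertools.combinations(feats, 2)
    }
    trios = {
        (a, b, c): three_way_ig(counts, a, b, c, ph)
        for a, b, c in itertools.combinations(feats, 3)
    }
    return InteractionNetwork(
        feature_ids=list(feats),
        main_effects=main,
        pairwise_ig=pairs,
        threeway_ig=trios,
    )
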