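"""Independent oracles shared by the unit and acceptance tests.

Everything here recomputes quantities from first principles (explicit sums
over full joint tables, exhaustive enumeration, closed-form expectations)
and never calls the implementation paths it is used to check.
"""

from __future__ import annotations

import itertools

import numpy as np


def joint_probs(counts: dict[tuple, int]) -> dict[tuple, float]:
    total = sum(counts.values())
    return {cell: c / total for cell, c in counts.items() if c > 0}


def bf_entropy(counts: dict[tuple, int], idx: tuple[int, ...]) -> float:
    """Entropy of a marginal by direct summation over the joint table."""
    probs: dict[tuple, float] = {}
    for cell, p in joint_probs(counts).items():
        key = tuple(cell[i] for i in idx)
        probs[key] = probs.get(key, 0.0) + p
    return -sum(p * np.log2(p) for p in probs.values() if p > 0)


def bf_mutual_information(
    counts: dict[tuple, int], lhs: tuple[int, ...], rhs: tuple[int, ...]
) -> float:
    """I(lhs; rhs) by the direct sum p(a,b) log [p(a,b) / (p(a) p(b))]."""
    pa: dict[tuple, float] = {}
    pb: dict[tuple, float] = {}
    pab: dict[tuple, float] = {}
    for cell, p in joint_probs(counts).items():
        a = tuple(cell[i] for i in lhs)
        b = tuple(cell[i] for i in rhs)
        pa[a] = pa.get(a, 0.0) + p
        pb[b] = pb.get(b, 0.0) + p
        pab[(a, b)] = pab.get((a, b), 0.0) + p
    return sum(
        p * np.log2(p / (pa[a] * pb[b])) for (a, b), p in pab.items() if p > 0
    )


def bf_two_way_ig(counts: dict[tuple, int], x: int, y: int, z: int) -> float:
    return (
        bf_mutual_information(counts, (x, y), (z,))
        - bf_mutual_information(counts, (x,), (z,))
        - bf_mutual_information(counts, (y,), (z,))
    )


def bf_three_way_ig(counts: dict[tuple, int], x: int, y: int, z: int, n: int) -> float:
    return (
        bf_mutual_information(counts, (x, y, z), (n,))
        - bf_two_way_ig(counts, x, y, n)
        - bf_two_way_ig(counts, x, z, n)
        - bf_two_way_ig(counts, y, z, n)
        - bf_mutual_information(counts, (x,), (n,))
        - bf_mutual_information(counts, (y,), (n,))
        - bf_mutual_information(counts, (z,), (n,))
    )


def random_contingency(
    rng: np.random.Generator, n_vars: int, n_cats: int
) -> dict[tuple, int]:
    """A random joint count table over n_vars variables with n_cats levels,
    including structural zeros."""
    cells = list(itertools.product(range(n_cats), repeat=n_vars))
    counts = {}
    for cell in cells:
        if rng.random() < 0.25:
            continue  # leave some cells unobserved
        counts[cell] = int(rng.integers(0, 20))
    if sum(counts.values()) == 0:
        counts[cells[0]] = 1
    return counts


# -- spec example joints ---------------------------------------------------

XOR_COUNTS = {(0, 0, 0): 1, (0, 1, 1): 1, (1, 0, 1): 1, (1, 1, 0): 1}
PARITY_COUNTS = {
    (x, y, z, (x + y + z) % 2): 1
    for x, y, z in itertools.product((0, 1), repeat=3)
}


def xor_dataset(n: int, m: int, pair: tuple[int, int], rng, noise: float = 0.0):
    """Uniform genotypes with phenotype = XOR of two binarized columns."""
    from epiforest.datatypes import GenotypeMatrix

    G = rng.integers(0, 3, size=(n, m))
    y = ((G[:, pair[0]] > 0) ^ (G[:, pair[1]] > 0)).astype(np.int64)
    if noise > 0:
        flip = rng.random(n) < noise
        y = y ^ flip
    return GenotypeMatrix(genotypes=G, phenotype=y.astype(np.int64))
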