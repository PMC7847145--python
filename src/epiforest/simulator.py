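"""HIBACHI-style synthetic-data generator.

Genotype/phenotype datasets with planted non-additive (epistatic)
architecture are produced by evolving an expression tree that maps uniform
random genotypes in {0,1,2} to a raw numeric output, thresholding that
output at a quantile to obtain a binary case/control phenotype with an
exact case fraction, and selecting trees under a two-objective fitness:

1. the sum of two-way (or three-way) information gain between every feature
   pair (trio) and the derived phenotype — maximizing planted synergy;
2. the expression-tree length — encouraging multiple interaction
   combinations.

Selection is NSGA-II over the two maximized objectives.  The best individual
of the whole run (highest IG objective, ties to the longer tree, then to the
earlier discovery) defines the emitted dataset, and because the generating
tree is known exactly, downstream modules can derive ground-truth feature
importances from it.

Every replicate is fully reproducible from ``(config, replicate_seed)``:
independent child seed streams drive genotype sampling, the GP loop, and the
final phenotype tie-breaking, so a serialized (tree, seed, config) triple
re-creates the identical dataset.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .datatypes import GenotypeMatrix
from .errors import (
    DegenerateInputError,
    DegenerateModelError,
    InvalidArgumentError,
    SimulationFailureError,
)
from .trees import (
    ExpressionTree,
    evaluate_tree,
    random_tree,
    subtree_crossover,
    subtree_mutation,
)

logger = logging.getLogger(__name__)

_WORST_IG = -np.inf


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of one simulation experiment cell.

    ``case_fraction`` is the fraction of samples labelled 1 (the study uses
    0.25 and 0.50); ``ig_order`` selects two-way or three-way information
    gain as the interaction objective.  GP hyperparameters default to a
    population of 100 trees evolved for 50 generations with one-point
    subtree crossover (p=0.5) and uniform subtree mutation (p=0.2) under a
    depth cap of 4.  The depth cap controls how many features a program can
    entangle: it is calibrated so that emitted datasets concentrate their
    effect on two to three features, the regime the per-rank zero-effect
    structure of the reference experiments exhibits.
    """

    n_samples: int = 1000
    n_features: int = 5
    case_fraction: float = 0.5
    ig_order: int = 2
    gp_population_size: int = 100
    generations: int = 50
    crossover_prob: float = 0.5
    mutation_prob: float = 0.2
    max_depth: int = 4
    seed: int = 0
    ig_aggregate: str = "sum"  # "sum" over all pairs/trios, or "max"

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise InvalidArgumentError("n_samples must be >= 1")
        if self.n_features < 2:
            raise InvalidArgumentError("n_features must be >= 2")
        if not 0.0 < self.case_fraction < 1.0:
            raise InvalidArgumentError("case_fraction must be in (0, 1)")
        if self.ig_order not in (2, 3):
            raise InvalidArgumentError("ig_order must be 2 or 3")
        if self.ig_order == 3 and self.n_features < 3:
            raise InvalidArgumentError("ig_order 3 requires >= 3 features")
        for p_name in ("crossover_prob", "mutation_prob"):
            p = getattr(self, p_name)
            if not 0.0 <= p <= 1.0:
                raise InvalidArgumentError(f"{p_name} must be in [0, 1]")
        if self.gp_population_size < 2 or self.generations < 1:
            raise InvalidArgumentError("population and generations must be positive")
        if self.max_depth < 2:
            raise InvalidArgumentError("max_depth must be >= 2")
        if self.ig_aggregate not in ("sum", "max"):
            raise InvalidArgumentError("ig_aggregate must be 'sum' or 'max'")


@dataclass
class SimulatedReplicate:
    """One emitted dataset together with its generating model."""

    dataset: GenotypeMatrix
    tree: ExpressionTree
    config: SimulationConfig
    replicate_seed: int
    fitness_at_end: tuple[float, int]
    history: list[dict] = field(default_factory=list)


def _seed_streams(seed: int) -> tuple[np.random.Generator, ...]:
    """Independent generators for (genotypes, final binarization, GP)."""
    children = np.random.SeedSequence(seed).spawn(3)
    return tuple(np.random.default_rng(c) for c in children)


def replicate_seed_for(master_seed: int, index: int) -> int:
    """Stable per-replicate seed derived from the master seed."""
    state = np.random.SeedSequence([int(master_seed), int(index)]).generate_state(1)[0]
    return int(state % (2**31))


def sample_genotypes(
    config: SimulationConfig, rng: np.random.Generator
) -> GenotypeMatrix:
    """Draw n x m genotypes i.i.d. uniform over {0, 1, 2} (phenotype unset)."""
    g = rng.integers(0, 3, size=(config.n_samples, config.n_features))
    return GenotypeMatrix(genotypes=g)


def binarize_phenotype(
    raw: np.ndarray, case_fraction: float, rng: np.random.Generator
) -> np.ndarray:
    """Quantile-threshold a raw output into an exact-count binary phenotype.

    Samples with raw value strictly above the (1 - case_fraction) quantile
    are cases; ties at the threshold are broken uniformly at random so the
    realized case count equals ``round(n * case_fraction)`` exactly.  A
    constant raw vector admits no such phenotype and raises
    :class:`DegenerateModelError`.
    """
    raw = np.asarray(raw, dtype=np.float64)
    n = raw.size
    if n < 1:
        raise InvalidArgumentError("raw vector must be non-empty")
    if not 0.0 < case_fraction < 1.0:
        raise InvalidArgumentError("case_fraction must be in (0, 1)")
    raw = np.nan_to_num(raw, posinf=1e300, neginf=-1e300)
    if raw.min() == raw.max():
        raise DegenerateModelError("constant raw output")
    k = int(round(n * case_fraction))
    if k < 1 or k > n - 1:
        raise DegenerateInputError(
            f"case count round({n}*{case_fraction}) = {k} leaves a single class"
        )
    threshold = np.partition(raw, n - k)[n - k]
    phenotype = (raw > threshold).astype(np.int64)
    n_above = int(phenotype.sum())
    ties = np.flatnonzero(raw == threshold)
    need = k - n_above
    if need > 0:
        chosen = rng.choice(ties, size=need, replace=False)
        phenotype[chosen] = 1
    return phenotype


class IGFitnessEvaluator:
    """Fast two-objective fitness for candidate trees on fixed genotypes.

    The genotype matrix is fixed for the whole GP run, so its row
    configuration codes, unique rows, and genotype-only marginal entropies
    are precomputed once; evaluating a tree then costs one program run over
    the unique rows, one quantile binarization, and one ``bincount`` into a
    3^m x 2 contingency tensor from which all needed marginal entropies are
    contracted.  Falls back to per-combination tabulation when 3^m would be
    large (m > 8).
    """

    def __init__(self, genotypes: GenotypeMatrix, config: SimulationConfig):
        self.config = config
        self.m = genotypes.n_features
        self.n = genotypes.n_samples
        self.G = genotypes.genotypes
        self.unique_rows, self.inverse = np.unique(
            self.G, axis=0, return_inverse=True
        )
        self._tensor_path = 3**self.m <= 6561
        if self._tensor_path:
            powers = 3 ** np.arange(self.m)
            self._row_code2 = 2 * (self.G @ powers)
            self._n_cells = 2 * 3**self.m
            self._shape = (3,) * self.m + (2,)
            g_counts = np.bincount(self._row_code2 // 2, minlength=3**self.m)
            g_tensor = g_counts.reshape((3,) * self.m).astype(np.float64)
            self._h_geno = {}
            for r in (1, 2, 3):
                for subset in itertools.combinations(range(self.m), r):
                    axes = tuple(a for a in range(self.m) if a not in subset)
                    marg = g_tensor.sum(axis=axes) if axes else g_tensor
                    self._h_geno[subset] = self._entropy_from_counts(marg)
        self._pairs = list(itertools.combinations(range(self.m), 2))
        self._trios = list(itertools.combinations(range(self.m), 3))
        self._cache: dict[tuple, tuple[float, int]] = {}

    def _entropy_from_counts(self, counts: np.ndarray) -> float:
        c = counts[counts > 0]
        if c.size == 0:
            return 0.0
        return float(np.log2(self.n) - (c * np.log2(c)).sum() / self.n)

    def objective_for_phenotype(self, y: np.ndarray) -> float:
        """Aggregate IG2 (or IG3) of all feature pairs (trios) vs ``y``."""
        if self._tensor_path:
            tensor = np.bincount(self._row_code2 + y, minlength=self._n_cells)
            tensor = tensor.reshape(self._shape).astype(np.float64)
            h_joint = lambda subset: self._entropy_from_counts(
                tensor.sum(axis=tuple(a for a in range(self.m) if a not in subset))
            )
            hy = self._entropy_from_counts(tensor.sum(axis=tuple(range(self.m))))
            h_geno = self._h_geno
        else:  # per-combination tabulation for wide matrices
            h_cache: dict[tuple, float] = {}

            def h_joint(subset: tuple) -> float:
                code = y.copy()
                mult = 2
                for j in subset:
                    code = code + mult * self.G[:, j]
                    mult *= 3
                c = np.bincount(code)
                return self._entropy_from_counts(c.astype(np.float64))

            def h_geno_of(subset: tuple) -> float:
                if subset not in h_cache:
                    code = np.zeros(self.n, dtype=np.int64)
                    mult = 1
                    for j in subset:
                        code = code + mult * self.G[:, j]
                        mult *= 3
                    h_cache[subset] = self._entropy_from_counts(
                        np.bincount(code).astype(np.float64)
                    )
                return h_cache[subset]

            h_geno = _LazyDict(h_geno_of)
            hy = self._entropy_from_counts(
                np.bincount(y, minlength=2).astype(np.float64)
            )

        mi1 = {
            (i,): h_geno[(i,)] + hy - h_joint((i,)) for i in range(self.m)
        }
        ig2 = {}
        for i, j in self._pairs:
            mi_ij = h_geno[(i, j)] + hy - h_joint((i, j))
            ig2[(i, j)] = mi_ij - mi1[(i,)] - mi1[(j,)]
        if self.config.ig_order == 2:
            values = list(ig2.values())
        else:
            values = []
            for i, j, k in self._trios:
                mi_ijk = h_geno[(i, j, k)] + hy - h_joint((i, j, k))
                values.append(
                    mi_ijk
                    - ig2[(i, j)] - ig2[(i, k)] - ig2[(j, k)]
                    - mi1[(i,)] - mi1[(j,)] - mi1[(k,)]
                )
        if self.config.ig_aggregate == "sum":
            return float(np.sum(values))
        return float(np.max(values))

    def phenotype_for_tree(
        self, tree: ExpressionTree, rng: np.random.Generator
    ) -> np.ndarray:
        raw_u = evaluate_tree(tree, self.unique_rows)
        raw = raw_u[self.inverse]
        return binarize_phenotype(raw, self.config.case_fraction, rng)

    def __call__(
        self, tree: ExpressionTree, rng: np.random.Generator
    ) -> tuple[float, int]:
        """(ig_objective, tree_size); degenerate trees get the worst IG."""
        sig = tree.signature()
        cached = self._cache.get(sig)
        if cached is not None:
            return cached
        try:
            y = self.phenotype_for_tree(tree, rng)
            fit = (self.objective_for_phenotype(y), tree.size)
        except DegenerateModelError:
            fit = (_WORST_IG, tree.size)
        self._cache[sig] = fit
        return fit


class _LazyDict:
    def __init__(self, fn):
        self._fn = fn

    def __getitem__(self, key):
        return self._fn(key)


# -- NSGA-II selection over (ig_objective, tree_size), both maximized ------


def _nondominated_fronts(F: np.ndarray) -> list[np.ndarray]:
    ge = (F[:, None, :] >= F[None, :, :]).all(axis=2)
    gt = (F[:, None, :] > F[None, :, :]).any(axis=2)
    dominates = ge & gt  # dominates[i, j]: i dominates j
    n_dom = dominates.sum(axis=0)  # times each j is dominated
    fronts = []
    remaining = np.ones(len(F), dtype=bool)
    while remaining.any():
        front = np.flatnonzero(remaining & (n_dom == 0))
        if front.size == 0:  # numerical safety: should not happen
            front = np.flatnonzero(remaining)
        fronts.append(front)
        remaining[front] = False
        n_dom = n_dom - dominates[front].sum(axis=0)
    return fronts


def _crowding_distance(F: np.ndarray) -> np.ndarray:
    n, k = F.shape
    dist = np.zeros(n)
    for obj in range(k):
        order = np.argsort(F[:, obj], kind="stable")
        span = F[order[-1], obj] - F[order[0], obj]
        dist[order[0]] = dist[order[-1]] = np.inf
        if span > 0 and n > 2:
            gaps = (F[order[2:], obj] - F[order[:-2], obj]) / span
            dist[order[1:-1]] += gaps
    return dist


def _nsga2_select(fits: list[tuple[float, int]], mu: int) -> list[int]:
    """Indices of the mu survivors by (front rank, crowding distance)."""
    F = np.array([(f[0] if np.isfinite(f[0]) else -1e18, f[1]) for f in fits])
    chosen: list[int] = []
    for front in _nondominated_fronts(F):
        if len(chosen) + front.size <= mu:
            chosen.extend(front.tolist())
        else:
            crowd = _crowding_distance(F[front])
            order = np.argsort(-crowd, kind="stable")
            chosen.extend(front[order][: mu - len(chosen)].tolist())
            break
    return chosen


def evolve_dataset(config: SimulationConfig, seed: int | None = None) -> SimulatedReplicate:
    """Run the full GP loop and emit the best individual's dataset.

    Deterministic given (config, seed); ``seed`` defaults to ``config.seed``.
    Raises :class:`SimulationFailureError` if every individual ever seen was
    degenerate (constant raw output).
    """
    rep_seed = int(config.seed if seed is None else seed)
    rng_geno, rng_bin, rng_gp = _seed_streams(rep_seed)
    genotypes = sample_genotypes(config, rng_geno)
    evaluator = IGFitnessEvaluator(genotypes, config)
    mu = config.gp_population_size

    pop = [
        random_tree(rng_gp, config.n_features, min_depth=2, max_depth=4)
        for _ in range(mu)
    ]
    fits = [evaluator(t, rng_gp) for t in pop]

    best_tree, best_fit = None, (_WORST_IG, -1)
    history: list[dict] = []

    def note_best() -> None:
        nonlocal best_tree, best_fit
        for t, f in zip(pop, fits):
            if f[0] > best_fit[0] or (f[0] == best_fit[0] and f[1] > best_fit[1]):
                best_tree, best_fit = t, f

    def log_gen(gen: int) -> None:
        finite = [f[0] for f in fits if np.isfinite(f[0])]
        history.append(
            {
                "generation": gen,
                "best_ig": best_fit[0],
                "mean_ig": float(np.mean(finite)) if finite else _WORST_IG,
                "n_degenerate": sum(1 for f in fits if not np.isfinite(f[0])),
            }
        )

    note_best()
    log_gen(0)

    for gen in range(1, config.generations + 1):
        # binary tournament on (front rank, crowding), then crossover+mutation
        F = np.array([(f[0] if np.isfinite(f[0]) else -1e18, f[1]) for f in fits])
        fronts = _nondominated_fronts(F)
        rank = np.empty(len(pop), dtype=int)
        crowd = np.empty(len(pop))
        for r, front in enumerate(fronts):
            rank[front] = r
            crowd[front] = _crowding_distance(F[front])

        def pick() -> ExpressionTree:
            a, b = rng_gp.integers(len(pop), size=2)
            if rank[a] < rank[b] or (rank[a] == rank[b] and crowd[a] > crowd[b]):
                return pop[a]
            return pop[b]

        offspring: list[ExpressionTree] = []
        while len(offspring) < mu:
            p1, p2 = pick(), pick()
            if rng_gp.random() < config.crossover_prob:
                c1, c2 = subtree_crossover(p1, p2, rng_gp, config.max_depth)
            else:
                c1, c2 = ExpressionTree(p1.nodes), ExpressionTree(p2.nodes)
            for child in (c1, c2):
                if rng_gp.random() < config.mutation_prob:
                    child = subtree_mutation(
                        child, rng_gp, config.n_features, config.max_depth
                    )
                offspring.append(child)
        offspring = offspring[:mu]
        off_fits = [evaluator(t, rng_gp) for t in offspring]

        pool = pop + offspring
        pool_fits = fits + off_fits
        keep = _nsga2_select(pool_fits, mu)
        pop = [pool[i] for i in keep]
        fits = [pool_fits[i] for i in keep]
        note_best()
        log_gen(gen)

    if best_tree is None or not np.isfinite(best_fit[0]):
        raise SimulationFailureError(
            f"all individuals degenerate after {config.generations} generations "
            f"(seed {rep_seed})"
        )

    phenotype = evaluator.phenotype_for_tree(best_tree, rng_bin)
    dataset = GenotypeMatrix(
        genotypes=genotypes.genotypes,
        phenotype=phenotype,
        feature_ids=list(genotypes.feature_ids),
        sample_ids=list(genotypes.sample_ids),
    )
    final_ig = evaluator.objective_for_phenotype(phenotype)
    return SimulatedReplicate(
        dataset=dataset,
        tree=best_tree,
        config=config,
        replicate_seed=rep_seed,
        fitness_at_end=(final_ig, best_tree.size),
        history=history,
    )


def generate_replicates(
    config: SimulationConfig, n_replicates: int
) -> list[SimulatedReplicate]:
    """Independent replicates with per-replicate seeds derived from
    ``config.seed``; failed replicates are skipped with a logged count."""
    if n_replicates < 1:
        raise InvalidArgumentError("n_replicates must be >= 1")
    out: list[SimulatedReplicate] = []
    failures = 0
    for i in range(n_replicates):
        rs = replicate_seed_for(config.seed, i)
        try:
            out.append(evolve_dataset(replace(config, seed=rs)))
        except SimulationFailureError as exc:
            failures += 1
            logger.warning("replicate %d failed: %s", i, exc)
        if (i + 1) % 10 == 0 or i + 1 == n_replicates:
            logger.info("simulated %d/%d replicates", i + 1, n_replicates)
    if failures:
        logger.warning("%d/%d replicates failed", failures, n_replicates)
    return out
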