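"""Seeded end-to-end driver: simulate -> ground truth -> metrics -> tables.

Artifacts are laid out as::

    out_dir/
      config.json           # resolved configuration + hash
      datasets/rep_XXX.tsv  # simulated genotype/phenotype tables
      trees/rep_XXX.json    # generating expression trees
      truth/rep_XXX.json    # sensitivity-analysis ground-truth profiles
      profiles/rep_XXX.<metric>.json
      tables/               # rank-success, zero-effect, detection TSVs

The run is resumable per replicate: artifacts that already exist with the
current configuration hash are reused, anything missing is recomputed.
Evaluation refuses to mix profiles from differing configuration hashes.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import evaluation, importance, io
from .errors import InvalidArgumentError, SimulationFailureError
from .infotheory import interaction_network
from .sensitivity import sensitivity_scores
from .simulator import SimulationConfig, evolve_dataset, replicate_seed_for

logger = logging.getLogger(__name__)

VALID_METRICS = ("PFI", "BIC", "SHAP", "PFI2", "PFI3")


@dataclass
class PipelineConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    n_replicates: int = 100
    metrics: tuple[str, ...] = ("PFI", "BIC", "SHAP")
    pfi_repeats: int | None = None  # None -> m - 1
    folds: int = 10
    sensitivity_reps: int = 100
    compute_networks: bool = False
    out_dir: str = "results"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        for m in self.metrics:
            if m not in VALID_METRICS:
                raise InvalidArgumentError(f"unknown metric {m!r}")
        if self.n_replicates < 1:
            raise InvalidArgumentError("n_replicates must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = SimulationConfig(**raw.pop("simulation", {}))
        raw.update({k: v for k, v in overrides.items() if v is not None})
        if "metrics" in raw:
            raw["metrics"] = tuple(raw["metrics"])
        return cls(simulation=sim, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["metrics"] = list(d["metrics"])
        return d


def _compute_profile(metric: str, dataset, seed: int, config: PipelineConfig):
    X = dataset.genotypes
    y = dataset.phenotype
    ids = dataset.feature_ids
    if metric in ("PFI", "PFI2", "PFI3"):
        size = {"PFI": 1, "PFI2": 2, "PFI3": 3}[metric]
        return importance.permutation_feature_importance(
            X, y, feature_ids=ids, tuple_size=size,
            n_repeats=config.pfi_repeats, rng=seed,
        )
    fit = importance.cv_balanced_accuracy(X, y, folds=config.folds, rng=seed)
    if metric == "BIC":
        return importance.builtin_gini_importance(fit, feature_ids=ids)
    return importance.shap_mean_importance(fit, X, feature_ids=ids)


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the full benchmark for one experimental cell.

    Returns the output directory.  Per-replicate simulation failures are
    logged and summarized; the run fails only if every replicate does.
    """
    out = Path(config.out_dir)
    chash = io.config_hash(config.to_dict())
    for sub in ("datasets", "trees", "truth", "profiles", "tables"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(
        json.dumps({"config": config.to_dict(), "config_hash": chash}, indent=1) + "\n"
    )

    sim = config.simulation
    truths, profiles_by_metric, failures = [], {m: [] for m in config.metrics}, 0
    networks = []
    for i in range(config.n_replicates):
        rep_seed = replicate_seed_for(config.seed, i)
        tag = f"rep_{i:03d}"
        ds_path = out / "datasets" / f"{tag}.tsv"
        tree_path = out / "trees" / f"{tag}.json"
        truth_path = out / "truth" / f"{tag}.json"

        try:
            if ds_path.exists() and tree_path.exists():
                dataset = io.read_genotype_table(ds_path)
                tree = io.read_tree(tree_path)
            else:
                rep = evolve_dataset(
                    dataclasses.replace(sim, seed=rep_seed)
                )
                dataset, tree = rep.dataset, rep.tree
                io.write_genotype_table(dataset, ds_path)
                io.write_tree(tree, tree_path)
        except SimulationFailureError as exc:
            failures += 1
            logger.warning("%s: %s", tag, exc)
            continue

        if truth_path.exists():
            truth, h = io.read_profile(truth_path)
            if h != chash:
                raise InvalidArgumentError(
                    f"{truth_path} was produced under config hash {h}, "
                    f"current is {chash}"
                )
        else:
            truth = sensitivity_scores(
                tree, dataset, n_reps=config.sensitivity_reps, rng=rep_seed
            )
            io.write_profile(truth, truth_path, config_hash_=chash)
        truths.append(truth)

        for metric in config.metrics:
            p_path = out / "profiles" / f"{tag}.{metric}.json"
            if p_path.exists():
                prof, h = io.read_profile(p_path)
                if h != chash:
                    raise InvalidArgumentError(
                        f"{p_path}: config hash mismatch ({h} != {chash})"
                    )
            else:
                prof = _compute_profile(metric, dataset, rep_seed, config)
                io.write_profile(prof, p_path, config_hash_=chash)
            profiles_by_metric[metric].append(prof)

        if config.compute_networks:
            networks.append(interaction_network(dataset))
        if (i + 1) % 10 == 0 or i + 1 == config.n_replicates:
            logger.info("replicate %d/%d done", i + 1, config.n_replicates)

    if not truths:
        raise SimulationFailureError("all replicates failed")
    if failures:
        logger.warning("%d/%d replicates failed", failures, config.n_replicates)

    cell = {
        "n_samples": sim.n_samples,
        "ig_order": sim.ig_order,
        "case_fraction": sim.case_fraction,
    }
    tables = out / "tables"
    single_metrics = {
        m: profiles_by_metric[m]
        for m in config.metrics
        if m in evaluation.RANK_METRICS
    }
    if single_metrics:
        rst = evaluation.rank_success_table(single_metrics, truths, cell=cell)
        rst.to_frame().to_csv(tables / "rank_success.tsv", sep="\t", index=False)
        rst.wide().to_csv(tables / "rank_success_wide.tsv", sep="\t")
        evaluation.effect_size_quantiles(
            {**single_metrics, "sensitivity": truths}, cell=cell
        ).to_csv(tables / "effect_size_quantiles.tsv", sep="\t", index=False)
    zet = evaluation.zero_effect_table(truths, cell=cell)
    zet.to_frame().to_csv(tables / "zero_effect.tsv", sep="\t", index=False)

    if config.compute_networks and networks:
        order = sim.ig_order
        rows = []
        if "PFI" in config.metrics:
            det = evaluation.interaction_detection_success(
                profiles_by_metric["PFI"], networks, "single_top_k", order, cell=cell
            )
            rows.append({"mode": det.mode, "success_pct": det.success_pct, **cell})
        multi = f"PFI{order}"
        if multi in config.metrics:
            det = evaluation.interaction_detection_success(
                profiles_by_metric[multi], networks, "multi_pfi", order, cell=cell
            )
            rows.append({"mode": det.mode, "success_pct": det.success_pct, **cell})
        if rows:
            import pandas as pd

            pd.DataFrame(rows).to_csv(tables / "detection.tsv", sep="\t", index=False)

    summary = {
        "config_hash": chash,
        "n_replicates_done": len(truths),
        "n_failures": failures,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=1) + "\n")
    return out
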