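"""Readers and writers for the pipeline's plain-text artifact formats.

Genotype datasets travel as TSV/CSV with a ``sample_id`` column, one column
per feature, and a ``phenotype`` column; expression trees as versioned
prefix-notation JSON; importance profiles as ``unit / score / rank`` TSV
plus JSON with metadata.  Every writer embeds the configuration hash and
seed so the evaluation stage can refuse to mix artifacts from different
runs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import GenotypeMatrix, ImportanceProfile
from .errors import ParseError
from .sensitivity import TrueImportanceProfile, rank_features
from .simulator import SimulationConfig
from .trees import ExpressionTree


def config_hash(config) -> str:
    """Stable short hash of a (dataclass or dict) configuration."""
    payload = asdict(config) if not isinstance(config, dict) else config
    blob = json.dumps(payload, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def read_genotype_table(path: str | Path, dialect: str | None = None) -> GenotypeMatrix:
    """Parse a SNP-matrix style TSV/CSV into a :class:`GenotypeMatrix`.

    The dialect is inferred from the extension unless given ("tsv"/"csv").
    Parse failures name the offending row (1-based, excluding header) and
    column.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    sep = {"tsv": "\t", "csv": ","}.get(
        dialect or ("csv" if path.suffix.lower() == ".csv" else "tsv")
    )
    try:
        df = pd.read_csv(path, sep=sep)
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if "sample_id" not in df.columns:
        raise ParseError(f"{path}: missing 'sample_id' column")
    if "phenotype" not in df.columns:
        raise ParseError(f"{path}: missing 'phenotype' column")
    feats = [c for c in df.columns if c not in ("sample_id", "phenotype")]
    if len(feats) < 2:
        raise ParseError(f"{path}: need at least 2 feature columns")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ParseError(f"{path}: duplicate sample_id {dup!r}")
    for col in feats + ["phenotype"]:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals != vals.astype("Int64").astype(float))
        allowed = (0, 1, 2) if col != "phenotype" else (0, 1)
        bad |= ~vals.isin(allowed)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0]) + 1
            raise ParseError(
                f"{path}: invalid value {df[col].iloc[row - 1]!r} in column "
                f"{col!r} at data row {row} (allowed: {allowed})"
            )
    return GenotypeMatrix.from_frame(df)


def write_genotype_table(dataset: GenotypeMatrix, path: str | Path) -> None:
    sep = "," if str(path).lower().endswith(".csv") else "\t"
    dataset.to_frame().to_csv(path, sep=sep, index=False)


def write_tree(tree: ExpressionTree, path: str | Path) -> None:
    Path(path).write_text(tree.to_json() + "\n")


def read_tree(path: str | Path) -> ExpressionTree:
    return ExpressionTree.from_json(Path(path).read_text())


def _profile_payload(profile) -> dict:
    if isinstance(profile, TrueImportanceProfile):
        units = profile.feature_ids
        metric = "sensitivity"
        extra = {"n_permutation_reps": profile.n_permutation_reps}
    else:
        units = [
            u if isinstance(u, str) else list(u) for u in profile.units
        ]
        metric = profile.metric
        extra = {
            "raw_scores": profile.raw_scores.tolist(),
            "model_descriptor": profile.model_descriptor,
        }
    return {
        "metric": metric,
        "units": list(units),
        "scores": np.asarray(profile.scores).tolist(),
        "all_zero": bool(profile.all_zero),
        "seed": None if profile.seed is None else int(profile.seed),
        "metadata": dict(profile.metadata),
        **extra,
    }


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj).__name__}")


def write_profile(profile, path: str | Path, config_hash_: str | None = None) -> None:
    """Profile as JSON (``.json``) or ``unit score rank`` TSV otherwise."""
    path = Path(path)
    payload = _profile_payload(profile)
    if config_hash_:
        payload["config_hash"] = config_hash_
    if path.suffix == ".json":
        path.write_text(json.dumps(payload, indent=1, default=_json_default) + "\n")
        return
    ranking = rank_features(profile)
    ids = payload["units"]
    rank_of = {
        (tuple(u) if isinstance(u, list) else u): r + 1
        for r, u in enumerate(
            [tuple(x) if isinstance(x, (list, tuple)) else x for x in ranking]
        )
    }
    lines = [f"# metric={payload['metric']}"
             + (f" config_hash={config_hash_}" if config_hash_ else "")]
    lines.append("unit\tscore\trank")
    for u, s in zip(ids, payload["scores"]):
        key = tuple(u) if isinstance(u, list) else u
        label = "+".join(u) if isinstance(u, list) else u
        lines.append(f"{label}\t{s:.10g}\t{rank_of[key]}")
    path.write_text("\n".join(lines) + "\n")


def read_profile(path: str | Path):
    """Read a JSON profile back into its in-memory type."""
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if payload["metric"] == "sensitivity":
        return TrueImportanceProfile(
            feature_ids=list(payload["units"]),
            scores=np.array(payload["scores"]),
            n_permutation_reps=payload["n_permutation_reps"],
            seed=payload.get("seed"),
            all_zero=payload["all_zero"],
            metadata=payload.get("metadata", {}),
        ), payload.get("config_hash")
    units = [tuple(u) if isinstance(u, list) else u for u in payload["units"]]
    return ImportanceProfile(
        metric=payload["metric"],
        units=units,
        scores=np.array(payload["scores"]),
        raw_scores=np.array(payload.get("raw_scores", payload["scores"])),
        model_descriptor=payload.get("model_descriptor", ""),
        seed=payload.get("seed"),
        all_zero=payload["all_zero"],
        metadata=payload.get("metadata", {}),
    ), payload.get("config_hash")


def read_vcf_matrix(path: str | Path) -> pd.DataFrame:
    """Minimal VCF -> genotype-matrix import shim.

    Reads an uncompressed VCF with GT fields, codes genotypes as the count
    of alternate alleles (0/1/2), and returns a frame with one row per
    sample ready for a phenotype column to be attached.  Not a full VCF
    parser: multi-allelic records and missing genotypes are rejected.
    """
    path = Path(path)
    variant_ids: list[str] = []
    rows: list[list[int]] = []
    samples: list[str] | None = None
    for line_no, line in enumerate(path.read_text().splitlines(), 1):
        if line.startswith("##") or not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if line.startswith("#CHROM"):
            samples = parts[9:]
            continue
        if samples is None:
            raise ParseError(f"{path}:{line_no}: data before #CHROM header")
        if "," in parts[4]:
            raise ParseError(f"{path}:{line_no}: multi-allelic record")
        vid = parts[2] if parts[2] != "." else f"{parts[0]}:{parts[1]}"
        fmt = parts[8].split(":")
        try:
            gt_idx = fmt.index("GT")
        except ValueError:
            raise ParseError(f"{path}:{line_no}: no GT field") from None
        row = []
        for s in parts[9:]:
            gt = s.split(":")[gt_idx].replace("|", "/")
            alleles = gt.split("/")
            if "." in alleles:
                raise ParseError(f"{path}:{line_no}: missing genotype")
            row.append(sum(int(a) for a in alleles))
        variant_ids.append(vid)
        rows.append(row)
    if samples is None:
        raise ParseError(f"{path}: no #CHROM header")
    mat = np.array(rows).T  # samples x variants
    df = pd.DataFrame(mat, columns=variant_ids)
    df.insert(0, "sample_id", samples)
    return df


def write_simulation_config(config: SimulationConfig, path: str | Path) -> None:
    Path(path).write_text(json.dumps(asdict(config), indent=1) + "\n")
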