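"""On-disk formats: TSV readers/writers, corpus manifests, pipeline runs.

Everything is plain text: TSV with header rows and "NA" for missing,
FASTA for cDNA, YAML manifests, JSON summaries. Labels are 0/1
(1 = essential). A corpus directory is a manifest plus per-species
feature and label tables, a species metadata table, and a divergence-time
matrix; writers and readers round-trip losslessly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

from .datatypes import DivergenceMatrix, FeatureSchema, SpeciesDataset, SpeciesMeta

__all__ = [
    "read_labels", "write_labels",
    "read_feature_table", "write_feature_table",
    "read_divergence", "write_divergence",
    "read_edge_list", "read_expression", "read_domain_hits", "read_fasta",
    "read_metadata", "write_metadata",
    "write_corpus", "read_corpus",
    "run_pipeline",
]

log = logging.getLogger(__name__)

MANIFEST_SCHEMA_VERSION = 1
_NA = "NA"


def _read_tsv(path: str | Path, **kw) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", na_values=[_NA], keep_default_na=False,
        float_precision="round_trip", **kw,
    )


def _write_tsv(frame: pd.DataFrame, path: str | Path, index: bool) -> None:
    frame.to_csv(path, sep="\t", na_rep=_NA, index=index)


def read_labels(path: str | Path) -> pd.Series:
    """Labels TSV (gene_id, essential) as an int series indexed by gene."""
    df = _read_tsv(path, dtype={"gene_id": str})
    if list(df.columns[:2]) != ["gene_id", "essential"]:
        raise ValueError(f"{path}: expected columns gene_id, essential, got {list(df.columns)}")
    if df["gene_id"].duplicated().any():
        dup = df["gene_id"][df["gene_id"].duplicated()].iloc[0]
        raise ValueError(f"{path}: duplicate gene_id {dup!r}")
    bad = df.index[~df["essential"].isin([0, 1])]
    if len(bad):
        row = int(bad[0])
        raise ValueError(
            f"{path}, line {row + 2}: label {df['essential'].iloc[row]!r} outside {{0,1}}"
        )
    return pd.Series(
        df["essential"].to_numpy(dtype=int), index=pd.Index(df["gene_id"], name="gene_id")
    )


def write_labels(labels: pd.Series, path: str | Path) -> None:
    out = pd.DataFrame({"gene_id": labels.index, "essential": labels.to_numpy(dtype=int)})
    _write_tsv(out, path, index=False)


def read_feature_table(path: str | Path, schema: FeatureSchema) -> pd.DataFrame:
    """Feature TSV (gene_id, species_id, features); categorical as strings."""
    dtype: dict = {"gene_id": str, "species_id": str}
    dtype.update({c: str for c in schema.categorical})
    df = _read_tsv(path, dtype=dtype)
    if "gene_id" not in df.columns:
        raise ValueError(f"{path}: missing gene_id column")
    df = df.set_index("gene_id")
    missing = set(schema.columns) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing feature columns {sorted(missing)}")
    for c in schema.continuous:
        df[c] = pd.to_numeric(df[c], errors="raise")
    return df


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    _write_tsv(table, path, index=True)


def read_divergence(path: str | Path) -> DivergenceMatrix:
    df = _read_tsv(path, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return DivergenceMatrix.from_frame(df)


def write_divergence(divergence: DivergenceMatrix, path: str | Path) -> None:
    _write_tsv(divergence.to_frame(), path, index=True)


def read_edge_list(path: str | Path) -> list[tuple[str, str]]:
    """Two-column TSV of node pairs (STRING-style export)."""
    df = _read_tsv(path, dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: edge list needs two columns")
    return list(df.iloc[:, :2].itertuples(index=False, name=None))


def read_expression(path: str | Path) -> pd.DataFrame:
    """Genes x conditions expression matrix, gene_id in the first column."""
    df = _read_tsv(path, dtype={0: str})
    return df.set_index(df.columns[0]).astype(float)


def read_domain_hits(path: str | Path):
    """Domain-hit TSV (gene_id, domain_id, bit_score, domain_length)."""
    from .features import DomainHit

    df = _read_tsv(path, dtype={"gene_id": str, "domain_id": str})
    needed = {"gene_id", "domain_id", "bit_score", "domain_length"}
    if not needed <= set(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(needed)}")
    hits: dict[str, list[DomainHit]] = {}
    for row in df.itertuples(index=False):
        hits.setdefault(row.gene_id, []).append(
            DomainHit(row.gene_id, row.domain_id, float(row.bit_score), int(row.domain_length))
        )
    return hits


def read_fasta(path: str | Path) -> dict[str, str]:
    """cDNA FASTA as id -> sequence; each length must be divisible by 3."""
    seqs = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        s = str(rec.seq).upper()
        if len(s) % 3:
            raise ValueError(f"{path}: sequence {rec.id} length {len(s)} not divisible by 3")
        seqs[rec.id] = s
    return seqs


_META_COLS = ["species_id", "quality_tier", "growth_condition", "gram", "oxygen", "shape"]


def read_metadata(path: str | Path) -> dict[str, SpeciesMeta]:
    df = _read_tsv(path, dtype=str)
    missing = set(_META_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing metadata columns {sorted(missing)}")
    out = {}
    for row in df.itertuples(index=False):
        if row.species_id in out:
            raise ValueError(f"{path}: duplicate species {row.species_id}")
        out[row.species_id] = SpeciesMeta(
            species_id=row.species_id, quality_tier=row.quality_tier,
            growth_condition=row.growth_condition, gram=row.gram,
            oxygen=row.oxygen, shape=row.shape,
        )
    return out


def write_metadata(metadata: Mapping[str, SpeciesMeta], path: str | Path) -> None:
    rows = [
        {c: getattr(m, c if c != "species_id" else "species_id") for c in _META_COLS}
        for m in metadata.values()
    ]
    _write_tsv(pd.DataFrame(rows, columns=_META_COLS), path, index=False)


def write_corpus(
    datasets: Mapping[str, SpeciesDataset],
    divergence: DivergenceMatrix,
    outdir: str | Path,
) -> Path:
    """Write a corpus directory and return the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    schema = next(iter(datasets.values())).schema
    species_entries = []
    for sp, ds in datasets.items():
        fpath = outdir / f"{sp}.features.tsv"
        lpath = outdir / f"{sp}.labels.tsv"
        write_feature_table(ds.features, fpath)
        write_labels(ds.labels, lpath)
        species_entries.append({"id": sp, "features": fpath.name, "labels": lpath.name})
    write_divergence(divergence, outdir / "divergence.tsv")
    write_metadata({sp: ds.meta for sp, ds in datasets.items()}, outdir / "metadata.tsv")
    manifest = {
        "schema_version": MANIFEST_SCHEMA_VERSION,
        "feature_schema": {
            "continuous": list(schema.continuous),
            "categorical": list(schema.categorical),
        },
        "divergence": "divergence.tsv",
        "metadata": "metadata.tsv",
        "species": species_entries,
    }
    mpath = outdir / "manifest.yaml"
    mpath.write_text(yaml.safe_dump(manifest, sort_keys=False))
    return mpath


def read_corpus(
    manifest_path: str | Path,
) -> tuple[dict[str, SpeciesDataset], DivergenceMatrix, dict[str, SpeciesMeta]]:
    """Load and validate a corpus directory from its manifest."""
    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    manifest = yaml.safe_load(manifest_path.read_text())
    if manifest.get("schema_version") != MANIFEST_SCHEMA_VERSION:
        raise ValueError(f"unsupported manifest schema version {manifest.get('schema_version')!r}")
    schema = FeatureSchema(
        continuous=tuple(manifest["feature_schema"]["continuous"]),
        categorical=tuple(manifest["feature_schema"]["categorical"]),
    )
    for key in ("divergence", "metadata"):
        if not (root / manifest[key]).exists():
            raise FileNotFoundError(f"manifest references missing file {root / manifest[key]}")
    divergence = read_divergence(root / manifest["divergence"])
    metadata = read_metadata(root / manifest["metadata"])
    datasets: dict[str, SpeciesDataset] = {}
    for entry in manifest["species"]:
        sp = entry["id"]
        if sp in datasets:
            raise ValueError(f"duplicate species {sp} in manifest")
        for key in ("features", "labels"):
            if not (root / entry[key]).exists():
                raise FileNotFoundError(f"manifest references missing file {root / entry[key]}")
        features = read_feature_table(root / entry["features"], schema)
        labels = read_labels(root / entry["labels"])
        stray = labels.index.difference(features.index)
        if len(stray):
            raise ValueError(f"{sp}: labels for genes absent from features: {list(stray[:5])}")
        datasets[sp] = SpeciesDataset(
            species_id=sp, features=features, labels=labels, schema=schema,
            meta=metadata.get(sp, SpeciesMeta(species_id=sp)),
        )
    missing_div = set(datasets) - set(divergence.species)
    if missing_div:
        raise ValueError(f"divergence matrix lacks species {sorted(missing_div)}")
    return datasets, divergence, metadata


def _config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]


def run_pipeline(config_path: str | Path) -> Path:
    """Run the configured experiment stages on a corpus; return outdir.

    The config names a corpus (a manifest, or a generator block to
    simulate one), the stages to run, and a seed. Outputs are
    deterministic given (config, seed); wall-clock details go to
    run.log only. Any stage failure is isolated, recorded, and reflected
    in a nonzero exit from the CLI.
    """
    from . import __version__
    from .evaluation import column_dispersion, cross_species_matrix, divergence_correlation
    from .experiments import (
        group_comparison, hasts_lasts_split, incomplete_training_curve,
        random_integration_pvalue, rule_based_select,
    )
    from .simulate import SimConfig, simulate_multispecies

    config_path = Path(config_path)
    config = yaml.safe_load(config_path.read_text())
    outdir = Path(config.get("outdir", config_path.parent / "results"))
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    valid_stages = ["matrix", "dispersion", "correlate", "incomplete", "groups", "null", "select"]
    stages = config.get("experiments", ["matrix", "dispersion", "correlate"])
    unknown = set(stages) - set(valid_stages)
    if unknown:
        raise ValueError(f"unknown experiment name(s) {sorted(unknown)}; valid: {valid_stages}")

    corpus_cfg = config.get("corpus", {})
    if "manifest" in corpus_cfg:
        datasets, divergence, metadata = read_corpus(corpus_cfg["manifest"])
    else:
        sim = SimConfig(**{**corpus_cfg.get("simulate", {}), "seed": seed})
        datasets, divergence = simulate_multispecies(sim)
        metadata = {sp: ds.meta for sp, ds in datasets.items()}
        write_corpus(datasets, divergence, outdir / "corpus")

    loglines = [f"esstrans {__version__} | config_hash={_config_hash(config)} | seed={seed}"]
    failures: list[str] = []
    matrix = None
    for stage in stages:
        t0 = time.perf_counter()
        try:
            if stage == "matrix":
                matrix = cross_species_matrix(datasets)
                _write_tsv(matrix.to_frame(), outdir / "auc_matrix.tsv", index=True)
            elif stage == "dispersion":
                matrix = matrix or cross_species_matrix(datasets)
                column_dispersion(matrix).to_csv(outdir / "dispersion.tsv", sep="\t")
            elif stage == "correlate":
                matrix = matrix or cross_species_matrix(datasets)
                res = divergence_correlation(matrix, divergence, mode="pooled")
                (outdir / "correlation.json").write_text(json.dumps(res.to_dict(), indent=1))
            elif stage == "incomplete":
                opts = config.get("incomplete", {})
                sp = opts.get("species", sorted(datasets)[0])
                curve = incomplete_training_curve(
                    datasets[sp],
                    fractions=opts.get("fractions"),
                    reps=int(opts.get("reps", 100)),
                    seed=seed,
                )
                curve.to_frame().to_csv(outdir / f"incomplete_{sp}.tsv", sep="\t", index=False)
            elif stage == "groups":
                opts = config.get("groups", {})
                test_sp = opts.get("test_species", sorted(datasets)[0])
                matrix = matrix or cross_species_matrix(datasets)
                col = matrix.to_frame()[test_sp].drop(index=test_sp).dropna()
                hasts, lasts, _ = hasts_lasts_split(col.to_dict())
                res = group_comparison(datasets, hasts, lasts, test_sp, k=int(opts.get("k", 4)))
                res.to_frame().to_csv(outdir / f"groups_{test_sp}.tsv", sep="\t", index=False)
            elif stage == "null":
                opts = config.get("null", {})
                test_sp = opts.get("test_species", sorted(datasets)[0])
                rule_set = opts.get("rule_set")
                if rule_set is None:
                    rule_set, _ = rule_based_select(metadata, divergence, test_sp, n=int(opts.get("k", 4)))
                res = random_integration_pvalue(
                    datasets, test_sp, rule_set,
                    k=int(opts.get("k", 4)),
                    n_sims=int(opts.get("n_sims", 10000)),
                    mode=opts.get("mode", "sampled"),
                    seed=seed,
                )
                payload = res.to_dict() | {"rule_set": list(rule_set), "test_species": test_sp}
                (outdir / f"null_{test_sp}.json").write_text(json.dumps(payload, indent=1))
            elif stage == "select":
                opts = config.get("select", {})
                target = opts.get("target", sorted(datasets)[0])
                top, ranking = rule_based_select(metadata, divergence, target, n=int(opts.get("n", 4)))
                ranking.to_csv(outdir / f"select_{target}.tsv", sep="\t", index=False)
        except Exception as e:  # noqa: BLE001 - isolate per-stage failures
            failures.append(f"{stage}: {e}")
            log.error("stage %s failed: %s", stage, e)
        loglines.append(f"stage={stage} runtime_s={time.perf_counter() - t0:.2f}")
    (outdir / "run.log").write_text("\n".join(loglines + [f"FAILED {f}" for f in failures]) + "\n")
    if failures:
        raise RuntimeError("; ".join(failures))
    return outdir
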