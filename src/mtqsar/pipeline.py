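"""End-to-end pipeline orchestration with a declarative config file.

A :class:`PipelineConfig` names the inputs (activities CSV, FASTA),
output directory, curation grid, suite configuration, ensemble cutoff
and seed. ``run_pipeline`` executes curate -> train -> evaluate -> sweep
and writes every artifact plus a manifest of content digests, so two runs
under the same config and seed are verifiably identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml
from Bio import SeqIO

from . import ensemble as ens
from .curation import curate_all, read_activity_table
from .errors import ConfigError
from .evaluation import evaluate_suite
from .modeling import SuiteConfig, build_suite


@dataclass
class PipelineConfig:
    """Declarative description of one pipeline run."""

    activities: str
    fasta: str
    out_dir: str
    seed: int = 0
    unit: str = "M"
    threshold_grid: list | None = None
    min_records: int = 40
    cutoff: int = ens.DEFAULT_CUTOFF
    batch_cap: int = ens.DEFAULT_BATCH_CAP
    suite: dict = field(default_factory=dict)  # SuiteConfig overrides

    @classmethod
    def from_mapping(cls, mapping: Mapping) -> "PipelineConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(mapping) - known
        if unknown:
            raise ConfigError(f"unknown pipeline config keys: {sorted(unknown)}")
        missing = {"activities", "fasta", "out_dir"} - set(mapping)
        if missing:
            raise ConfigError(f"missing required config keys: {sorted(missing)}")
        cfg = cls(**dict(mapping))
        SuiteConfig.from_dict(cfg.suite)  # validate suite keys up front
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        return cls.from_mapping(data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(vars(self), sort_keys=True))

    def suite_config(self) -> SuiteConfig:
        cfg = SuiteConfig.from_dict(self.suite)
        cfg.vote_cutoff = self.cutoff
        return cfg


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run curate -> train -> evaluate -> sweep; return the manifest.

    The manifest maps artifact names to paths and SHA-256 digests and is
    itself written to ``<out_dir>/manifest.json``.
    """
    out = Path(config.out_dir)
    for path in (config.activities, config.fasta):
        if not Path(path).exists():
            raise ConfigError(f"input file not found: {path}")
    out.mkdir(parents=True, exist_ok=True)

    # curation
    by_target = read_activity_table(config.activities, default_unit=config.unit)
    datasets = curate_all(by_target, candidates=config.threshold_grid,
                          min_records=config.min_records)
    curated_dir = out / "curated"
    curated_dir.mkdir(exist_ok=True)
    for tid, ds in datasets.items():
        ds.write(curated_dir / f"{tid}.csv")

    # training
    sequences = read_fasta(config.fasta)
    suite = build_suite(datasets, sequences, config.suite_config(), seed=config.seed)
    suite_dir = out / "suite"
    suite.save(suite_dir)

    # evaluation
    metrics = evaluate_suite(suite, datasets)
    metrics_path = out / "metrics.csv"
    metrics.to_csv(metrics_path, index=False)

    # cutoff sweep on the pooled held-out partitions
    from .model import CPIModel, CPIResults

    results = CPIResults(model=CPIModel(datasets, sequences, suite.config), suite=suite)
    sweep = results.sweep_cutoffs()
    sweep_path = out / "sweep.csv"
    sweep.to_csv(sweep_path, index=False)

    artifacts = {
        "metrics": metrics_path,
        "sweep": sweep_path,
        "suite_manifest": suite_dir / "manifest.json",
    }
    for tid in datasets:
        artifacts[f"curated_{tid}"] = curated_dir / f"{tid}.csv"
    manifest = {
        "seed": config.seed,
        "targets": sorted(datasets),
        "n_classifiers": suite.n_classifiers,
        "artifacts": {
            name: {"path": str(p), "sha256": _digest(p)}
            for name, p in sorted(artifacts.items())
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
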