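"""High-level modelling interface: a model object fitted into a results object.

:class:`CPIModel` bundles curated per-target activity datasets with the
target sequences and a suite configuration; ``fit`` trains the full
16-classifier-per-target ensemble and returns :class:`CPIResults`, which
carries the trained suite, lazily computed evaluation tables, a
``summary()`` report, and the prediction / cutoff-sweep / network
operations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import ensemble as ens
from .curation import ActivityDataset, RawActivityRecord, curate_all
from .errors import DomainError
from .evaluation import evaluate_suite
from .modeling import ModelSuite, SuiteConfig, build_suite


class CPIModel:
    """Chemical-protein interaction model over a panel of targets.

    Parameters
    ----------
    datasets : mapping of target id to :class:`ActivityDataset`
        Curated, threshold-labelled activity sets, one per target.
    sequences : mapping of target id to amino-acid string
        Protein sequences for the proteochemometric half of the suite.
    config : SuiteConfig, optional
        Split fraction, fold count, descriptor families, hyperparameter
        overrides. Defaults follow the standard protocol (80/20 split,
        5 folds).
    """

    def __init__(
        self,
        datasets: Mapping[str, ActivityDataset],
        sequences: Mapping[str, str],
        config: SuiteConfig | None = None,
    ):
        if not datasets:
            raise DomainError("no datasets supplied")
        self.datasets = dict(datasets)
        self.sequences = dict(sequences)
        self.config = config or SuiteConfig()

    @classmethod
    def from_frames(
        cls,
        activities: pd.DataFrame,
        sequences: Mapping[str, str],
        config: SuiteConfig | None = None,
        threshold_candidates: Sequence[float] | None = None,
        unit: str = "M",
    ) -> "CPIModel":
        """Build from a raw long-form activity table.

        ``activities`` needs columns compound_id, smiles, ic50, target_id
        (IC50 in ``unit``); records are curated per target before modelling.
        """
        by_target: dict[str, list[RawActivityRecord]] = {}
        for row in activities.itertuples():
            rec = RawActivityRecord(
                str(row.compound_id), str(row.smiles), float(row.ic50),
                str(row.target_id), unit=str(getattr(row, "unit", unit)),
            )
            by_target.setdefault(rec.target_id, []).append(rec)
        datasets = curate_all(by_target, candidates=threshold_candidates)
        return cls(datasets, dict(sequences), config)

    def fit(self, seed: int = 0) -> "CPIResults":
        """Train all classifiers and return the results object."""
        suite = build_suite(self.datasets, self.sequences, self.config, seed=seed)
        return CPIResults(model=self, suite=suite)


@dataclass
class CPIResults:
    """Trained suite plus evaluation, prediction and export methods."""

    model: CPIModel
    suite: ModelSuite
    _metrics: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def metrics(self) -> pd.DataFrame:
        """Cross-validation and held-out metric table (computed once)."""
        if self._metrics is None:
            self._metrics = evaluate_suite(self.suite, self.model.datasets)
        return self._metrics

    def test_votes(self) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
        """Vote counts and true labels over the pooled held-out partitions.

        Returns (vote_counts, labels, detail table); this is the input for
        the ensemble cutoff sweep.
        """
        counts, labels, rows = [], [], []
        for tid in self.suite.target_ids:
            ds = self.model.datasets[tid]
            split = self.suite.splits[tid]
            y = ds.labels()
            test_smiles = [ds.records[i].canonical_smiles for i in split.test_idx]
            if not test_smiles:
                continue
            votes = ens.vote_matrix(self.suite, test_smiles, tid)
            for row_votes, i in zip(votes, split.test_idx):
                count = int(row_votes.sum())
                counts.append(count)
                labels.append(int(y[i]))
                rows.append({"compound_id": ds.records[i].compound_id,
                             "target_id": tid, "vote_count": count,
                             "label": int(y[i])})
        return (np.asarray(counts), np.asarray(labels), pd.DataFrame(rows))

    def sweep_cutoffs(self) -> pd.DataFrame:
        """Ensemble metrics at cutoffs 1..16 on the pooled test partitions."""
        counts, labels, _ = self.test_votes()
        return ens.sweep_cutoffs(counts, labels)

    def predict(self, molecules, targets: Sequence[str] | None = None,
                cutoff: int | None = None) -> ens.PredictionResult:
        config = ens.EnsembleConfig(cutoff=cutoff or self.suite.config.vote_cutoff)
        return ens.predict_batch(self.suite, molecules, targets, config)

    def to_network(self, prediction: ens.PredictionResult | pd.DataFrame,
                   cutoff: int | None = None):
        table = prediction.table if isinstance(prediction, ens.PredictionResult) else prediction
        return ens.build_network(table, cutoff=cutoff)

    def summary(self) -> str:
        """Plain-text performance summary, one block per partition."""
        m = self.metrics
        lines = [
            "Chemical-protein interaction model suite",
            "=" * 44,
            f"targets: {self.suite.n_targets}   classifiers: {self.suite.n_classifiers} "
            f"({self.suite.n_per_target_classifiers} per-target + {len(self.suite.pcm)} PCM)",
            f"vote cutoff: {self.suite.config.vote_cutoff} of 16   "
            f"master seed: {self.suite.master_seed}",
            "",
        ]
        for part in ("cv", "test"):
            sub = m[m["partition"] == part]
            if sub.empty:
                continue
            lines.append(f"[{part}] mean over {len(sub)} classifier rows:")
            means = sub[["AUC", "SE", "SP", "Q", "MCC"]].mean()
            lines.append("  " + "  ".join(f"{k}={v:.3f}" for k, v in means.items()))
        lines.append("")
        with pd.option_context("display.width", 120, "display.max_rows", 400):
            lines.append(m.round(3).to_string(index=False))
        return "\n".join(lines)
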