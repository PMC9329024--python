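"""Classification metrics, cross-validation, and suite-wide reports.

The five indicators are the usual ones for binary activity classifiers:

    SE  = TP / (TP + FN)                       (sensitivity, recall on actives)
    SP  = TN / (TN + FP)                       (specificity)
    Q   = (TP + TN) / (TP + TN + FP + FN)      (accuracy)
    MCC = (TP*TN - FN*FP) / sqrt((TP+FN)(TP+FP)(TN+FN)(TN+FP))
    AUC = area under the ROC curve, i.e. the probability that a random
          active is scored above a random inactive, ties counting 1/2.

Any ratio with a zero denominator is reported as 0 by convention, so the
metrics are total functions of the confusion counts.

Cross-validation pools the out-of-fold predictions of all k folds into a
single confusion table before computing metrics; with small folds this
keeps MCC well-defined where per-fold tables would degenerate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from . import featurization as feat
from .curation import ActivityDataset
from .errors import DomainError
from .modeling import (
    ALGORITHMS,
    COMPOUND_FEATURE_KINDS,
    PCM_FEATURE_KINDS,
    FoldPlan,
    ModelSpec,
    ModelSuite,
    TrainedClassifier,
    make_estimator,
    make_folds,
    pool_pcm_dataset,
)

METRIC_COLUMNS = ("AUC", "SE", "SP", "Q", "MCC")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @classmethod
    def from_predictions(cls, y_true: Sequence[int], y_pred: Sequence[int]) -> "ConfusionCounts":
        yt = np.asarray(y_true, dtype=int)
        yp = np.asarray(y_pred, dtype=int)
        if yt.shape != yp.shape:
            raise DomainError("label/prediction length mismatch")
        return cls(
            tp=int(((yt == 1) & (yp == 1)).sum()),
            tn=int(((yt == 0) & (yp == 0)).sum()),
            fp=int(((yt == 0) & (yp == 1)).sum()),
            fn=int(((yt == 1) & (yp == 0)).sum()),
        )


@dataclass
class MetricReport:
    """SE/SP/Q/MCC (and optionally AUC) with provenance."""

    se: float
    sp: float
    q: float
    mcc: float
    auc: float | None = None
    counts: ConfusionCounts | None = None
    model: str = ""
    partition: str = ""
    n: int = 0

    def as_row(self) -> dict:
        return {
            "model": self.model,
            "partition": self.partition,
            "AUC": self.auc,
            "SE": self.se,
            "SP": self.sp,
            "Q": self.q,
            "MCC": self.mcc,
            "n": self.n,
        }


def _ratio(num: int, den: int) -> float:
    return num / den if den else 0.0


def compute_metrics(counts: ConfusionCounts) -> MetricReport:
    """SE, SP, Q and MCC from a confusion table (AUC left unset)."""
    if counts.total < 1:
        raise DomainError("empty confusion table")
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    denom2 = (tp + fn) * (tp + fp) * (tn + fn) * (tn + fp)
    mcc = (tp * tn - fn * fp) / math.sqrt(denom2) if denom2 else 0.0
    return MetricReport(
        se=_ratio(tp, tp + fn),
        sp=_ratio(tn, tn + fp),
        q=_ratio(tp + tn, counts.total),
        mcc=mcc,
        counts=counts,
        n=counts.total,
    )


def roc_auc(labels: Sequence[int], scores: Sequence[float]) -> float:
    """ROC AUC, equal to the Mann-Whitney win probability with ties = 1/2."""
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise DomainError("ROC AUC needs both classes present")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def cross_validate(
    spec: ModelSpec,
    features: np.ndarray,
    labels: np.ndarray,
    fold_plan: FoldPlan,
    threshold: float = 0.5,
) -> MetricReport:
    """k-fold cross-validation with out-of-fold predictions pooled.

    Each fold's held-out rows are scored by a model trained on the other
    folds; one confusion table and one AUC are computed from the pooled
    out-of-fold scores.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    oof_scores = np.full(len(y), np.nan)
    for train_idx, held_idx in fold_plan.iter_train_test():
        if len(np.unique(y[train_idx])) < 2:
            raise DomainError("a fold's training portion is single-class")
        est = make_estimator(spec)
        est.fit(X[train_idx], y[train_idx])
        proba = est.predict_proba(X[held_idx])
        classes = list(est.classes_ if hasattr(est, "classes_") else est[-1].classes_)
        oof_scores[held_idx] = proba[:, classes.index(1)]
    covered = ~np.isnan(oof_scores)
    y_cov = y[covered]
    scores = oof_scores[covered]
    preds = (scores >= threshold).astype(int)
    report = compute_metrics(ConfusionCounts.from_predictions(y_cov, preds))
    report.auc = roc_auc(y_cov, scores) if len(np.unique(y_cov)) == 2 else None
    report.partition = "cv"
    report.n = int(covered.sum())
    return report


def _held_out_report(tc: TrainedClassifier, X: np.ndarray, y: np.ndarray) -> MetricReport:
    scores = tc.predict_scores(X)
    preds = (scores >= tc.threshold).astype(int)
    report = compute_metrics(ConfusionCounts.from_predictions(y, preds))
    report.auc = roc_auc(y, scores) if len(np.unique(y)) == 2 else None
    report.partition = "test"
    report.n = len(y)
    return report


def evaluate_suite(
    suite: ModelSuite,
    datasets: Mapping[str, ActivityDataset],
    partitions: Sequence[str] = ("cv", "test"),
) -> pd.DataFrame:
    """Metric table for every classifier in the suite.

    One row per (target x 8 models x partition) plus (PCM x 8 models x
    partition), the structural twin of a per-target performance summary.
    Cross-validation rows re-fit fold models inside each training
    partition; test rows score the already-trained classifiers on the
    held-out 20%.
    """
    rows = []
    fp_cache: dict[str, dict[str, np.ndarray]] = {
        tid: {kind: feat.fingerprint_matrix(datasets[tid].smiles(), kind)
              for kind in COMPOUND_FEATURE_KINDS}
        for tid in suite.target_ids
    }

    def add_row(report: MetricReport, target: str, name: str):
        alg, kind = name.split("_", 1)
        rows.append({
            "target": target, "algorithm": alg, "feature_kind": kind,
            "partition": report.partition, "AUC": report.auc, "SE": report.se,
            "SP": report.sp, "Q": report.q, "MCC": report.mcc, "n": report.n,
        })

    for tid in suite.target_ids:
        ds = datasets[tid]
        y = ds.labels()
        split = suite.splits[tid]
        plan = None
        if "cv" in partitions:
            plan = make_folds(split, suite.config.n_folds,
                              seed=_fold_seed(suite, tid))
        for name, tc in suite.per_target[tid].items():
            X = fp_cache[tid][tc.spec.fingerprint_kind]
            if "cv" in partitions and plan is not None:
                rep = cross_validate(tc.spec, X, y, plan, tc.threshold)
                add_row(rep, tid, name)
            if "test" in partitions and len(split.test_idx):
                rep = _held_out_report(tc, X[split.test_idx], y[split.test_idx])
                add_row(rep, tid, name)

    # pooled PCM rows
    for kind in PCM_FEATURE_KINDS:
        fp_kind = kind.replace("_protein", "")
        fps = {t: fp_cache[t][fp_kind] for t in suite.target_ids}
        X_tr, y_tr, _ = pool_pcm_dataset(
            datasets, suite.registry, fp_kind, fingerprints=fps,
            row_indices={t: suite.splits[t].train_idx for t in suite.target_ids},
        )
        X_te, y_te = None, None
        if any(len(suite.splits[t].test_idx) for t in suite.target_ids):
            X_te, y_te, _ = pool_pcm_dataset(
                datasets, suite.registry, fp_kind, fingerprints=fps,
                row_indices={t: suite.splits[t].test_idx for t in suite.target_ids},
            )
        if "cv" in partitions:
            pooled_split = _trivial_split(y_tr)
            plan = make_folds(pooled_split, suite.config.n_folds,
                              seed=_fold_seed(suite, f"pcm_{fp_kind}"))
        for alg in ALGORITHMS:
            name = f"{alg}_{kind}"
            tc = suite.pcm[name]
            if "cv" in partitions:
                rep = cross_validate(tc.spec, X_tr, y_tr, plan, tc.threshold)
                add_row(rep, "PCM", name)
            if "test" in partitions and X_te is not None:
                rep = _held_out_report(tc, X_te, y_te)
                add_row(rep, "PCM", name)

    return pd.DataFrame(rows)


def _fold_seed(suite: ModelSuite, tag: str) -> int:
    from .modeling import child_seed

    return child_seed(suite.master_seed, "folds", tag)


def _trivial_split(y: np.ndarray):
    from .modeling import DataSplit

    return DataSplit(np.arange(len(y)), np.array([], dtype=int), y, 0.0, 0)
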