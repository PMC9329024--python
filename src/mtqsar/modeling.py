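"""The per-target and proteochemometric classifier suite.

For every target, eight classifiers are trained — the cross of four
learners (random forest, k-nearest neighbours, RBF support vector machine,
one-hidden-layer neural network) with two compound fingerprints (MACCS,
ECFP6). A further eight proteochemometric (PCM) classifiers are trained
once on the pooled data of all targets, with each row's fingerprint
extended by its target's projected protein descriptor block. A suite over
T targets therefore holds 8*T + 8 classifiers, and any compound-target
query is answered by exactly 16 of them.

Data handling follows the usual chemogenomics protocol: a stratified
80/20 train/test split per target, and stratified k-fold (default 5)
cross-validation inside the training partition. Everything is
deterministic under a single master seed, which fans out to per-component
seeds via a stable hash of the component name.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import joblib
import numpy as np
from sklearn.calibration import CalibratedClassifierCV
from sklearn.neighbors import KNeighborsClassifier
from sklearn.ensemble import RandomForestClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import MinMaxScaler
from sklearn.svm import SVC

from . import featurization as feat
from .curation import ActivityDataset
from .errors import ConfigError, DomainError, UnknownTargetError

ALGORITHMS = ("RF", "SVM", "KNN", "NN")
COMPOUND_FEATURE_KINDS = ("MACCS", "ECFP6")
PCM_FEATURE_KINDS = ("MACCS_protein", "ECFP6_protein")

#: Canonical vote order: the 8 per-target models, then the 8 PCM models.
PER_TARGET_MODEL_NAMES = tuple(
    f"{alg}_{kind}" for alg in ALGORITHMS for kind in COMPOUND_FEATURE_KINDS
)
PCM_MODEL_NAMES = tuple(
    f"{alg}_{kind}" for alg in ALGORITHMS for kind in PCM_FEATURE_KINDS
)
ALL_MODEL_NAMES = PER_TARGET_MODEL_NAMES + PCM_MODEL_NAMES

DEFAULT_HYPERPARAMETERS: dict[str, dict] = {
    "RF": {"n_estimators": 500, "max_depth": None},
    "KNN": {"n_neighbors": 5, "metric": "euclidean"},
    "SVM": {"C": 1.0, "gamma": "scale", "kernel": "rbf"},
    "NN": {"hidden_layer_sizes": (100,), "activation": "relu", "max_iter": 500},
}


def child_seed(master_seed: int, *tags: str) -> int:
    """Deterministic sub-seed derived from the master seed and a name path."""
    h = zlib.crc32("/".join(tags).encode())
    return (int(master_seed) * 1_000_003 + h) % (2**31 - 1)


@dataclass(frozen=True)
class ModelSpec:
    """Identity and configuration of one classifier in the suite."""

    algorithm: str
    feature_kind: str
    hyperparameters: tuple[tuple[str, object], ...] = ()
    seed: int = 0

    def __post_init__(self):
        if self.algorithm not in ALGORITHMS:
            raise ConfigError(f"unknown algorithm {self.algorithm!r}")
        if self.feature_kind not in COMPOUND_FEATURE_KINDS + PCM_FEATURE_KINDS:
            raise ConfigError(f"unknown feature kind {self.feature_kind!r}")

    @property
    def name(self) -> str:
        return f"{self.algorithm}_{self.feature_kind}"

    @property
    def is_pcm(self) -> bool:
        return self.feature_kind.endswith("_protein")

    @property
    def fingerprint_kind(self) -> str:
        return self.feature_kind.replace("_protein", "")

    def params(self) -> dict:
        merged = dict(DEFAULT_HYPERPARAMETERS[self.algorithm])
        merged.update(dict(self.hyperparameters))
        return merged


def make_estimator(spec: ModelSpec):
    """Instantiate the scikit-learn estimator behind a spec.

    Count fingerprints go into the tree model raw; distance- and
    gradient-based learners (KNN, SVM, NN) see min-max scaled features so
    no slot dominates the metric or the kernel.
    """
    p = spec.params()
    if spec.algorithm == "RF":
        return RandomForestClassifier(random_state=spec.seed, n_jobs=1, **p)
    if spec.algorithm == "KNN":
        core = KNeighborsClassifier(**p)
    elif spec.algorithm == "SVM":
        # probability scores via a calibrated decision function
        core = CalibratedClassifierCV(SVC(random_state=spec.seed, **p), ensemble=False)
    elif spec.algorithm == "NN":
        core = MLPClassifier(random_state=spec.seed, **p)
    else:  # pragma: no cover - guarded by ModelSpec
        raise ConfigError(spec.algorithm)
    return Pipeline([("scale", MinMaxScaler(clip=True)), ("model", core)])


@dataclass
class TrainedClassifier:
    """A fitted classifier plus its decision threshold and provenance."""

    spec: ModelSpec
    estimator: object
    threshold: float = 0.5
    n_train: int = 0
    class_counts: tuple[int, int] = (0, 0)
    n_features: int = 0

    def predict_scores(self, X: np.ndarray) -> np.ndarray:
        """Positive-class probability in [0, 1] for each row."""
        proba = self.estimator.predict_proba(np.asarray(X, dtype=float))
        classes = list(getattr(self.estimator, "classes_", None)
                       if hasattr(self.estimator, "classes_")
                       else self.estimator[-1].classes_)
        return proba[:, classes.index(1)]

    def predict_labels(self, X: np.ndarray) -> np.ndarray:
        """Binary vote: 1 where the positive-class score meets the threshold."""
        return (self.predict_scores(X) >= self.threshold).astype(int)


def train_classifier(spec: ModelSpec, features: np.ndarray, labels: np.ndarray) -> TrainedClassifier:
    """Fit one classifier. Deterministic for fixed (spec, data, seed)."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    if len(X) != len(y) or len(y) < 2:
        raise DomainError("need at least two labelled rows with matching shapes")
    uniq = set(np.unique(y))
    if uniq != {0, 1}:
        raise DomainError(f"training requires both classes, got labels {sorted(uniq)}")
    est = make_estimator(spec)
    est.fit(X, y)
    return TrainedClassifier(
        spec=spec,
        estimator=est,
        n_train=len(y),
        class_counts=(int((y == 0).sum()), int((y == 1).sum())),
        n_features=X.shape[1],
    )


# -- splitting and folding ---------------------------------------------------

@dataclass
class DataSplit:
    """Stratified train/test index split over one dataset."""

    train_idx: np.ndarray
    test_idx: np.ndarray
    labels: np.ndarray  # full label vector the split refers to
    test_fraction: float
    seed: int

    def validate(self) -> None:
        n = len(self.labels)
        combined = np.sort(np.concatenate([self.train_idx, self.test_idx]))
        assert np.array_equal(combined, np.arange(n)), "split not a partition"


def stratified_split(labels: np.ndarray | ActivityDataset,
                     test_fraction: float = 0.2, seed: int = 0) -> DataSplit:
    """Stratified split of indices into train and test.

    Per class, round(n_class * test_fraction) items go to the test side, so
    the per-class test proportion is within one item of the global fraction.
    """
    if isinstance(labels, ActivityDataset):
        labels = labels.labels()
    y = np.asarray(labels, dtype=int)
    if not 0.0 <= test_fraction < 1.0:
        raise DomainError("test_fraction must be in [0, 1)")
    if test_fraction == 0.0:
        return DataSplit(np.arange(len(y)), np.array([], dtype=int), y, 0.0, seed)
    rng = np.random.default_rng(seed)
    train, test = [], []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        if len(idx) < 2:
            raise DomainError(f"class {cls} has fewer than 2 members")
        n_test = int(round(len(idx) * test_fraction))
        n_test = min(max(n_test, 1), len(idx) - 1)
        perm = rng.permutation(idx)
        test.append(perm[:n_test])
        train.append(perm[n_test:])
    split = DataSplit(
        np.sort(np.concatenate(train)), np.sort(np.concatenate(test)),
        y, test_fraction, seed,
    )
    split.validate()
    return split


@dataclass
class FoldPlan:
    """k disjoint, class-stratified folds over the training partition."""

    folds: list[np.ndarray]  # global indices; union = split.train_idx
    k: int
    seed: int

    def iter_train_test(self):
        """Yield (train_indices, held_out_indices) per fold."""
        all_idx = np.concatenate(self.folds)
        for fold in self.folds:
            mask = ~np.isin(all_idx, fold)
            yield np.sort(all_idx[mask]), np.sort(fold)


def make_folds(split: DataSplit, k: int = 5, seed: int = 0) -> FoldPlan:
    """Build a stratified fold plan whose fold sizes differ by at most one.

    Remainder items of each class are dealt to the currently smallest
    folds, which keeps both the per-class counts and the overall fold sizes
    within one of each other.
    """
    if k < 2:
        raise DomainError("need at least 2 folds")
    y = split.labels
    train = split.train_idx
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    class_ids = sorted(np.unique(y[train]), key=lambda c: -int((y[train] == c).sum()))
    for cls in class_ids:
        idx = train[y[train] == cls]
        if len(idx) < k:
            raise DomainError(
                f"class {cls} has {len(idx)} training members, fewer than k={k}"
            )
        perm = rng.permutation(idx)
        base, rem = divmod(len(perm), k)
        order = sorted(range(k), key=lambda f: (len(folds[f]), f))
        sizes = {f: base + (1 if rank < rem else 0) for rank, f in enumerate(order)}
        pos = 0
        for f in range(k):
            folds[f].extend(perm[pos : pos + sizes[f]])
            pos += sizes[f]
    plan = FoldPlan([np.sort(np.array(f, dtype=int)) for f in folds], k, seed)
    sizes = [len(f) for f in plan.folds]
    assert max(sizes) - min(sizes) <= 1
    assert np.array_equal(np.sort(np.concatenate(plan.folds)), np.sort(train))
    return plan


# -- target registry ---------------------------------------------------------

@dataclass
class TargetRegistry:
    """Protein side of the suite: sequences, descriptors, scaler, projection.

    The descriptor matrix over the registered sequences is min-max
    normalized and PCA-projected once; the frozen transforms supply every
    target's protein block for PCM feature assembly.
    """

    sequences: dict[str, str]
    families: tuple[str, ...]
    scaler: feat.FeatureScaler
    projection: feat.ProjectionModel
    blocks: dict[str, np.ndarray] = field(default_factory=dict)

    @classmethod
    def from_sequences(cls, sequences: Mapping[str, str],
                       families: Sequence[str] = feat.DEFAULT_FAMILIES,
                       n_components: int = feat.DEFAULT_PROTEIN_COMPONENTS) -> "TargetRegistry":
        if len(sequences) < 2:
            raise DomainError("registry needs at least 2 target sequences")
        ids = sorted(sequences)
        desc = np.vstack([
            compute_cached_descriptors(sequences[t], tuple(families)) for t in ids
        ])
        scaler = feat.FeatureScaler.fit(desc)
        scaled = scaler.transform(desc)
        projection = feat.fit_projection(scaled, n_components)
        blocks = dict(zip(ids, projection.project(scaled)))
        return cls(dict(sequences), tuple(families), scaler, projection, blocks)

    @property
    def target_ids(self) -> list[str]:
        return sorted(self.sequences)

    @property
    def k_effective(self) -> int:
        return self.projection.k_effective

    def protein_block(self, target_id: str) -> np.ndarray:
        if target_id not in self.blocks:
            raise UnknownTargetError(target_id, self.target_ids)
        return self.blocks[target_id]


def compute_cached_descriptors(sequence: str, families: tuple[str, ...]) -> np.ndarray:
    return feat.compute_protein_descriptors(sequence, families).to_numpy()


# -- suite configuration and construction ------------------------------------

@dataclass
class SuiteConfig:
    """Tunable knobs of a suite build; defaults match the standard protocol."""

    test_fraction: float = 0.2
    n_folds: int = 5
    protein_families: tuple[str, ...] = feat.DEFAULT_FAMILIES
    protein_components: int = feat.DEFAULT_PROTEIN_COMPONENTS
    hyperparameters: dict = field(default_factory=dict)  # per-algorithm overrides
    vote_cutoff: int = 9

    def spec_for(self, algorithm: str, feature_kind: str, seed: int) -> ModelSpec:
        overrides = tuple(sorted(self.hyperparameters.get(algorithm, {}).items()))
        return ModelSpec(algorithm, feature_kind, overrides, seed)

    def to_dict(self) -> dict:
        return {
            "test_fraction": self.test_fraction,
            "n_folds": self.n_folds,
            "protein_families": list(self.protein_families),
            "protein_components": self.protein_components,
            "hyperparameters": self.hyperparameters,
            "vote_cutoff": self.vote_cutoff,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "SuiteConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown suite config keys: {sorted(unknown)}")
        d = dict(d)
        if "protein_families" in d:
            d["protein_families"] = tuple(d["protein_families"])
        return cls(**d)


def pool_pcm_dataset(
    datasets: Mapping[str, ActivityDataset],
    registry: TargetRegistry,
    fingerprint_kind: str,
    fingerprints: Mapping[str, np.ndarray] | None = None,
    row_indices: Mapping[str, np.ndarray] | None = None,
) -> tuple[np.ndarray, np.ndarray, list[tuple[str, int]]]:
    """Pool per-target rows into one PCM design matrix.

    Returns (X, y, provenance) where provenance lists (target_id, local
    row index) per pooled row. ``row_indices`` restricts each dataset to a
    subset (e.g. its training partition); ``fingerprints`` may supply
    precomputed per-target fingerprint matrices.
    """
    X_rows, y_rows, prov = [], [], []
    for tid in sorted(datasets):
        ds = datasets[tid]
        block = registry.protein_block(tid)  # raises for unregistered targets
        fps = (fingerprints[tid] if fingerprints is not None
               else feat.fingerprint_matrix(ds.smiles(), fingerprint_kind))
        idx = (np.asarray(row_indices[tid]) if row_indices is not None
               else np.arange(len(ds)))
        labels = ds.labels()
        for i in idx:
            X_rows.append(feat.assemble_pcm(fps[i], block, registry.k_effective))
            y_rows.append(labels[i])
            prov.append((tid, int(i)))
    if not X_rows:
        raise DomainError("no rows to pool")
    return np.vstack(X_rows), np.asarray(y_rows, dtype=int), prov


@dataclass
class ModelSuite:
    """The full trained ensemble: 8 classifiers per target plus 8 PCM ones."""

    config: SuiteConfig
    registry: TargetRegistry
    per_target: dict[str, dict[str, TrainedClassifier]]
    pcm: dict[str, TrainedClassifier]
    splits: dict[str, DataSplit]
    master_seed: int
    thresholds: dict[str, float] = field(default_factory=dict)

    @property
    def target_ids(self) -> list[str]:
        return sorted(self.per_target)

    @property
    def n_targets(self) -> int:
        return len(self.per_target)

    @property
    def n_classifiers(self) -> int:
        return sum(len(m) for m in self.per_target.values()) + len(self.pcm)

    @property
    def n_per_target_classifiers(self) -> int:
        return sum(len(m) for m in self.per_target.values())

    @property
    def model_names(self) -> tuple[str, ...]:
        """The 16 model names voting on any compound-target pair, in order."""
        return ALL_MODEL_NAMES

    def models_for(self, target_id: str) -> dict[str, TrainedClassifier]:
        if target_id not in self.per_target:
            raise UnknownTargetError(target_id, self.target_ids)
        return {**self.per_target[target_id], **self.pcm}

    # -- persistence --------------------------------------------------------

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        (directory / "models").mkdir(parents=True, exist_ok=True)
        manifest = {
            "master_seed": self.master_seed,
            "config": self.config.to_dict(),
            "thresholds": self.thresholds,
            "registry": {
                "sequences": self.registry.sequences,
                "families": list(self.registry.families),
                "scaler": self.registry.scaler.to_dict(),
                "projection": self.registry.projection.to_dict(),
                "blocks": {t: b.tolist() for t, b in self.registry.blocks.items()},
            },
            "splits": {
                t: {
                    "train_idx": s.train_idx.tolist(),
                    "test_idx": s.test_idx.tolist(),
                    "labels": s.labels.tolist(),
                    "test_fraction": s.test_fraction,
                    "seed": s.seed,
                }
                for t, s in self.splits.items()
            },
            "targets": self.target_ids,
            "model_names": list(ALL_MODEL_NAMES),
        }
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        for tid, models in self.per_target.items():
            for name, tc in models.items():
                joblib.dump(tc, directory / "models" / f"{tid}__{name}.joblib")
        for name, tc in self.pcm.items():
            joblib.dump(tc, directory / "models" / f"__pcm__{name}.joblib")

    @classmethod
    def load(cls, directory: str | Path) -> "ModelSuite":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        reg = manifest["registry"]
        registry = TargetRegistry(
            sequences=reg["sequences"],
            families=tuple(reg["families"]),
            scaler=feat.FeatureScaler.from_dict(reg["scaler"]),
            projection=feat.ProjectionModel.from_dict(reg["projection"]),
            blocks={t: np.asarray(b, float) for t, b in reg["blocks"].items()},
        )
        splits = {
            t: DataSplit(
                np.asarray(s["train_idx"], int), np.asarray(s["test_idx"], int),
                np.asarray(s["labels"], int), s["test_fraction"], s["seed"],
            )
            for t, s in manifest["splits"].items()
        }
        per_target: dict[str, dict[str, TrainedClassifier]] = {}
        pcm: dict[str, TrainedClassifier] = {}
        for path in sorted((directory / "models").glob("*.joblib")):
            tc: TrainedClassifier = joblib.load(path)
            stem = path.stem
            if stem.startswith("__pcm__"):
                pcm[stem.removeprefix("__pcm__")] = tc
            else:
                tid, name = stem.split("__", 1)
                per_target.setdefault(tid, {})[name] = tc
        return cls(
            config=SuiteConfig.from_dict(manifest["config"]),
            registry=registry,
            per_target=per_target,
            pcm=pcm,
            splits=splits,
            master_seed=manifest["master_seed"],
            thresholds={t: float(v) for t, v in manifest["thresholds"].items()},
        )


def build_suite(
    datasets: Mapping[str, ActivityDataset],
    sequences: Mapping[str, str],
    config: SuiteConfig | None = None,
    seed: int = 0,
) -> ModelSuite:
    """Train the whole suite from curated datasets and target sequences."""
    if not datasets:
        raise DomainError("need at least one curated dataset")
    missing = set(datasets) - set(sequences)
    if missing:
        raise DomainError(f"no protein sequence for targets {sorted(missing)}")
    config = config or SuiteConfig()

    if len(sequences) >= 2:
        registry = TargetRegistry.from_sequences(
            sequences, config.protein_families, config.protein_components
        )
    else:  # single-target suite: degenerate protein side, zero-length block
        tid = next(iter(sequences))
        desc = compute_cached_descriptors(sequences[tid], tuple(config.protein_families))
        registry = TargetRegistry(
            sequences=dict(sequences),
            families=tuple(config.protein_families),
            scaler=feat.FeatureScaler(np.zeros_like(desc), np.ones_like(desc)),
            projection=feat.ProjectionModel(
                mean=desc.astype(float), components=np.empty((0, len(desc))),
                explained_variance=np.empty(0), k_configured=config.protein_components,
            ),
            blocks={tid: np.empty(0)},
        )

    fingerprints: dict[str, dict[str, np.ndarray]] = {}
    splits: dict[str, DataSplit] = {}
    per_target: dict[str, dict[str, TrainedClassifier]] = {}
    thresholds: dict[str, float] = {}

    for tid in sorted(datasets):
        ds = datasets[tid]
        thresholds[tid] = ds.threshold
        fingerprints[tid] = {
            kind: feat.fingerprint_matrix(ds.smiles(), kind)
            for kind in COMPOUND_FEATURE_KINDS
        }
        split = stratified_split(ds.labels(), config.test_fraction,
                                 child_seed(seed, "split", tid))
        splits[tid] = split
        models: dict[str, TrainedClassifier] = {}
        y = ds.labels()
        for alg in ALGORITHMS:
            for kind in COMPOUND_FEATURE_KINDS:
                spec = config.spec_for(alg, kind, child_seed(seed, "model", tid, alg, kind))
                X = fingerprints[tid][kind][split.train_idx]
                models[spec.name] = train_classifier(spec, X, y[split.train_idx])
        per_target[tid] = models

    pcm: dict[str, TrainedClassifier] = {}
    train_indices = {tid: splits[tid].train_idx for tid in datasets}
    for kind in PCM_FEATURE_KINDS:
        fp_kind = kind.replace("_protein", "")
        X, y, _ = pool_pcm_dataset(
            datasets, registry, fp_kind,
            fingerprints={t: fingerprints[t][fp_kind] for t in datasets},
            row_indices=train_indices,
        )
        for alg in ALGORITHMS:
            spec = config.spec_for(alg, kind, child_seed(seed, "model", "pcm", alg, kind))
            pcm[spec.name] = train_classifier(spec, X, y)

    return ModelSuite(
        config=config,
        registry=registry,
        per_target=per_target,
        pcm=pcm,
        splits=splits,
        master_seed=seed,
        thresholds=thresholds,
    )
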