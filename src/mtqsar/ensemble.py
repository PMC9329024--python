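"""Multivoting ensemble calls, cutoff sweeps, batch prediction, networks.

For a compound-target pair, the 8 per-target classifiers and the 8 PCM
classifiers each cast a binary vote; the pair is called an interaction
when at least ``cutoff`` of the 16 votes are positive (default 9, the
calibrated optimum of the cutoff sweep). Sweeping the cutoff from 1 to 16
trades sensitivity against specificity monotonically, which is how the
default is chosen. Active calls over a molecule set induce a bipartite
compound-target network that can be exported as SIF or GraphML.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from rdkit import Chem

from . import featurization as feat
from .curation import standardize_structure
from .errors import BatchLimitError, DomainError, InvalidSmilesError
from .evaluation import ConfusionCounts, compute_metrics, roc_auc
from .modeling import ALL_MODEL_NAMES, ModelSuite

N_VOTERS = 16
DEFAULT_CUTOFF = 9
DEFAULT_BATCH_CAP = 1000

ACTIVE, INACTIVE = "active", "inactive"


@dataclass
class EnsembleConfig:
    cutoff: int = DEFAULT_CUTOFF
    batch_cap: int = DEFAULT_BATCH_CAP

    def __post_init__(self):
        if not 1 <= self.cutoff <= N_VOTERS:
            raise DomainError(f"cutoff must be in [1, {N_VOTERS}], got {self.cutoff}")


@dataclass
class VoteVector:
    """The 16 named binary votes for one compound-target pair."""

    compound_id: str
    target_id: str
    votes: dict[str, int]  # keyed by canonical model name, insertion-ordered

    def __post_init__(self):
        if tuple(self.votes) != ALL_MODEL_NAMES:
            raise DomainError("votes must carry all 16 canonical model names in order")
        if any(v not in (0, 1) for v in self.votes.values()):
            raise DomainError("votes must be binary")

    @property
    def vote_count(self) -> int:
        return sum(self.votes.values())


def vote_matrix(suite: ModelSuite, smiles_list: Sequence[str], target_id: str) -> np.ndarray:
    """(n_molecules, 16) binary vote matrix for one target.

    Columns follow the canonical model order (8 per-target, then 8 PCM).
    Much faster than per-molecule queries because each classifier scores
    the whole batch at once.
    """
    models = suite.models_for(target_id)  # raises UnknownTargetError
    fps = {
        kind: feat.fingerprint_matrix(smiles_list, kind).astype(float)
        for kind in ("MACCS", "ECFP6")
    }
    block = suite.registry.protein_block(target_id)
    votes = np.zeros((len(smiles_list), N_VOTERS), dtype=int)
    for j, name in enumerate(ALL_MODEL_NAMES):
        tc = models[name]
        X = fps[tc.spec.fingerprint_kind]
        if tc.spec.is_pcm:
            X = np.hstack([X, np.tile(block, (len(X), 1))])
        votes[:, j] = tc.predict_labels(X)
    return votes


def collect_votes(suite: ModelSuite, canonical_smiles: str, target_id: str,
                  compound_id: str = "") -> VoteVector:
    """Query all 16 classifiers of a target for one molecule."""
    row = vote_matrix(suite, [canonical_smiles], target_id)[0]
    votes = {name: int(v) for name, v in zip(ALL_MODEL_NAMES, row)}
    return VoteVector(compound_id or canonical_smiles, target_id, votes)


def call_interaction(votes: VoteVector | int, config: EnsembleConfig | int | None = None) -> str:
    """Threshold a vote count: active iff vote_count >= cutoff."""
    count = votes.vote_count if isinstance(votes, VoteVector) else int(votes)
    if isinstance(config, EnsembleConfig):
        cutoff = config.cutoff
    elif config is None:
        cutoff = DEFAULT_CUTOFF
    else:
        cutoff = EnsembleConfig(cutoff=int(config)).cutoff
    return ACTIVE if count >= cutoff else INACTIVE


def sweep_cutoffs(
    vote_vectors: Sequence[VoteVector] | Sequence[int] | np.ndarray,
    true_labels: Sequence[int],
) -> pd.DataFrame:
    """Ensemble metrics at every cutoff 1..16.

    The ``AUC`` column is the balanced accuracy (SE + SP) / 2 at each
    cutoff, mirroring how a cutoff table is conventionally summarized on a
    balanced test set; ``vote_auc`` is the orthodox ROC AUC obtained by
    treating the 0-16 vote count itself as a ranking score (constant
    across rows).
    """
    counts = np.array([
        v.vote_count if isinstance(v, VoteVector) else int(v) for v in vote_vectors
    ])
    y = np.asarray(true_labels, dtype=int)
    if len(counts) != len(y):
        raise DomainError("vote/label length mismatch")
    if len(np.unique(y)) < 2:
        raise DomainError("sweep needs both classes among the true labels")
    vote_auc = roc_auc(y, counts)
    rows = []
    for cutoff in range(1, N_VOTERS + 1):
        preds = (counts >= cutoff).astype(int)
        rep = compute_metrics(ConfusionCounts.from_predictions(y, preds))
        rows.append({
            "cutoff": cutoff,
            "AUC": (rep.se + rep.sp) / 2,
            "Q": rep.q,
            "SE": rep.se,
            "SP": rep.sp,
            "MCC": rep.mcc,
            "vote_auc": vote_auc,
        })
    frame = pd.DataFrame(rows)
    assert (np.diff(frame["SE"]) <= 1e-12).all(), "SE must be non-increasing"
    assert (np.diff(frame["SP"]) >= -1e-12).all(), "SP must be non-decreasing"
    return frame


def best_cutoff(sweep: pd.DataFrame, by: str = "Q") -> int:
    """Smallest cutoff attaining the maximum of the chosen column."""
    col = sweep[by].to_numpy()
    return int(sweep["cutoff"].to_numpy()[int(np.argmax(col))])


# -- batch prediction --------------------------------------------------------

@dataclass
class PredictionResult:
    """Long-form prediction table plus the per-molecule rejection log."""

    table: pd.DataFrame
    rejections: pd.DataFrame = field(default_factory=pd.DataFrame)


def read_smiles_file(path: str | Path) -> list[tuple[str, str]]:
    """Read a .smi file: one SMILES per line, optional id after whitespace."""
    out = []
    for i, line in enumerate(Path(path).read_text().splitlines()):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split(None, 1)
        smiles = parts[0]
        mol_id = parts[1].strip() if len(parts) > 1 else f"mol_{i + 1}"
        out.append((mol_id, smiles))
    return out


def read_sdf_file(path: str | Path) -> list[tuple[str, str]]:
    """Read an SDF file into (id, SMILES) pairs; unparseable blocks keep
    a placeholder id and an empty SMILES so they surface as rejections."""
    out = []
    supplier = Chem.SDMolSupplier(str(path), sanitize=True)
    for i, mol in enumerate(supplier):
        if mol is None:
            out.append((f"mol_{i + 1}", ""))
            continue
        name = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"mol_{i + 1}"
        out.append((name, Chem.MolToSmiles(mol)))
    return out


def _load_molecules(molecules) -> list[tuple[str, str]]:
    if isinstance(molecules, (str, Path)):
        path = Path(molecules)
        if path.suffix.lower() == ".sdf":
            return read_sdf_file(path)
        return read_smiles_file(path)
    out = []
    for item in molecules:
        if isinstance(item, str):
            out.append((item, item))
        else:
            mol_id, smiles = item
            out.append((str(mol_id), smiles))
    return out


def predict_batch(
    suite: ModelSuite,
    molecules,
    targets: Sequence[str] | None = None,
    config: EnsembleConfig | None = None,
) -> PredictionResult:
    """Predict every (molecule x target) pair with all 16 voters.

    ``molecules`` may be a path to a .smi/.sdf file, a list of SMILES, or
    a list of (id, SMILES) pairs. Molecules beyond the batch cap raise;
    unparseable ones are skipped and listed in the rejection table.
    """
    config = config or EnsembleConfig()
    pairs = _load_molecules(molecules)
    if len(pairs) > config.batch_cap:
        raise BatchLimitError(len(pairs), config.batch_cap)
    targets = list(targets) if targets is not None else suite.target_ids

    rejections = []
    accepted: list[tuple[str, str]] = []
    for mol_id, smiles in pairs:
        try:
            accepted.append((mol_id, standardize_structure(smiles)))
        except InvalidSmilesError as exc:
            rejections.append({"compound_id": mol_id, "smiles": smiles, "reason": str(exc)})

    rows = []
    if accepted:
        smiles_list = [s for _, s in accepted]
        votes_by_target = {tid: vote_matrix(suite, smiles_list, tid) for tid in targets}
        for i, (mol_id, canonical) in enumerate(accepted):
            for tid in targets:
                vrow = votes_by_target[tid][i]
                row = {"compound_id": mol_id, "smiles": canonical, "target_id": tid}
                row.update({name: int(v) for name, v in zip(ALL_MODEL_NAMES, vrow)})
                count = int(vrow.sum())
                row["vote_count"] = count
                row["call"] = call_interaction(count, config)
                rows.append(row)
    columns = (["compound_id", "smiles", "target_id"] + list(ALL_MODEL_NAMES)
               + ["vote_count", "call"])
    table = pd.DataFrame(rows, columns=columns)
    return PredictionResult(
        table=table,
        rejections=pd.DataFrame(rejections, columns=["compound_id", "smiles", "reason"]),
    )


# -- interaction networks ----------------------------------------------------

def build_network(table: pd.DataFrame, cutoff: int | None = None) -> nx.Graph:
    """Bipartite compound-target graph with an edge per active call.

    With ``cutoff`` given, calls are re-thresholded from ``vote_count``;
    otherwise the stored ``call`` column is used. Duplicate rows collapse
    to a single edge.
    """
    graph = nx.Graph()
    if len(table) == 0:
        return graph
    if cutoff is not None:
        active = table["vote_count"] >= EnsembleConfig(cutoff=cutoff).cutoff
    else:
        active = table["call"] == ACTIVE
    for row in table[active].itertuples():
        graph.add_node(row.compound_id, kind="compound")
        graph.add_node(row.target_id, kind="target")
        graph.add_edge(row.compound_id, row.target_id)
    return graph


@dataclass
class DegreeStats:
    degrees: dict[str, int]
    median_degree: float
    mean_targets_per_compound: float
    mean_compounds_per_target: float
    empty: bool = False


def degree_stats(network: nx.Graph) -> DegreeStats:
    """Node degrees, all-node median degree, and the two bipartite means."""
    if network.number_of_nodes() == 0:
        return DegreeStats({}, float("nan"), float("nan"), float("nan"), empty=True)
    degrees = {n: d for n, d in network.degree()}
    compounds = [n for n, d in network.nodes(data=True) if d.get("kind") == "compound"]
    targets = [n for n, d in network.nodes(data=True) if d.get("kind") == "target"]
    return DegreeStats(
        degrees=degrees,
        median_degree=float(np.median(list(degrees.values()))),
        mean_targets_per_compound=(
            float(np.mean([degrees[c] for c in compounds])) if compounds else float("nan")
        ),
        mean_compounds_per_target=(
            float(np.mean([degrees[t] for t in targets])) if targets else float("nan")
        ),
    )


def filter_by_median_degree(network: nx.Graph) -> nx.Graph:
    """Keep compound nodes whose degree strictly exceeds the all-node median.

    Target nodes are always retained; edges survive only if their compound
    endpoint does. Mirrors the promiscuity filter used when focusing an
    interaction network on multitarget compounds.
    """
    if network.number_of_nodes() == 0:
        raise DomainError("cannot filter an empty network")
    stats = degree_stats(network)
    keep = {
        n for n, d in network.nodes(data=True)
        if d.get("kind") != "compound" or stats.degrees[n] > stats.median_degree
    }
    return network.subgraph(keep).copy()


def write_sif(network: nx.Graph, path: str | Path, relation: str = "interacts") -> None:
    """Write edges as SIF lines ``compound <relation> target``."""
    lines = []
    for u, v in sorted(network.edges()):
        if network.nodes[u].get("kind") == "compound":
            c, t = u, v
        else:
            c, t = v, u
        lines.append(f"{c}\t{relation}\t{t}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def write_graphml(network: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(network, str(path))
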