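"""Compound fingerprints, protein sequence descriptors, and PCM features.

Compounds are encoded either as 166-bit MACCS structural keys or as
1024-slot ECFP6 count fingerprints (circular substructures of radius 3,
hashed). Proteins are encoded from sequence alone: amino-acid composition,
dipeptide composition, optionally tripeptide composition, and the
composition/transition/distribution (CTD) descriptors over seven
physicochemical groupings. Proteochemometric (PCM) feature vectors
concatenate a compound fingerprint with a min-max-normalized,
PCA-projected protein descriptor block.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import MACCSkeys, rdFingerprintGenerator
from sklearn.decomposition import PCA

from .errors import DomainError, InvalidSmilesError, InvalidSequenceError

MACCS_BITS = 166
ECFP_BITS = 1024
ECFP_RADIUS = 3

#: Default number of protein principal components to retain. The effective
#: number is capped at min(k, n_sequences - 1, n_features).
DEFAULT_PROTEIN_COMPONENTS = 150

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

_MORGAN = rdFingerprintGenerator.GetMorganGenerator(radius=ECFP_RADIUS, fpSize=ECFP_BITS)

FAMILY_AAC = "aac"
FAMILY_DIPEPTIDE = "dipeptide"
FAMILY_TRIPEPTIDE = "tripeptide"
FAMILY_CTD = "ctd"
DEFAULT_FAMILIES = (FAMILY_AAC, FAMILY_DIPEPTIDE, FAMILY_CTD)

# Three-class physicochemical groupings of the 20 amino acids used by the
# CTD descriptors. Each grouping partitions the alphabet.
CTD_GROUPS: dict[str, tuple[str, str, str]] = {
    "hydrophobicity": ("RKEDQN", "GASTPHY", "CLVIMFW"),
    "vdw_volume": ("GASTPDC", "NVEQIL", "MHKFRYW"),
    "polarity": ("LIFWCMVY", "PATGS", "HQRKNED"),
    "polarizability": ("GASDT", "CPNVEQIL", "KMHFRYW"),
    "charge": ("KR", "ANCQGHILMFPSTWYV", "DE"),
    "secondary_structure": ("EALMQKRH", "VIYCWFT", "GNPSD"),
    "solvent_accessibility": ("ALFCGIVW", "RKQEND", "MSPTHY"),
}


def _mol(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InvalidSmilesError(smiles)
    return mol


def compute_maccs(smiles: str) -> np.ndarray:
    """166-slot binary MACCS key vector for a molecule.

    RDKit emits 167 bits with slot 0 permanently unused; it is dropped so
    the vector length matches the key dictionary.
    """
    fp = MACCSkeys.GenMACCSKeys(_mol(smiles))
    return np.asarray(fp, dtype=np.int64)[1:]


def compute_ecfp6(smiles: str) -> np.ndarray:
    """ECFP6 count fingerprint: radius-3 circular substructure occurrence
    counts hashed into 1024 slots. Entries are counts, not bits."""
    return _MORGAN.GetCountFingerprintAsNumPy(_mol(smiles)).astype(np.int64)


def fingerprint_matrix(smiles_list: Sequence[str], kind: str) -> np.ndarray:
    """Stack fingerprints of one ``kind`` ("MACCS" or "ECFP6") into a matrix."""
    fn = {"MACCS": compute_maccs, "ECFP6": compute_ecfp6}.get(kind)
    if fn is None:
        raise DomainError(f"unknown fingerprint kind {kind!r}")
    return np.vstack([fn(s) for s in smiles_list])


# -- protein sequence descriptors -------------------------------------------

def _check_sequence(sequence: str) -> str:
    if len(sequence) < 2:
        raise DomainError("sequence must have length >= 2")
    for i, letter in enumerate(sequence):
        if letter not in AMINO_ACIDS:
            raise InvalidSequenceError(letter, i)
    return sequence


def _aac(seq: str) -> pd.Series:
    n = len(seq)
    counts = {f"AAC_{a}": seq.count(a) / n for a in AMINO_ACIDS}
    return pd.Series(counts, dtype=float)


def _kmer_composition(seq: str, k: int, prefix: str) -> pd.Series:
    total = len(seq) - k + 1
    counts = dict.fromkeys(
        (prefix + "".join(p) for p in product(AMINO_ACIDS, repeat=k)), 0.0
    )
    for i in range(total):
        counts[prefix + seq[i : i + k]] += 1.0
    return pd.Series(counts, dtype=float) / total


def _ctd(seq: str) -> pd.Series:
    """Composition, transition and distribution over the seven groupings.

    Per grouping: 3 class fractions, 3 inter-class transition frequencies
    (adjacent pairs, direction-insensitive, normalized by L-1), and for each
    class the sequence positions (as % of length) at which the first, 25%,
    50%, 75% and last occurrence fall — 21 + 21 + 105 = 147 values.
    """
    n = len(seq)
    values: dict[str, float] = {}
    for prop, groups in CTD_GROUPS.items():
        cls = np.empty(n, dtype=np.int64)
        for ci, letters in enumerate(groups):
            for j, aa in enumerate(seq):
                if aa in letters:
                    cls[j] = ci
        # composition
        for ci in range(3):
            values[f"CTD_C_{prop}_{ci + 1}"] = float((cls == ci).sum()) / n
        # transitions between distinct classes among adjacent residues
        pairs = list(zip(cls[:-1], cls[1:]))
        for a, b, name in ((0, 1, "12"), (0, 2, "13"), (1, 2, "23")):
            t = sum(1 for x, y in pairs if {x, y} == {a, b})
            values[f"CTD_T_{prop}_{name}"] = t / (n - 1)
        # distribution: residue positions of occurrence quantiles, % of length
        for ci in range(3):
            pos = np.flatnonzero(cls == ci) + 1  # 1-based positions
            if len(pos) == 0:
                qvals = [0.0] * 5
            else:
                m = len(pos)
                idx = [0,
                       max(1, int(np.ceil(0.25 * m))) - 1,
                       max(1, int(np.ceil(0.50 * m))) - 1,
                       max(1, int(np.ceil(0.75 * m))) - 1,
                       m - 1]
                qvals = [pos[i] / n * 100.0 for i in idx]
            for qname, val in zip(("first", "q25", "q50", "q75", "last"), qvals):
                values[f"CTD_D_{prop}_{ci + 1}_{qname}"] = val
    return pd.Series(values, dtype=float)


def compute_protein_descriptors(
    sequence: str, families: Sequence[str] = DEFAULT_FAMILIES
) -> pd.Series:
    """Named descriptor vector for one protein sequence.

    ``families`` selects among ``aac`` (20), ``dipeptide`` (400),
    ``tripeptide`` (8000) and ``ctd`` (147). The default set (567 features)
    omits tripeptides, which dominate the runtime and add little signal for
    small target panels.
    """
    seq = _check_sequence(sequence)
    blocks = []
    for fam in families:
        if fam == FAMILY_AAC:
            blocks.append(_aac(seq))
        elif fam == FAMILY_DIPEPTIDE:
            blocks.append(_kmer_composition(seq, 2, "DPC_"))
        elif fam == FAMILY_TRIPEPTIDE:
            blocks.append(_kmer_composition(seq, 3, "TPC_"))
        elif fam == FAMILY_CTD:
            blocks.append(_ctd(seq))
        else:
            raise DomainError(f"unknown descriptor family {fam!r}")
    if not blocks:
        raise DomainError("no descriptor families enabled")
    return pd.concat(blocks)


@dataclass
class ProteinDescriptorVector:
    target_id: str
    features: pd.Series


# -- min-max scaling ---------------------------------------------------------

@dataclass
class FeatureScaler:
    """Per-feature min-max normalization to [0, 1].

    Features constant on the fit data map to 0; values outside the fitted
    range at transform time are clipped into [0, 1], so frozen scalers never
    leak out-of-range magnitudes into downstream models.
    """

    mins: np.ndarray = field(default_factory=lambda: np.empty(0))
    maxs: np.ndarray = field(default_factory=lambda: np.empty(0))

    @classmethod
    def fit(cls, matrix: np.ndarray) -> "FeatureScaler":
        matrix = np.asarray(matrix, dtype=float)
        if matrix.size == 0:
            raise DomainError("cannot fit a scaler on an empty matrix")
        return cls(mins=matrix.min(axis=0), maxs=matrix.max(axis=0))

    def transform(self, matrix: np.ndarray) -> np.ndarray:
        matrix = np.atleast_2d(np.asarray(matrix, dtype=float))
        span = self.maxs - self.mins
        safe = np.where(span > 0, span, 1.0)
        out = (matrix - self.mins) / safe
        out[:, span == 0] = 0.0
        return np.clip(out, 0.0, 1.0)

    def to_dict(self) -> dict:
        return {"mins": self.mins.tolist(), "maxs": self.maxs.tolist()}

    @classmethod
    def from_dict(cls, d: Mapping) -> "FeatureScaler":
        return cls(np.asarray(d["mins"], float), np.asarray(d["maxs"], float))


def fit_scaler(matrix: np.ndarray) -> FeatureScaler:
    return FeatureScaler.fit(matrix)


def apply_scaler(scaler: FeatureScaler, matrix: np.ndarray) -> np.ndarray:
    return scaler.transform(matrix)


# -- PCA projection ----------------------------------------------------------

@dataclass
class ProjectionModel:
    """Frozen principal-component projection of the protein descriptor block.

    ``k`` as configured may exceed what the fit matrix can support; the
    effective dimension is min(k, n_rows - 1, n_cols).
    """

    mean: np.ndarray
    components: np.ndarray  # (k_eff, n_features), rows orthonormal
    explained_variance: np.ndarray
    k_configured: int

    @property
    def k_effective(self) -> int:
        return self.components.shape[0]

    def project(self, vectors: np.ndarray) -> np.ndarray:
        vectors = np.asarray(vectors, dtype=float)
        return (np.atleast_2d(vectors) - self.mean) @ self.components.T

    def to_dict(self) -> dict:
        return {
            "mean": self.mean.tolist(),
            "components": self.components.tolist(),
            "explained_variance": self.explained_variance.tolist(),
            "k_configured": self.k_configured,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ProjectionModel":
        return cls(
            np.asarray(d["mean"], float),
            np.asarray(d["components"], float),
            np.asarray(d["explained_variance"], float),
            int(d["k_configured"]),
        )


def fit_projection(matrix: np.ndarray, k: int = DEFAULT_PROTEIN_COMPONENTS) -> ProjectionModel:
    """Fit a PCA projection with the rank-capped number of components."""
    if k < 1:
        raise DomainError("number of components must be >= 1")
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] < 2:
        raise DomainError("projection requires a matrix with >= 2 rows")
    k_eff = min(k, matrix.shape[0] - 1, matrix.shape[1])
    pca = PCA(n_components=k_eff, svd_solver="full")
    pca.fit(matrix)
    return ProjectionModel(
        mean=pca.mean_,
        components=pca.components_,
        explained_variance=pca.explained_variance_,
        k_configured=k,
    )


def project(model: ProjectionModel, vectors: np.ndarray) -> np.ndarray:
    return model.project(vectors)


def assemble_pcm(fingerprint: np.ndarray, protein_block: np.ndarray,
                 expected_k: int | None = None) -> np.ndarray:
    """Concatenate a compound fingerprint with a projected protein block."""
    fingerprint = np.asarray(fingerprint, dtype=float).ravel()
    protein_block = np.asarray(protein_block, dtype=float).ravel()
    if len(fingerprint) not in (MACCS_BITS, ECFP_BITS):
        raise DomainError(f"unexpected fingerprint length {len(fingerprint)}")
    if expected_k is not None and len(protein_block) != expected_k:
        raise DomainError(
            f"protein block length {len(protein_block)} != configured {expected_k}"
        )
    return np.concatenate([fingerprint, protein_block])
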