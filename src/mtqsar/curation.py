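"""Curation of raw bioactivity records into labelled classification sets.

Raw activity tables (compound id, SMILES, IC50, target id) are turned into
per-target binary classification datasets: structures are salt-stripped and
canonicalized, IC50 values converted to pIC50 = -log10(IC50 in mol/L),
duplicate compounds collapsed, and an activity threshold chosen so the
active/inactive classes come out as close to balanced as the pIC50
distribution allows.
"""

from __future__ import annotations

import json
import math
import statistics
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem.MolStandardize import rdMolStandardize

from .errors import ConfigError, DomainError, InvalidSmilesError

# RDKit logs every parse failure at error level; rejected SMILES are part of
# the curation contract and reported structurally instead.
RDLogger.DisableLog("rdApp.error")

#: Default grid of candidate activity thresholds, in pIC50 units.
DEFAULT_THRESHOLD_GRID: tuple[float, ...] = tuple(
    np.arange(4.0, 9.0 + 1e-9, 0.5).round(2)
)

#: Datasets smaller than this after curation are flagged as underpowered.
MIN_RECORDS = 40

#: Half-width of the ambiguity band around the threshold used when duplicate
#: measurements of one compound disagree across the threshold.
AMBIGUITY_BAND = 0.3

ACTIVE, INACTIVE = "active", "inactive"

_UNCHARGER = rdMolStandardize.Uncharger()

_UNIT_TO_MOLAR = {"M": 1.0, "mM": 1e-3, "uM": 1e-6, "nM": 1e-9, "pM": 1e-12}


@dataclass(frozen=True)
class RawActivityRecord:
    """One measured activity as it arrives from an external export."""

    compound_id: str
    smiles: str
    ic50: float  # in the unit named by ``unit``
    target_id: str
    unit: str = "M"

    def ic50_molar(self) -> float:
        if self.unit not in _UNIT_TO_MOLAR:
            raise DomainError(f"unknown concentration unit {self.unit!r}")
        return self.ic50 * _UNIT_TO_MOLAR[self.unit]


@dataclass(frozen=True)
class CompoundRecord:
    """A curated compound: canonical parent structure, pIC50 and class label."""

    compound_id: str
    canonical_smiles: str
    pic50: float
    label: str | None = None  # "active" / "inactive" once thresholded

    def with_label(self, threshold: float) -> "CompoundRecord":
        lab = ACTIVE if self.pic50 >= threshold else INACTIVE
        return CompoundRecord(self.compound_id, self.canonical_smiles, self.pic50, lab)


@dataclass
class Rejection:
    """A record dropped during curation, with the reason."""

    compound_id: str
    smiles: str
    reason: str


@dataclass
class ActivityDataset:
    """Curated, deduplicated, threshold-labelled dataset for one target."""

    target_id: str
    records: list[CompoundRecord]
    threshold: float
    rejections: list[Rejection] = field(default_factory=list)
    underpowered: bool = False

    @property
    def n_active(self) -> int:
        return sum(r.label == ACTIVE for r in self.records)

    @property
    def n_inactive(self) -> int:
        return sum(r.label == INACTIVE for r in self.records)

    def __len__(self) -> int:
        return len(self.records)

    def smiles(self) -> list[str]:
        return [r.canonical_smiles for r in self.records]

    def labels(self) -> np.ndarray:
        """Binary label vector, 1 = active."""
        return np.array([1 if r.label == ACTIVE else 0 for r in self.records])

    def pic50s(self) -> np.ndarray:
        return np.array([r.pic50 for r in self.records])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "compound_id": [r.compound_id for r in self.records],
                "canonical_smiles": [r.canonical_smiles for r in self.records],
                "pic50": [r.pic50 for r in self.records],
                "label": [r.label for r in self.records],
            }
        )

    def validate(self) -> None:
        """Check the dataset invariants; raise ``AssertionError`` on violation."""
        seen = set()
        for r in self.records:
            assert r.canonical_smiles not in seen, "duplicate canonical SMILES"
            seen.add(r.canonical_smiles)
            assert math.isfinite(r.pic50)
            expected = ACTIVE if r.pic50 >= self.threshold else INACTIVE
            assert r.label == expected, "label inconsistent with threshold"
        assert self.n_active + self.n_inactive == len(self.records)

    # -- serialization ------------------------------------------------------

    def write(self, csv_path: str | Path) -> None:
        """Write the curated table plus a JSON sidecar with the metadata."""
        csv_path = Path(csv_path)
        self.to_frame().to_csv(csv_path, index=False)
        sidecar = {
            "target_id": self.target_id,
            "threshold": self.threshold,
            "n_active": self.n_active,
            "n_inactive": self.n_inactive,
            "n_records": len(self.records),
            "underpowered": self.underpowered,
            "rejections": [vars(r) for r in self.rejections],
        }
        csv_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def read(cls, csv_path: str | Path) -> "ActivityDataset":
        csv_path = Path(csv_path)
        frame = pd.read_csv(csv_path)
        meta = json.loads(csv_path.with_suffix(".json").read_text())
        records = [
            CompoundRecord(str(row.compound_id), row.canonical_smiles, float(row.pic50), row.label)
            for row in frame.itertuples()
        ]
        ds = cls(
            target_id=meta["target_id"],
            records=records,
            threshold=float(meta["threshold"]),
            rejections=[Rejection(**r) for r in meta.get("rejections", [])],
            underpowered=bool(meta.get("underpowered", False)),
        )
        ds.validate()
        return ds


def standardize_structure(smiles: str) -> str:
    """Canonical SMILES of the neutralized parent (largest) fragment.

    Salt forms are reduced to the largest covalent fragment by heavy-atom
    count (ties broken by lexicographically smallest canonical SMILES), and
    formal charges are neutralized where chemically possible. The operation
    is idempotent.

    Raises
    ------
    InvalidSmilesError
        If the input does not parse.
    """
    if not smiles or not smiles.strip():
        raise InvalidSmilesError(smiles, "empty SMILES")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InvalidSmilesError(smiles)
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=True)
    if not frags:
        raise InvalidSmilesError(smiles, "no fragments")
    parent = min(frags, key=lambda f: (-f.GetNumHeavyAtoms(), Chem.MolToSmiles(f)))
    parent = _UNCHARGER.uncharge(parent)
    return Chem.MolToSmiles(parent)


def to_pic50(ic50_molar: float) -> float:
    """pIC50 = -log10 of a molar IC50.

    Raises
    ------
    DomainError
        If ``ic50_molar`` is not strictly positive (or not finite).
    """
    if not (ic50_molar > 0) or not math.isfinite(ic50_molar):
        raise DomainError(f"IC50 must be a positive finite molar value, got {ic50_molar}")
    return -math.log10(ic50_molar)


def deduplicate(records: Sequence[CompoundRecord]) -> list[CompoundRecord]:
    """Collapse records sharing a canonical SMILES to one per structure.

    When duplicate measurements disagree, the retained pIC50 is their median
    (robust to the occasional wild assay value). The surviving compound id is
    the lexicographically smallest among the duplicates, and the output is
    sorted by canonical SMILES so the result is order-independent.
    """
    return [rec for rec, _ in _deduplicate_with_spread(records)]


def _deduplicate_with_spread(
    records: Sequence[CompoundRecord],
) -> list[tuple[CompoundRecord, tuple[float, float]]]:
    """Deduplicate and keep each structure's (min, max) duplicate pIC50 spread."""
    groups: dict[str, list[CompoundRecord]] = {}
    for rec in records:
        groups.setdefault(rec.canonical_smiles, []).append(rec)
    out = []
    for smi in sorted(groups):
        grp = groups[smi]
        pic50 = float(statistics.median(r.pic50 for r in grp))
        cid = min(r.compound_id for r in grp)
        spread = (min(r.pic50 for r in grp), max(r.pic50 for r in grp))
        out.append((CompoundRecord(cid, smi, pic50), spread))
    return out


def select_balance_threshold(
    pic50s: Sequence[float], candidates: Sequence[float] | None = None
) -> float:
    """Pick the candidate threshold giving the most balanced class split.

    The threshold minimizing ``|#{p >= t} - #{p < t}|`` is returned; ties are
    broken by the smallest candidate, which favours the active class.
    """
    if len(pic50s) == 0:
        raise DomainError("cannot choose a threshold for an empty pIC50 list")
    cands = sorted(candidates) if candidates is not None else list(DEFAULT_THRESHOLD_GRID)
    if not cands:
        raise DomainError("empty candidate threshold list")
    vals = np.asarray(pic50s, dtype=float)

    def imbalance(t: float) -> int:
        n_act = int((vals >= t).sum())
        return abs(n_act - (len(vals) - n_act))

    return float(min(cands, key=lambda t: (imbalance(t), t)))


def build_dataset(
    raw: Iterable[RawActivityRecord],
    target_id: str,
    candidates: Sequence[float] | None = None,
    min_records: int = MIN_RECORDS,
) -> ActivityDataset:
    """Run the full curation chain for one target.

    standardize -> pIC50 -> deduplicate -> balance threshold -> label.
    Unparseable structures are skipped and reported in ``rejections``;
    compounds whose duplicate measurements straddle the chosen threshold with
    a median inside the ambiguity band are dropped as unlabelable.
    """
    rejections: list[Rejection] = []
    curated: list[CompoundRecord] = []
    for rec in raw:
        if rec.target_id != target_id:
            raise DomainError(
                f"record {rec.compound_id} is for target {rec.target_id!r}, "
                f"expected {target_id!r}"
            )
        try:
            smi = standardize_structure(rec.smiles)
            pic50 = to_pic50(rec.ic50_molar())
        except (InvalidSmilesError, DomainError) as exc:
            rejections.append(Rejection(rec.compound_id, rec.smiles, str(exc)))
            continue
        curated.append(CompoundRecord(rec.compound_id, smi, pic50))

    deduped = _deduplicate_with_spread(curated)
    if not deduped:
        return ActivityDataset(target_id, [], threshold=float("nan"),
                               rejections=rejections, underpowered=True)

    threshold = select_balance_threshold([r.pic50 for r, _ in deduped], candidates)

    records: list[CompoundRecord] = []
    for rec, (lo, hi) in deduped:
        straddles = lo < threshold <= hi
        if straddles and abs(rec.pic50 - threshold) <= AMBIGUITY_BAND:
            rejections.append(
                Rejection(rec.compound_id, rec.canonical_smiles,
                          "ambiguous duplicate activity at the threshold")
            )
            continue
        records.append(rec.with_label(threshold))

    ds = ActivityDataset(
        target_id,
        records,
        threshold=threshold,
        rejections=rejections,
        underpowered=len(records) < min_records,
    )
    ds.validate()
    return ds


# -- tabular ingestion -------------------------------------------------------

def read_activity_table(
    path: str | Path, default_unit: str = "M"
) -> dict[str, list[RawActivityRecord]]:
    """Read a CSV/TSV activity table and group records by target.

    Expected columns: ``compound_id, smiles, ic50, target_id`` plus an
    optional ``unit`` column; ``default_unit`` applies where absent.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    frame = pd.read_csv(path, sep=sep)
    required = {"compound_id", "smiles", "ic50", "target_id"}
    missing = required - set(frame.columns)
    if missing:
        raise ConfigError(f"{path}: missing required columns {sorted(missing)}")
    by_target: dict[str, list[RawActivityRecord]] = {}
    for row in frame.itertuples():
        unit = getattr(row, "unit", default_unit)
        rec = RawActivityRecord(
            compound_id=str(row.compound_id),
            smiles=str(row.smiles),
            ic50=float(row.ic50),
            target_id=str(row.target_id),
            unit=str(unit),
        )
        by_target.setdefault(rec.target_id, []).append(rec)
    return by_target


def curate_all(
    by_target: dict[str, list[RawActivityRecord]],
    candidates: Sequence[float] | None = None,
    min_records: int = MIN_RECORDS,
) -> dict[str, ActivityDataset]:
    """Curate every target's record list into an :class:`ActivityDataset`."""
    return {
        tid: build_dataset(recs, tid, candidates=candidates, min_records=min_records)
        for tid, recs in sorted(by_target.items())
    }
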