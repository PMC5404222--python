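"""Labelled screening tables: pK conversion, active/decoy labelling,
DUD-E-style directory ingestion and near-duplicate ligand filtering.

Labelling convention: a molecule with a measured affinity (IC50, EC50, Ki
or Kd) of 1 μM or better (pK ≥ 6) is active; weaker measured molecules
keep their measured pK but are inactive; structureless decoys are imputed
a constant pK of 5.95, just under the activity cutoff, so a regression
model can train on a realistic active:decoy imbalance.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .complex_io import best_pose, parse_ligand_poses, parse_protein
from .descriptors import DEFAULT_CONFIG, DescriptorConfig, feature_names, featurize

logger = logging.getLogger(__name__)

MEASURES = ("IC50", "EC50", "Ki", "Kd")

_UNIT_TO_MOLAR = {
    "M": 1.0,
    "mM": 1e-3,
    "uM": 1e-6,
    "μM": 1e-6,
    "µM": 1e-6,
    "nM": 1e-9,
    "pM": 1e-12,
}


def to_pk(value: float, unit: str = "M") -> float:
    """Convert a concentration-type affinity to pK units: −log10(value in M).

    >>> to_pk(1, "uM")
    6.0
    """
    if unit not in _UNIT_TO_MOLAR:
        raise ValueError(f"unknown unit {unit!r}; expected one of {sorted(_UNIT_TO_MOLAR)}")
    molar = float(value) * _UNIT_TO_MOLAR[unit]
    if molar <= 0:
        raise ValueError(f"affinity must be positive, got {value} {unit}")
    return -math.log10(molar)


@dataclass(frozen=True)
class LabelConfig:
    active_cutoff_pk: float = 6.0
    inactive_label: float = 5.95

    def __post_init__(self) -> None:
        if not self.inactive_label < self.active_cutoff_pk:
            raise ValueError("inactive_label must lie below active_cutoff_pk")


DEFAULT_LABELS = LabelConfig()


@dataclass(frozen=True)
class ActivityRecord:
    molecule_id: str
    target_id: str
    measure: str  # IC50 / EC50 / Ki / Kd / decoy
    pk: float
    is_active: bool
    raw_value: float | None = None  # molar, None for decoys

    @property
    def is_decoy(self) -> bool:
        return self.measure == "decoy"


def label_records(
    raw: pd.DataFrame, config: LabelConfig = DEFAULT_LABELS
) -> list[ActivityRecord]:
    """Label a raw activity table (columns: molecule_id, target_id, measure,
    value, unit, decoy_flag).

    Decoys receive the constant imputed pK; measured rows convert through
    ``to_pk`` and are active iff pk ≥ the cutoff.  A row with neither a
    measured affinity nor a decoy flag is an error.
    """
    records: list[ActivityRecord] = []
    for row in raw.itertuples(index=False):
        mol_id, target_id = str(row.molecule_id), str(row.target_id)
        decoy = bool(getattr(row, "decoy_flag", False))
        if decoy:
            records.append(
                ActivityRecord(mol_id, target_id, "decoy", config.inactive_label, False)
            )
            continue
        value = getattr(row, "value", None)
        if value is None or (isinstance(value, float) and np.isnan(value)):
            raise ValueError(
                f"row for molecule {mol_id!r} on target {target_id!r} has neither "
                "a measured affinity nor a decoy flag"
            )
        measure = str(getattr(row, "measure", "Ki"))
        if measure not in MEASURES:
            raise ValueError(f"unknown affinity measure {measure!r} for {mol_id!r}")
        unit = str(getattr(row, "unit", "M"))
        pk = to_pk(float(value), unit)
        records.append(
            ActivityRecord(
                mol_id,
                target_id,
                measure,
                pk,
                pk >= config.active_cutoff_pk,
                raw_value=float(value) * _UNIT_TO_MOLAR[unit],
            )
        )
    return records


# ---------------------------------------------------------------------------
# dataset container

@dataclass
class ScreeningDataset:
    """Labelled records plus one feature vector per (target, molecule).

    ``records`` rows align with ``features`` rows; each record is the best
    docked pose of one molecule against one target.
    """

    records: pd.DataFrame  # target_id, molecule_id, pk, is_active, is_decoy
    features: np.ndarray
    feature_names: tuple[str, ...]
    feature_version: str

    def __post_init__(self) -> None:
        self.records = self.records.reset_index(drop=True)
        self.features = np.asarray(self.features, dtype=float)
        if len(self.records) != len(self.features):
            raise ValueError("records/features row mismatch")
        if self.features.ndim != 2 or self.features.shape[1] != len(self.feature_names):
            raise ValueError("feature matrix does not match feature_names")
        dup = self.records.duplicated(["target_id", "molecule_id"])
        if dup.any():
            raise ValueError("duplicate (target_id, molecule_id) records")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def targets(self) -> list[str]:
        return list(dict.fromkeys(self.records["target_id"]))

    def subset(self, mask: np.ndarray) -> "ScreeningDataset":
        mask = np.asarray(mask)
        return ScreeningDataset(
            self.records.loc[mask].copy(),
            self.features[mask],
            self.feature_names,
            self.feature_version,
        )

    def to_frame(self) -> pd.DataFrame:
        """Single flat table: label columns followed by feature columns."""
        feats = pd.DataFrame(self.features, columns=list(self.feature_names))
        return pd.concat([self.records.reset_index(drop=True), feats], axis=1)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, feature_version: str) -> "ScreeningDataset":
        label_cols = [c for c in ("target_id", "molecule_id", "pk", "is_active", "is_decoy") if c in frame.columns]
        feat_cols = [c for c in frame.columns if c not in label_cols]
        return cls(
            frame[label_cols].copy(),
            frame[feat_cols].to_numpy(dtype=float),
            tuple(feat_cols),
            feature_version,
        )

    @classmethod
    def from_csv(cls, path, feature_version: str) -> "ScreeningDataset":
        return cls.from_frame(pd.read_csv(path), feature_version)


# ---------------------------------------------------------------------------
# DUD-E-style directory ingestion

@dataclass(frozen=True)
class LayoutPatterns:
    """File names inside each per-target subdirectory."""

    receptor: str = "receptor.pdb"
    actives: str = "actives.sdf"
    decoys: str = "decoys.sdf"


def ingest_dude_layout(
    root,
    version: str = "v1",
    *,
    config: DescriptorConfig = DEFAULT_CONFIG,
    labels: LabelConfig = DEFAULT_LABELS,
    patterns: LayoutPatterns = LayoutPatterns(),
    score_property: str = "minimizedAffinity",
    pk_property: str = "pK",
    strict: bool = False,
) -> ScreeningDataset:
    """Featurize and label a per-target directory tree.

    Each subdirectory of ``root`` is one target holding a receptor PDB and
    multi-pose actives/decoys SDF files.  Per molecule the best-scoring
    pose is kept and featurized with the requested descriptor version.
    Actives carry their measured pK as an SD property (``pk_property``).
    Targets with a missing receptor are skipped with a warning unless
    ``strict``.
    """
    root = Path(root)
    rows, feats = [], []
    target_dirs = sorted(p for p in root.iterdir() if p.is_dir()) if root.exists() else []
    if not target_dirs:
        logger.warning("no target subdirectories found under %s", root)
    names = feature_names(version, config)
    manifest = {}
    for tdir in target_dirs:
        receptor_path = tdir / patterns.receptor
        if not receptor_path.exists():
            if strict:
                raise FileNotFoundError(receptor_path)
            logger.warning("target %s skipped: missing receptor %s", tdir.name, receptor_path)
            continue
        protein = parse_protein(receptor_path, target_id=tdir.name)
        counts = {"actives": 0, "decoys": 0}
        for role, fname in (("actives", patterns.actives), ("decoys", patterns.decoys)):
            fpath = tdir / fname
            if not fpath.exists():
                logger.warning("target %s has no %s file", tdir.name, role)
                continue
            poses = parse_ligand_poses(
                fpath, score_property=score_property, strict=strict
            )
            by_mol: dict[str, list] = {}
            for pose in poses:
                by_mol.setdefault(pose.molecule_id, []).append(pose)
            for mol_id, mol_poses in by_mol.items():
                pose = best_pose(mol_poses)
                fv = featurize(protein, pose, version, config)
                if role == "decoys":
                    pk, active, decoy = labels.inactive_label, False, True
                else:
                    pk = _active_pk(fpath, mol_poses, pk_property, labels)
                    active, decoy = pk >= labels.active_cutoff_pk, False
                rows.append(
                    {
                        "target_id": tdir.name,
                        "molecule_id": mol_id,
                        "pk": pk,
                        "is_active": active,
                        "is_decoy": decoy,
                        "docking_score": pose.docking_score,
                    }
                )
                feats.append(fv.values)
                counts[role] += 1
        manifest[tdir.name] = counts
        logger.info(
            "target %s: %d actives, %d decoys", tdir.name, counts["actives"], counts["decoys"]
        )
    records = pd.DataFrame(
        rows,
        columns=["target_id", "molecule_id", "pk", "is_active", "is_decoy", "docking_score"],
    )
    features = np.array(feats, dtype=float) if feats else np.zeros((0, len(names)))
    ds = ScreeningDataset(records, features, names, version)
    ds.manifest = manifest  # type: ignore[attr-defined]
    return ds


def _active_pk(fpath, mol_poses, pk_property: str, labels: LabelConfig) -> float:
    """Measured pK for an active, read from the pose file's SD property."""
    from rdkit import Chem

    # the pose objects no longer carry SD properties, so re-read lazily once
    cache_attr = "_rfscreen_pk_cache"
    cache = getattr(_active_pk, cache_attr, {})
    key = str(fpath)
    if key not in cache:
        by_name = {}
        for mol in Chem.SDMolSupplier(str(fpath), removeHs=False, sanitize=False):
            if mol is None or not mol.HasProp("_Name"):
                continue
            if mol.HasProp(pk_property):
                by_name[mol.GetProp("_Name").strip()] = float(mol.GetProp(pk_property))
        cache[key] = by_name
        setattr(_active_pk, cache_attr, cache)
    mol_id = mol_poses[0].molecule_id
    try:
        return cache[key][mol_id]
    except KeyError:
        raise ValueError(
            f"active {mol_id!r} in {fpath} lacks the {pk_property!r} property"
        ) from None


# ---------------------------------------------------------------------------
# near-duplicate filtering

def _path_fingerprint(smiles: str):
    from rdkit import Chem

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    return Chem.RDKFingerprint(mol, minPath=1, maxPath=7, fpSize=1024)


def near_duplicate_filter(
    query_smiles: Sequence[str],
    reference_smiles: Sequence[str],
    threshold: float = 0.99,
) -> tuple[list[str], pd.DataFrame]:
    """Drop query molecules nearly identical to any reference molecule.

    Similarity is Tanimoto on hashed linear-path fingerprints (paths of
    1–7 bonds, 1024 bits); a query at or above ``threshold`` against any
    reference is removed.  Unparseable queries are removed and logged.
    Returns (retained SMILES, removal report).
    """
    from rdkit import DataStructs

    ref_fps = [fp for fp in (_path_fingerprint(s) for s in reference_smiles) if fp is not None]
    retained: list[str] = []
    report_rows = []
    for smi in query_smiles:
        fp = _path_fingerprint(smi)
        if fp is None:
            logger.warning("unparseable query molecule %r removed", smi)
            report_rows.append({"smiles": smi, "removed": True, "max_similarity": np.nan})
            continue
        sims = [DataStructs.TanimotoSimilarity(fp, ref) for ref in ref_fps]
        max_sim = max(sims) if sims else 0.0
        removed = max_sim >= threshold
        report_rows.append({"smiles": smi, "removed": removed, "max_similarity": max_sim})
        if not removed:
            retained.append(smi)
    report = pd.DataFrame(report_rows, columns=["smiles", "removed", "max_similarity"])
    return retained, report
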