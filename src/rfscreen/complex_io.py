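"""Reading docked protein-ligand complexes into a uniform atomic representation.

Proteins come from PDB files (all chains, heavy atoms; hydrogens are kept
but flagged, waters and heteroatoms are dropped unless asked for).  Ligand
poses come from multi-record SDF or MOL2 files as written by docking
engines, one pose per record, with the engine's score read from a named
record property.  Everything downstream works on plain ``Atom`` tuples so
no RDKit/Biopython object leaks out of this module.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

# atomic numbers for every element this package ever sees; extend freely
_ATOMIC_NUMBERS = {
    "H": 1, "B": 5, "C": 6, "N": 7, "O": 8, "F": 9, "Na": 11, "Mg": 12,
    "Al": 13, "Si": 14, "P": 15, "S": 16, "Cl": 17, "K": 19, "Ca": 20,
    "Mn": 25, "Fe": 26, "Co": 27, "Ni": 28, "Cu": 29, "Zn": 30, "Br": 35,
    "I": 53, "Se": 34,
}

_WATER_RESNAMES = {"HOH", "WAT", "DOD", "H2O"}


class ParseError(ValueError):
    """Raised when a structure file cannot be parsed."""


class EmptyStructureError(ParseError):
    """Raised when a parsed structure contains no heavy atoms."""


def _normalize_element(symbol: str) -> str:
    sym = "".join(ch for ch in symbol.strip() if ch.isalpha())
    if not sym:
        raise ParseError(f"cannot derive an element from symbol {symbol!r}")
    return sym.capitalize()


def atomic_number(element: str) -> int:
    """Atomic number for an element symbol; unknown symbols raise KeyError."""
    elem = _normalize_element(element)
    try:
        return _ATOMIC_NUMBERS[elem]
    except KeyError:
        raise KeyError(f"element {elem!r} not in the atomic-number table") from None


@dataclass(frozen=True)
class Atom:
    """A typed point atom: element plus Cartesian coordinates in Å."""

    element: str
    x: float
    y: float
    z: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "element", _normalize_element(self.element))
        if not all(np.isfinite([self.x, self.y, self.z])):
            raise ValueError(f"non-finite coordinates for atom {self.element}")

    @property
    def atomic_number(self) -> int:
        return atomic_number(self.element)

    @property
    def is_heavy(self) -> bool:
        return self.atomic_number > 1

    @property
    def coords(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


def _heavy(atoms: Sequence[Atom]) -> list[Atom]:
    return [a for a in atoms if a.is_heavy]


def heavy_arrays(atoms: Sequence[Atom]) -> tuple[np.ndarray, np.ndarray]:
    """(elements, coords) arrays restricted to heavy atoms."""
    heavy = _heavy(atoms)
    elements = np.array([a.element for a in heavy], dtype=object)
    coords = (
        np.array([[a.x, a.y, a.z] for a in heavy], dtype=float)
        if heavy
        else np.zeros((0, 3))
    )
    return elements, coords


@dataclass(frozen=True)
class ProteinStructure:
    target_id: str
    atoms: tuple[Atom, ...]
    source_path: str = ""

    def __post_init__(self) -> None:
        if not _heavy(self.atoms):
            raise EmptyStructureError(
                f"protein {self.target_id!r} contains no heavy atoms"
            )

    @property
    def n_heavy(self) -> int:
        return len(_heavy(self.atoms))


@dataclass(frozen=True)
class LigandPose:
    molecule_id: str
    pose_id: int
    atoms: tuple[Atom, ...]
    docking_score: float
    n_rotatable_bonds: int = 0
    smiles: str | None = None

    def __post_init__(self) -> None:
        if self.pose_id < 0:
            raise ValueError("pose_id must be non-negative")
        if self.n_rotatable_bonds < 0:
            raise ValueError("n_rotatable_bonds must be non-negative")
        if not _heavy(self.atoms):
            raise EmptyStructureError(
                f"ligand {self.molecule_id!r} pose {self.pose_id} has no heavy atoms"
            )

    @property
    def n_heavy(self) -> int:
        return len(_heavy(self.atoms))


@dataclass(frozen=True)
class ComplexRecord:
    """One protein + one docked ligand pose, the unit the featurizer scores."""

    target_id: str
    molecule_id: str
    pose: LigandPose
    protein: ProteinStructure


# ---------------------------------------------------------------------------
# protein parsing

def parse_protein(
    path: str | Path,
    format: str = "pdb",
    *,
    target_id: str | None = None,
    keep_heteroatoms: bool = False,
) -> ProteinStructure:
    """Read a protein from a PDB file.

    All chains are retained.  Waters are always dropped; other hetero
    residues (cofactors, ions) are dropped unless ``keep_heteroatoms``.
    Hydrogens are parsed but flagged via ``Atom.is_heavy``.  The element is
    taken from the element column when present and inferred from the atom
    name otherwise.
    """
    if format.lower() != "pdb":
        raise ValueError(f"unsupported protein format {format!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)

    from Bio.PDB import PDBParser
    from Bio.PDB.PDBExceptions import PDBConstructionWarning

    parser = PDBParser(PERMISSIVE=True, QUIET=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", PDBConstructionWarning)
            structure = parser.get_structure(path.stem, str(path))
    except Exception as exc:  # Biopython raises assorted exception types
        raise ParseError(f"cannot parse PDB file {path}: {exc}") from exc

    atoms: list[Atom] = []
    for residue in structure.get_residues():
        hetfield = residue.id[0].strip()
        resname = residue.get_resname().strip()
        if resname in _WATER_RESNAMES or hetfield == "W":
            continue
        if hetfield and not keep_heteroatoms:
            continue
        for bio_atom in residue.get_atoms():
            element = bio_atom.element or bio_atom.get_name()
            x, y, z = (float(c) for c in bio_atom.coord)
            atoms.append(Atom(element, x, y, z))

    if not any(a.is_heavy for a in atoms):
        raise EmptyStructureError(f"no heavy protein atoms found in {path}")
    return ProteinStructure(
        target_id=target_id or path.stem,
        atoms=tuple(atoms),
        source_path=str(path),
    )


# ---------------------------------------------------------------------------
# ligand parsing

#: default SD tag carrying the docking score (smina/Vina convention)
DEFAULT_SCORE_PROPERTY = "minimizedAffinity"


def _count_rotatable_bonds(mol) -> int:
    """Strict rotor count: single, acyclic, non-terminal heavy-atom bonds,
    amides excluded.  Counted on the heavy-atom skeleton so explicit
    hydrogens cannot turn a terminal bond into an apparent rotor."""
    from rdkit import Chem
    from rdkit.Chem import rdMolDescriptors

    return int(
        rdMolDescriptors.CalcNumRotatableBonds(
            Chem.RemoveHs(mol), rdMolDescriptors.NumRotatableBondsOptions.Strict
        )
    )


def _mol_to_pose(mol, pose_id: int, score_property: str, record_label: str) -> LigandPose:
    from rdkit import Chem

    if not mol.HasProp(score_property):
        raise ParseError(
            f"record {record_label} lacks the docking-score property "
            f"{score_property!r}"
        )
    try:
        docking_score = float(mol.GetProp(score_property))
    except ValueError as exc:
        raise ParseError(
            f"record {record_label}: score property {score_property!r} is not numeric"
        ) from exc

    conf = mol.GetConformer()
    atoms = []
    for rd_atom in mol.GetAtoms():
        pos = conf.GetAtomPosition(rd_atom.GetIdx())
        atoms.append(Atom(rd_atom.GetSymbol(), pos.x, pos.y, pos.z))
    name = mol.GetProp("_Name").strip() if mol.HasProp("_Name") else ""
    return LigandPose(
        molecule_id=name or record_label,
        pose_id=pose_id,
        atoms=tuple(atoms),
        docking_score=docking_score,
        n_rotatable_bonds=_count_rotatable_bonds(mol),
        smiles=Chem.MolToSmiles(Chem.RemoveHs(mol)),
    )


def _iter_sdf_mols(path: Path):
    from rdkit import Chem

    supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=True)
    yield from supplier


def _iter_mol2_mols(path: Path):
    """Split a multi-record MOL2 file and parse each block with RDKit.

    MOL2 has no SD-style property block; key/value pairs are read from
    ``# key: value`` comment lines inside each record and attached as mol
    properties.
    """
    from rdkit import Chem

    text = path.read_text()
    blocks = ["@<TRIPOS>MOLECULE" + b for b in text.split("@<TRIPOS>MOLECULE")[1:]]
    if not blocks:
        raise ParseError(f"{path} contains no @<TRIPOS>MOLECULE record")
    for block in blocks:
        mol = Chem.MolFromMol2Block(block, removeHs=False, sanitize=True)
        if mol is not None:
            for line in block.splitlines():
                line = line.strip()
                if line.startswith("#") and ":" in line:
                    key, _, value = line.lstrip("# ").partition(":")
                    mol.SetProp(key.strip(), value.strip())
        yield mol


def parse_ligand_poses(
    path: str | Path,
    format: str | None = None,
    *,
    score_property: str = DEFAULT_SCORE_PROPERTY,
    molecule_id: str | None = None,
    strict: bool = False,
) -> list[LigandPose]:
    """Read docked ligand poses from a multi-record SDF or MOL2 file.

    ``pose_id`` is assigned in file order starting at 0.  A record that
    fails to parse is skipped with a warning (``strict=True`` raises); a
    record missing the docking-score property always raises, naming the
    record.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "sdf":
        mols = _iter_sdf_mols(path)
    elif fmt == "mol2":
        mols = _iter_mol2_mols(path)
    else:
        raise ValueError(f"unsupported ligand format {fmt!r}")

    poses: list[LigandPose] = []
    pose_id = 0
    for index, mol in enumerate(mols):
        label = f"{path.name}[{index}]"
        if mol is None:
            if strict:
                raise ParseError(f"malformed ligand record {label}")
            logger.warning("skipping malformed ligand record %s", label)
            continue
        pose = _mol_to_pose(mol, pose_id, score_property, label)
        if molecule_id is not None:
            pose = LigandPose(
                molecule_id=molecule_id,
                pose_id=pose.pose_id,
                atoms=pose.atoms,
                docking_score=pose.docking_score,
                n_rotatable_bonds=pose.n_rotatable_bonds,
                smiles=pose.smiles,
            )
        poses.append(pose)
        pose_id += 1
    return poses


def best_pose(poses: Iterable[LigandPose]) -> LigandPose:
    """The pose with the lowest docking score (docking scores are energies,
    lower is better); ties broken by lowest pose_id."""
    poses = list(poses)
    if not poses:
        raise ValueError("best_pose requires a non-empty pose collection")
    molecule_ids = {p.molecule_id for p in poses}
    if len(molecule_ids) > 1:
        raise ValueError(f"poses belong to multiple molecules: {sorted(molecule_ids)}")
    return min(poses, key=lambda p: (p.docking_score, p.pose_id))


# ---------------------------------------------------------------------------
# writers (round-trip support and synthetic fixtures)

def write_pdb(structure: ProteinStructure, path: str | Path) -> None:
    """Write a minimal single-chain PDB file (ATOM records only)."""
    path = Path(path)
    lines = []
    for i, atom in enumerate(structure.atoms, start=1):
        # one residue per atom: duplicate atom names inside a residue would
        # be collapsed by standards-following readers
        name = atom.element.upper().rjust(2)
        lines.append(
            f"ATOM  {i:5d} {name:<4s} UNK A{i % 10000:4d}    "
            f"{atom.x:8.3f}{atom.y:8.3f}{atom.z:8.3f}  1.00  0.00          "
            f"{atom.element.upper():>2s}"
        )
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


def write_sdf(
    poses: Sequence[LigandPose],
    path: str | Path,
    *,
    score_property: str = DEFAULT_SCORE_PROPERTY,
    extra_properties: Sequence[dict] | None = None,
) -> None:
    """Write poses to a V2000 multi-record SDF (atoms only, no bonds).

    Good enough for descriptor work, which only needs elements and
    coordinates; rotor counts of re-parsed files are therefore 0.
    """
    path = Path(path)
    chunks = []
    for i, pose in enumerate(poses):
        n = len(pose.atoms)
        lines = [pose.molecule_id, "  rfscreen          3D", ""]
        lines.append(f"{n:3d}{0:3d}  0  0  0  0  0  0  0  0999 V2000")
        for atom in pose.atoms:
            lines.append(
                f"{atom.x:10.4f}{atom.y:10.4f}{atom.z:10.4f} "
                f"{atom.element:<3s} 0  0  0  0  0  0  0  0  0  0  0  0"
            )
        lines.append("M  END")
        props = {score_property: repr(pose.docking_score)}
        if extra_properties is not None:
            props.update({k: str(v) for k, v in extra_properties[i].items()})
        for key, value in props.items():
            lines.append(f">  <{key}>")
            lines.append(value)
            lines.append("")
        lines.append("$$$$")
        chunks.append("\n".join(lines))
    path.write_text("\n".join(chunks) + "\n")
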