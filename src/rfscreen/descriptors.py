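"""Element-pair contact descriptors and Vina-style empirical terms.

The descriptor is a census of protein-ligand heavy-atom pairs within a
12 Å cutoff, indexed by (protein element, ligand element) over the classic
4 × 9 grid — protein {C,N,O,S}, ligand {C,N,O,F,P,S,Cl,Br,I}:

* v1 — one distance bin [0, 12] Å → 36 integer counts;
* v2 — six 2 Å bins (0–2, …, 10–12 Å) → 216 integer counts;
* v3 — the 36 v1 counts plus six empirical terms in the AutoDock Vina
  functional form (gauss1, gauss2, repulsion, hydrophobic, hbond, and the
  ligand rotor count) → 42 values.

Bins are half-open [lo, hi) except the last, which closes at the cutoff so
a pair at exactly 12.0 Å is still tallied.  Atoms whose element is outside
the configured grids contribute nothing to the counts but do contribute to
the Vina pair terms whenever their van-der-Waals radius is known, matching
Vina's own behaviour.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .complex_io import Atom, LigandPose, ProteinStructure, heavy_arrays

PROTEIN_ELEMENTS: tuple[str, ...] = ("C", "N", "O", "S")
LIGAND_ELEMENTS: tuple[str, ...] = ("C", "N", "O", "F", "P", "S", "Cl", "Br", "I")

#: Vina (X-score) van-der-Waals radii in Å, used for the surface distance
#: d = r - (R_i + R_j) in the empirical terms.
VDW_RADII: dict[str, float] = {
    "C": 1.9, "N": 1.8, "O": 1.7, "F": 1.5, "P": 2.1, "S": 2.0,
    "Cl": 1.8, "Br": 2.0, "I": 2.2,
    "Mg": 1.2, "Mn": 1.2, "Zn": 1.2, "Ca": 1.2, "Fe": 1.2,
    "Na": 1.2, "K": 1.2, "Cu": 1.2, "Ni": 1.2, "Co": 1.2, "Se": 1.9,
}

#: pair-term interatomic distance cutoff in Å (Vina's own)
VINA_PAIR_CUTOFF = 8.0

#: heavy-atom covalent contact threshold used to infer bonding when the
#: input carries no explicit connectivity (PDB proteins, bare SDF poses)
_BOND_DISTANCE = 1.9


@dataclass(frozen=True)
class DescriptorConfig:
    """Geometry of the contact census."""

    cutoff: float = 12.0
    bin_edges_v2: tuple[float, ...] = (0.0, 2.0, 4.0, 6.0, 8.0, 10.0, 12.0)
    protein_elements: tuple[str, ...] = PROTEIN_ELEMENTS
    ligand_elements: tuple[str, ...] = LIGAND_ELEMENTS

    def __post_init__(self) -> None:
        edges = tuple(float(e) for e in self.bin_edges_v2)
        if any(b <= a for a, b in zip(edges, edges[1:])):
            raise ValueError("bin edges must be strictly increasing")
        if edges[-1] != self.cutoff:
            raise ValueError("last bin edge must equal the cutoff")
        for name, elems in (
            ("protein", self.protein_elements),
            ("ligand", self.ligand_elements),
        ):
            if not elems or len(set(elems)) != len(elems):
                raise ValueError(f"{name} element set must be non-empty, no duplicates")
        object.__setattr__(self, "bin_edges_v2", edges)

    @property
    def n_pairs(self) -> int:
        return len(self.protein_elements) * len(self.ligand_elements)


DEFAULT_CONFIG = DescriptorConfig()


@dataclass(frozen=True)
class FeatureVector:
    version: str
    values: np.ndarray
    names: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != (len(self.names),):
            raise ValueError("values and names length mismatch")
        object.__setattr__(self, "values", values)


@dataclass(frozen=True)
class VinaTerms:
    gauss1: float
    gauss2: float
    repulsion: float
    hydrophobic: float
    hbond: float
    n_rotors: int

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.gauss1, self.gauss2, self.repulsion, self.hydrophobic,
             self.hbond, float(self.n_rotors)]
        )


VINA_TERM_NAMES = ("gauss1", "gauss2", "repulsion", "hydrophobic", "hbond", "n_rotors")


# ---------------------------------------------------------------------------
# contact counting

def _grid_distances(protein: ProteinStructure, ligand: LigandPose, config: DescriptorConfig):
    """Heavy-atom pair distances with element grid indices (-1 = off-grid)."""
    p_elems, p_xyz = heavy_arrays(protein.atoms)
    l_elems, l_xyz = heavy_arrays(ligand.atoms)
    p_index = {e: i for i, e in enumerate(config.protein_elements)}
    l_index = {e: i for i, e in enumerate(config.ligand_elements)}
    p_idx = np.array([p_index.get(e, -1) for e in p_elems], dtype=int)
    l_idx = np.array([l_index.get(e, -1) for e in l_elems], dtype=int)
    dist = cdist(p_xyz, l_xyz) if len(p_elems) and len(l_elems) else np.zeros((len(p_elems), len(l_elems)))
    return p_idx, l_idx, dist


def count_contacts(
    protein: ProteinStructure,
    ligand: LigandPose,
    config: DescriptorConfig = DEFAULT_CONFIG,
    *,
    bin_edges: Sequence[float] | None = None,
) -> np.ndarray:
    """3-way contact count table, shape (n_protein_elements, n_ligand_elements, n_bins).

    Entry (P, L, b) is the number of heavy-atom pairs of those elements
    whose Euclidean distance falls in bin b.  Bins are [lo, hi) with the
    final bin closed at the cutoff.
    """
    edges = np.asarray(
        config.bin_edges_v2 if bin_edges is None else bin_edges, dtype=float
    )
    n_bins = len(edges) - 1
    p_idx, l_idx, dist = _grid_distances(protein, ligand, config)
    table = np.zeros(
        (len(config.protein_elements), len(config.ligand_elements), n_bins),
        dtype=np.int64,
    )
    if dist.size == 0:
        return table

    bin_of = np.searchsorted(edges, dist, side="right") - 1
    bin_of[dist == edges[-1]] = n_bins - 1  # closed upper edge
    valid = (
        (p_idx[:, None] >= 0)
        & (l_idx[None, :] >= 0)
        & (dist >= edges[0])
        & (dist <= edges[-1])
    )
    pi, li = np.nonzero(valid)
    np.add.at(table, (p_idx[pi], l_idx[li], bin_of[pi, li]), 1)
    return table


def _pair_names(config: DescriptorConfig) -> list[tuple[str, str]]:
    """(ligand, protein) element pairs in ligand-element-major order."""
    return [(l, p) for l in config.ligand_elements for p in config.protein_elements]


def featurize_v1(
    protein: ProteinStructure,
    ligand: LigandPose,
    config: DescriptorConfig = DEFAULT_CONFIG,
) -> FeatureVector:
    """36 single-bin contact counts, ligand-element-major ordering."""
    table = count_contacts(
        protein, ligand, config, bin_edges=(0.0, config.cutoff)
    )[:, :, 0]
    p_pos = {e: i for i, e in enumerate(config.protein_elements)}
    l_pos = {e: i for i, e in enumerate(config.ligand_elements)}
    pairs = _pair_names(config)
    values = np.array([table[p_pos[p], l_pos[l]] for l, p in pairs], dtype=float)
    names = tuple(f"{l}-{p}" for l, p in pairs)
    return FeatureVector("v1", values, names)


def featurize_v2(
    protein: ProteinStructure,
    ligand: LigandPose,
    config: DescriptorConfig = DEFAULT_CONFIG,
) -> FeatureVector:
    """216 binned contact counts: 36 element pairs × 6 bins, pair-major."""
    table = count_contacts(protein, ligand, config)
    edges = config.bin_edges_v2
    p_pos = {e: i for i, e in enumerate(config.protein_elements)}
    l_pos = {e: i for i, e in enumerate(config.ligand_elements)}
    values, names = [], []
    for l, p in _pair_names(config):
        for b, (lo, hi) in enumerate(zip(edges, edges[1:])):
            values.append(table[p_pos[p], l_pos[l], b])
            names.append(f"{l}-{p}_{lo:g}-{hi:g}A")
    return FeatureVector("v2", np.array(values, dtype=float), tuple(names))


# ---------------------------------------------------------------------------
# Vina empirical terms

def _infer_polar_and_hydrophobic(atoms) -> tuple[np.ndarray, np.ndarray]:
    """Per-heavy-atom (is_hydrophobic, is_polar) flags.

    Connectivity is inferred geometrically: two heavy atoms closer than
    1.9 Å are taken as bonded.  A carbon is hydrophobic when no N/O is
    bonded to it; N and O are polar (treated as both donor- and
    acceptor-capable — docked poses carry no reliable protonation, so the
    donor/acceptor distinction is deliberately collapsed).
    """
    elems, xyz = heavy_arrays(atoms)
    n = len(elems)
    is_polar = np.array([e in ("N", "O") for e in elems])
    is_hydrophobic = np.zeros(n, dtype=bool)
    carbon = np.array([e == "C" for e in elems])
    if n:
        dist = cdist(xyz, xyz)
        np.fill_diagonal(dist, np.inf)
        bonded_to_polar = ((dist < _BOND_DISTANCE) & is_polar[None, :]).any(axis=1)
        is_hydrophobic = carbon & ~bonded_to_polar
    return is_hydrophobic, is_polar


def vina_terms(protein: ProteinStructure, ligand: LigandPose) -> VinaTerms:
    """Raw (unweighted) Vina pair-potential sums over heavy-atom pairs
    within 8 Å, on the surface distance d = r − (R_i + R_j)."""
    p_elems, p_xyz = heavy_arrays(protein.atoms)
    l_elems, l_xyz = heavy_arrays(ligand.atoms)
    for e in set(p_elems) | set(l_elems):
        if e not in VDW_RADII:
            raise KeyError(f"element {e!r} missing from the vdW radius table")
    p_r = np.array([VDW_RADII[e] for e in p_elems])
    l_r = np.array([VDW_RADII[e] for e in l_elems])
    dist = cdist(p_xyz, l_xyz)
    within = dist <= VINA_PAIR_CUTOFF
    d = dist - (p_r[:, None] + l_r[None, :])

    p_hyd, p_pol = _infer_polar_and_hydrophobic(protein.atoms)
    l_hyd, l_pol = _infer_polar_and_hydrophobic(ligand.atoms)

    dw = d[within]
    gauss1 = float(np.exp(-((dw / 0.5) ** 2)).sum())
    gauss2 = float(np.exp(-(((dw - 3.0) / 2.0) ** 2)).sum())
    repulsion = float((dw[dw < 0] ** 2).sum())

    hyd_pair = within & p_hyd[:, None] & l_hyd[None, :]
    dh = d[hyd_pair]
    hydrophobic = float(np.clip((1.5 - dh) / 1.0, 0.0, 1.0).sum())

    pol_pair = within & p_pol[:, None] & l_pol[None, :]
    dp = d[pol_pair]
    hbond = float(np.clip(-dp / 0.7, 0.0, 1.0).sum())

    return VinaTerms(
        gauss1=gauss1,
        gauss2=gauss2,
        repulsion=repulsion,
        hydrophobic=hydrophobic,
        hbond=hbond,
        n_rotors=int(ligand.n_rotatable_bonds),
    )


def featurize_v3(
    protein: ProteinStructure,
    ligand: LigandPose,
    config: DescriptorConfig = DEFAULT_CONFIG,
) -> FeatureVector:
    """42 values: the 36 v1 counts followed by the six Vina terms."""
    v1 = featurize_v1(protein, ligand, config)
    terms = vina_terms(protein, ligand)
    return FeatureVector(
        "v3",
        np.concatenate([v1.values, terms.as_array()]),
        v1.names + VINA_TERM_NAMES,
    )


_FEATURIZERS = {"v1": featurize_v1, "v2": featurize_v2, "v3": featurize_v3}


def featurize(
    protein: ProteinStructure,
    ligand: LigandPose,
    version: str = "v1",
    config: DescriptorConfig = DEFAULT_CONFIG,
) -> FeatureVector:
    """Dispatch to the versioned featurizer (v1, v2 or v3)."""
    try:
        fn = _FEATURIZERS[version]
    except KeyError:
        raise ValueError(f"unknown descriptor version {version!r}") from None
    return fn(protein, ligand, config)


def feature_names(version: str, config: DescriptorConfig = DEFAULT_CONFIG) -> tuple[str, ...]:
    """Stable feature-column names for a descriptor version."""
    pairs = _pair_names(config)
    if version == "v1":
        return tuple(f"{l}-{p}" for l, p in pairs)
    if version == "v2":
        edges = config.bin_edges_v2
        return tuple(
            f"{l}-{p}_{lo:g}-{hi:g}A"
            for l, p in pairs
            for lo, hi in zip(edges, edges[1:])
        )
    if version == "v3":
        return tuple(f"{l}-{p}" for l, p in pairs) + VINA_TERM_NAMES
    raise ValueError(f"unknown descriptor version {version!r}")
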