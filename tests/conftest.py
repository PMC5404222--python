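"""Shared fixtures: tiny literal structure files and independent oracles.

The oracle implementations here are deliberately naive double loops over
atom pairs, written without reference to the production (vectorised)
descriptor code so the two can check each other.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from rfscreen.complex_io import LigandPose, ProteinStructure
from rfscreen.descriptors import VDW_RADII, DescriptorConfig

# ---------------------------------------------------------------------------
# literal protein fixture: ALA (5 heavy) + VAL (7) + LYS (9) = 21 heavy atoms,
# plus one hydrogen, two waters and one phosphate heteroatom group that the
# parser must drop by default.

THREE_RESIDUE_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  C   ALA A   1      10.674   6.693  -4.139  1.00  0.00           C
ATOM      4  O   ALA A   1       9.462   6.615  -4.312  1.00  0.00           O
ATOM      5  CB  ALA A   1      11.949   4.632  -4.749  1.00  0.00           C
ATOM      6  H   ALA A   1      10.310   5.545  -6.702  1.00  0.00           H
ATOM      7  N   VAL A   2      11.211   7.328  -3.098  1.00  0.00           N
ATOM      8  CA  VAL A   2      10.422   7.982  -2.049  1.00  0.00           C
ATOM      9  C   VAL A   2      11.102   7.832  -0.690  1.00  0.00           C
ATOM     10  O   VAL A   2      12.303   7.563  -0.607  1.00  0.00           O
ATOM     11  CB  VAL A   2      10.204   9.476  -2.384  1.00  0.00           C
ATOM     12  CG1 VAL A   2       9.332  10.166  -1.334  1.00  0.00           C
ATOM     13  CG2 VAL A   2       9.569   9.615  -3.768  1.00  0.00           C
ATOM     14  N   LYS A   3      10.326   8.011   0.378  1.00  0.00           N
ATOM     15  CA  LYS A   3      10.858   7.899   1.736  1.00  0.00           C
ATOM     16  C   LYS A   3       9.902   8.574   2.716  1.00  0.00           C
ATOM     17  O   LYS A   3       8.689   8.572   2.502  1.00  0.00           O
ATOM     18  CB  LYS A   3      11.069   6.434   2.138  1.00  0.00           C
ATOM     19  CG  LYS A   3      11.674   6.267   3.529  1.00  0.00           C
ATOM     20  CD  LYS A   3      11.863   4.800   3.902  1.00  0.00           C
ATOM     21  CE  LYS A   3      12.455   4.643   5.297  1.00  0.00           C
ATOM     22  NZ  LYS A   3      12.632   3.221   5.697  1.00  0.00           N
HETATM   23  P   PO4 A 101       2.000   2.000   2.000  1.00  0.00           P
HETATM   24  O   HOH A 201      20.000  20.000  20.000  1.00  0.00           O
HETATM   25  O   HOH A 202      21.000  21.000  21.000  1.00  0.00           O
END
"""

WATER_ONLY_PDB = """\
HETATM    1  O   HOH A   1       0.000   0.000   0.000  1.00  0.00           O
HETATM    2  O   HOH A   2       3.000   0.000   0.000  1.00  0.00           O
END
"""

SINGLE_CA_PDB = """\
ATOM      1  CA  GLY A   1       0.000   0.000   0.000  1.00  0.00           C
END
"""


@pytest.fixture
def three_residue_pdb(tmp_path):
    path = tmp_path / "three_residue.pdb"
    path.write_text(THREE_RESIDUE_PDB)
    return path


@pytest.fixture
def water_only_pdb(tmp_path):
    path = tmp_path / "waters.pdb"
    path.write_text(WATER_ONLY_PDB)
    return path


@pytest.fixture
def single_ca_pdb(tmp_path):
    path = tmp_path / "single_ca.pdb"
    path.write_text(SINGLE_CA_PDB)
    return path


def sdf_from_smiles(smiles_scores, path, score_property="minimizedAffinity",
                    extra_props=None):
    """Write an SDF with embedded 3D coordinates from (smiles, score) pairs."""
    from rdkit import Chem
    from rdkit.Chem import AllChem

    writer = Chem.SDWriter(str(path))
    for i, (smi, score) in enumerate(smiles_scores):
        mol = Chem.AddHs(Chem.MolFromSmiles(smi))
        AllChem.EmbedMolecule(mol, randomSeed=17 + i)
        mol.SetProp("_Name", f"mol{i}")
        mol.SetProp(score_property, str(score))
        if extra_props:
            for key, value in extra_props[i].items():
                mol.SetProp(key, str(value))
        writer.write(mol)
    writer.close()
    return path


# ---------------------------------------------------------------------------
# oracles

def oracle_contact_table(protein: ProteinStructure, ligand: LigandPose,
                         config: DescriptorConfig) -> np.ndarray:
    """Brute-force pair census: explicit double loop, scalar math only."""
    edges = list(config.bin_edges_v2)
    n_bins = len(edges) - 1
    table = np.zeros(
        (len(config.protein_elements), len(config.ligand_elements), n_bins),
        dtype=np.int64,
    )
    for pa in protein.atoms:
        if not pa.is_heavy or pa.element not in config.protein_elements:
            continue
        pi = config.protein_elements.index(pa.element)
        for la in ligand.atoms:
            if not la.is_heavy or la.element not in config.ligand_elements:
                continue
            li = config.ligand_elements.index(la.element)
            d = math.dist((pa.x, pa.y, pa.z), (la.x, la.y, la.z))
            for b in range(n_bins):
                lo, hi = edges[b], edges[b + 1]
                last = b == n_bins - 1
                if (lo <= d < hi) or (last and d == hi):
                    table[pi, li, b] += 1
                    break
    return table


def oracle_vina_terms(protein: ProteinStructure, ligand: LigandPose) -> dict:
    """Brute-force Vina pair sums with scalar loops and if-chains."""

    def typing(atoms):
        heavy = [a for a in atoms if a.is_heavy]
        flags = []
        for a in heavy:
            polar = a.element in ("N", "O")
            hydrophobic = False
            if a.element == "C":
                hydrophobic = True
                for b in heavy:
                    if b is a:
                        continue
                    if b.element in ("N", "O") and math.dist(
                        (a.x, a.y, a.z), (b.x, b.y, b.z)
                    ) < 1.9:
                        hydrophobic = False
                        break
            flags.append((a, hydrophobic, polar))
        return flags

    p_flags = typing(protein.atoms)
    l_flags = typing(ligand.atoms)
    terms = {"gauss1": 0.0, "gauss2": 0.0, "repulsion": 0.0,
             "hydrophobic": 0.0, "hbond": 0.0}
    for pa, p_hyd, p_pol in p_flags:
        for la, l_hyd, l_pol in l_flags:
            r = math.dist((pa.x, pa.y, pa.z), (la.x, la.y, la.z))
            if r > 8.0:
                continue
            d = r - (VDW_RADII[pa.element] + VDW_RADII[la.element])
            terms["gauss1"] += math.exp(-((d / 0.5) ** 2))
            terms["gauss2"] += math.exp(-(((d - 3.0) / 2.0) ** 2))
            if d < 0:
                terms["repulsion"] += d * d
            if p_hyd and l_hyd:
                if d <= 0.5:
                    terms["hydrophobic"] += 1.0
                elif d < 1.5:
                    terms["hydrophobic"] += 1.5 - d
            if p_pol and l_pol:
                if d <= -0.7:
                    terms["hbond"] += 1.0
                elif d < 0:
                    terms["hbond"] += -d / 0.7
    return terms


def oracle_pearson(x, y) -> float:
    """Textbook Pearson correlation, scalar accumulation."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / math.sqrt(sxx * syy)


def oracle_auc(scores, labels) -> float:
    """Pairwise enumeration of active-inactive score comparisons."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))
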