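"""Contact descriptors: oracle equivalence, invariances, Vina terms."""

import numpy as np
import pytest

from rfscreen.complex_io import Atom, LigandPose, ProteinStructure
from rfscreen.descriptors import (
    DEFAULT_CONFIG,
    DescriptorConfig,
    count_contacts,
    feature_names,
    featurize_v1,
    featurize_v2,
    featurize_v3,
    vina_terms,
)
from rfscreen.synthetic import make_complex_fixture

from .conftest import oracle_contact_table, oracle_vina_terms


def single_pair_complex(d, p_elem="C", l_elem="C"):
    protein = ProteinStructure("t", (Atom(p_elem, 0, 0, 0),))
    ligand = LigandPose("m", 0, (Atom(l_elem, d, 0, 0),), -1.0)
    return protein, ligand


class TestConfig:
    def test_defaults(self):
        assert DEFAULT_CONFIG.cutoff == 12.0
        assert DEFAULT_CONFIG.bin_edges_v2 == (0, 2, 4, 6, 8, 10, 12)
        assert DEFAULT_CONFIG.n_pairs == 36

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"bin_edges_v2": (0, 4, 2, 12)},
            {"bin_edges_v2": (0, 2, 4, 6, 8, 10, 11)},
            {"protein_elements": ()},
            {"ligand_elements": ("C", "C")},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            DescriptorConfig(**kwargs)


class TestCountContacts:
    def test_single_pair_lands_in_4_6_bin(self):
        protein, ligand = single_pair_complex(5.0)
        table = count_contacts(protein, ligand)
        assert table.sum() == 1
        assert table[0, 0, 2] == 1  # (C, C, 4-6 Å)

    def test_pair_at_exact_cutoff_counted_in_last_bin(self):
        protein, ligand = single_pair_complex(12.0)
        table = count_contacts(protein, ligand)
        assert table[0, 0, -1] == 1

    def test_pair_beyond_cutoff_ignored(self):
        protein, ligand = single_pair_complex(12.000001)
        assert count_contacts(protein, ligand).sum() == 0

    def test_off_grid_elements_ignored(self):
        protein = ProteinStructure("t", (Atom("Fe", 0, 0, 0), Atom("C", 1, 0, 0)))
        ligand = LigandPose("m", 0, (Atom("B", 3, 0, 0), Atom("C", 2, 0, 0)), -1.0)
        table = count_contacts(protein, ligand)
        assert table.sum() == 1  # only the C-C pair

    def test_hydrogens_never_counted(self):
        protein = ProteinStructure("t", (Atom("C", 0, 0, 0), Atom("H", 0.5, 0, 0)))
        ligand = LigandPose("m", 0, (Atom("C", 3, 0, 0), Atom("H", 3.5, 0, 0)), -1.0)
        assert count_contacts(protein, ligand).sum() == 1


class TestFeaturizers:
    def test_v1_single_pair(self):
        protein, ligand = single_pair_complex(5.0)
        fv = featurize_v1(protein, ligand)
        assert len(fv.values) == 36
        assert fv.values.sum() == 1
        assert fv.values[fv.names.index("C-C")] == 1

    def test_v2_single_pair_slot(self):
        protein, ligand = single_pair_complex(5.0)
        fv = featurize_v2(protein, ligand)
        assert len(fv.values) == 216
        assert fv.values[fv.names.index("C-C_4-6A")] == 1
        assert fv.values.sum() == 1

    def test_v3_prefix_is_v1(self):
        protein, ligand, _ = make_complex_fixture(25, 10, seed=5)
        v1 = featurize_v1(protein, ligand)
        v3 = featurize_v3(protein, ligand)
        assert len(v3.values) == 42
        np.testing.assert_array_equal(v3.values[:36], v1.values)
        assert v3.names[:36] == v1.names

    def test_empty_contact_case(self):
        protein = ProteinStructure("t", (Atom("C", 0, 0, 0),))
        ligand = LigandPose("m", 0, (Atom("C", 100, 0, 0),), -1.0, n_rotatable_bonds=3)
        assert featurize_v1(protein, ligand).values.sum() == 0
        v3 = featurize_v3(protein, ligand)
        assert v3.values[:41].sum() == 0
        assert v3.values[41] == 3  # rotor count survives

    def test_feature_names_stable(self):
        assert feature_names("v1")[:4] == ("C-C", "C-N", "C-O", "C-S")
        assert feature_names("v2")[0] == "C-C_0-2A"
        assert feature_names("v3")[-6:] == (
            "gauss1", "gauss2", "repulsion", "hydrophobic", "hbond", "n_rotors"
        )


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(30))
    def test_counts_match_bruteforce(self, seed):
        protein, ligand, _ = make_complex_fixture(
            n_protein_atoms=1 + seed % 50,
            n_ligand_atoms=1 + (seed * 7) % 50,
            box_size=18.0,
            seed=seed,
            ligand_palette=("C", "N", "O", "F", "Cl", "Br"),
        )
        expected = oracle_contact_table(protein, ligand, DEFAULT_CONFIG)
        np.testing.assert_array_equal(
            count_contacts(protein, ligand), expected
        )
        assert featurize_v1(protein, ligand).values.sum() == expected.sum()

    @pytest.mark.parametrize("seed", range(10))
    def test_vina_terms_match_bruteforce(self, seed):
        protein, ligand, _ = make_complex_fixture(30, 12, box_size=12.0, seed=seed)
        got = vina_terms(protein, ligand)
        want = oracle_vina_terms(protein, ligand)
        for name in ("gauss1", "gauss2", "repulsion", "hydrophobic", "hbond"):
            assert getattr(got, name) == pytest.approx(want[name], abs=1e-9)


class TestInvariances:
    def test_bin_marginalization(self):
        for seed in range(10):
            protein, ligand, _ = make_complex_fixture(40, 15, seed=seed)
            v1 = featurize_v1(protein, ligand).values
            v2 = featurize_v2(protein, ligand).values.reshape(36, 6)
            np.testing.assert_array_equal(v2.sum(axis=1), v1)

    def test_atom_order_permutation_invariance(self):
        protein, ligand, _ = make_complex_fixture(20, 10, seed=11)
        rng = np.random.default_rng(0)
        p2 = ProteinStructure(
            protein.target_id,
            tuple(protein.atoms[i] for i in rng.permutation(len(protein.atoms))),
        )
        l2 = LigandPose(
            ligand.molecule_id, 0,
            tuple(ligand.atoms[i] for i in rng.permutation(len(ligand.atoms))),
            ligand.docking_score,
        )
        np.testing.assert_array_equal(
            featurize_v2(protein, ligand).values, featurize_v2(p2, l2).values
        )

    def test_rigid_transform_invariance(self):
        protein, ligand, _ = make_complex_fixture(20, 10, seed=13)
        angle = 0.7
        rot = np.array(
            [[np.cos(angle), -np.sin(angle), 0],
             [np.sin(angle), np.cos(angle), 0],
             [0, 0, 1]]
        )
        shift = np.array([3.0, -2.0, 7.5])

        def transform(atoms):
            return tuple(
                Atom(a.element, *(rot @ a.coords + shift)) for a in atoms
            )

        p2 = ProteinStructure(protein.target_id, transform(protein.atoms))
        l2 = LigandPose(ligand.molecule_id, 0, transform(ligand.atoms),
                        ligand.docking_score)
        np.testing.assert_allclose(
            featurize_v3(protein, ligand).values,
            featurize_v3(p2, l2).values,
            atol=1e-9,
        )


class TestVinaTerms:
    def test_zero_surface_distance(self):
        """Two carbons at r = R_C + R_C: d = 0, gauss1 = 1, no repulsion."""
        protein, ligand = single_pair_complex(3.8)
        terms = vina_terms(protein, ligand)
        assert terms.gauss1 == pytest.approx(1.0)
        assert terms.repulsion == 0.0

    def test_far_apart_all_zero(self):
        protein, ligand = single_pair_complex(20.0)
        terms = vina_terms(protein, ligand)
        assert terms.as_array()[:5].sum() == 0.0

    def test_unknown_element_names_offender(self):
        protein = ProteinStructure("t", (Atom("C", 0, 0, 0),))
        ligand = LigandPose("m", 0, (Atom("B", 2, 0, 0),), -1.0)
        with pytest.raises(KeyError, match="B"):
            vina_terms(protein, ligand)

    def test_off_grid_element_still_contributes(self):
        """Zn is outside the contact grids but has a radius, so it adds to
        the pair terms while adding nothing to the counts."""
        protein = ProteinStructure("t", (Atom("Zn", 0, 0, 0),))
        ligand = LigandPose("m", 0, (Atom("C", 3.1, 0, 0),), -1.0)
        assert count_contacts(protein, ligand).sum() == 0
        assert vina_terms(protein, ligand).gauss1 == pytest.approx(1.0)
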