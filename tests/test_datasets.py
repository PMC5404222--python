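"""Labelling, pK conversion, DUD-E-style ingestion, duplicate filtering."""

import numpy as np
import pandas as pd
import pytest

from rfscreen.datasets import (
    LabelConfig,
    ScreeningDataset,
    ingest_dude_layout,
    label_records,
    near_duplicate_filter,
    to_pk,
)
from rfscreen.synthetic import BenchmarkSpec, make_benchmark, make_dude_style_tree


class TestToPk:
    @pytest.mark.parametrize(
        "value,unit,expected",
        [
            (1, "uM", 6.0),     # the activity cutoff: 1 μM ↔ pK 6
            (1, "M", 0.0),
            (10, "nM", 8.0),
            (1, "mM", 3.0),
            (100, "pM", 10.0),
        ],
    )
    def test_closed_form(self, value, unit, expected):
        assert to_pk(value, unit) == pytest.approx(expected)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            to_pk(0, "nM")
        with pytest.raises(ValueError):
            to_pk(-1, "uM")

    def test_unknown_unit_rejected(self):
        with pytest.raises(ValueError):
            to_pk(1, "mg/mL")


class TestLabelRecords:
    def _table(self, rows):
        return pd.DataFrame(
            rows, columns=["molecule_id", "target_id", "measure", "value", "unit", "decoy_flag"]
        )

    def test_decoy_gets_constant_label(self):
        (rec,) = label_records(self._table([("d1", "t", None, None, None, True)]))
        assert rec.pk == 5.95
        assert not rec.is_active
        assert rec.is_decoy

    def test_potent_ligand_active(self):
        (rec,) = label_records(self._table([("m1", "t", "Ki", 100, "nM", False)]))
        assert rec.pk == pytest.approx(7.0)
        assert rec.is_active

    def test_weak_ligand_keeps_measured_pk(self):
        """A 50 μM IC50 is below the cutoff: inactive but not clamped."""
        (rec,) = label_records(self._table([("m2", "t", "IC50", 50, "uM", False)]))
        assert rec.pk == pytest.approx(4.301, abs=1e-3)
        assert not rec.is_active
        assert not rec.is_decoy

    def test_row_without_affinity_or_flag_errors(self):
        with pytest.raises(ValueError, match="m3"):
            label_records(self._table([("m3", "t", "Ki", None, "nM", False)]))

    def test_label_partition(self):
        """Every record is exactly one of active / measured-inactive / decoy."""
        recs = label_records(
            self._table(
                [
                    ("a", "t", "Kd", 1, "nM", False),
                    ("b", "t", "IC50", 900, "uM", False),
                    ("c", "t", None, None, None, True),
                ]
            )
        )
        kinds = [
            (r.is_active, (not r.is_active) and not r.is_decoy, r.is_decoy)
            for r in recs
        ]
        assert all(sum(k) == 1 for k in kinds)

    def test_inactive_label_must_sit_below_cutoff(self):
        with pytest.raises(ValueError):
            LabelConfig(active_cutoff_pk=5.0, inactive_label=5.95)


class TestIngestDudeLayout:
    def test_mini_layout_record_count(self, tmp_path):
        """3 targets × (4 actives + 200 decoys) → 612 records."""
        spec = BenchmarkSpec(n_targets=3, actives_per_target=4, decoys_per_active=50, seed=5)
        root = make_dude_style_tree(spec, tmp_path / "tree")
        ds = ingest_dude_layout(root, "v1")
        assert len(ds) == 612
        counts = ds.records.groupby("target_id")["is_decoy"].agg(["size", "sum"])
        assert (counts["size"] == 204).all()
        assert (counts["sum"] == 200).all()

    def test_random_hit_rate_near_2_percent(self, tmp_path):
        spec = BenchmarkSpec(n_targets=1, actives_per_target=4, decoys_per_active=50, seed=6)
        ds = ingest_dude_layout(make_dude_style_tree(spec, tmp_path / "t"), "v1")
        actives = ds.records["is_active"].sum()
        assert 100 * actives / len(ds) == pytest.approx(100 / 51, abs=1e-9)

    def test_empty_directory_yields_empty_dataset(self, tmp_path):
        ds = ingest_dude_layout(tmp_path / "empty", "v1")
        assert len(ds) == 0

    def test_missing_receptor_skipped_permissive_fails_strict(self, tmp_path):
        spec = BenchmarkSpec(n_targets=2, actives_per_target=2, decoys_per_active=2, seed=7)
        root = make_dude_style_tree(spec, tmp_path / "tree")
        (root / "T001" / "receptor.pdb").unlink()
        ds = ingest_dude_layout(root, "v1")
        assert set(ds.records["target_id"]) == {"T000"}
        with pytest.raises(FileNotFoundError):
            ingest_dude_layout(root, "v1", strict=True)

    def test_best_pose_selected(self, tmp_path):
        """Ingestion keeps the lowest-scoring pose of each molecule."""
        spec = BenchmarkSpec(n_targets=1, actives_per_target=2, decoys_per_active=2, seed=8)
        root = make_dude_style_tree(spec, tmp_path / "tree", n_poses=3)
        ds = ingest_dude_layout(root, "v1")
        from rfscreen.complex_io import parse_ligand_poses

        poses = parse_ligand_poses(root / "T000" / "actives.sdf")
        by_mol = {}
        for p in poses:
            by_mol.setdefault(p.molecule_id, []).append(p.docking_score)
        for row in ds.records.itertuples():
            if not row.is_decoy and row.molecule_id in by_mol:
                assert row.docking_score == min(by_mol[row.molecule_id])


class TestScreeningDataset:
    def test_csv_round_trip(self, tmp_path):
        ds = make_benchmark(BenchmarkSpec(n_targets=2, actives_per_target=3,
                                          decoys_per_active=4, seed=1))
        path = tmp_path / "ds.csv"
        ds.to_csv(path)
        again = ScreeningDataset.from_csv(path, "v1")
        assert len(again) == len(ds)
        np.testing.assert_allclose(again.features, ds.features)
        assert again.feature_names == ds.feature_names

    def test_duplicate_records_rejected(self):
        rec = pd.DataFrame(
            {"target_id": ["t", "t"], "molecule_id": ["m", "m"],
             "pk": [6, 6], "is_active": [True, True], "is_decoy": [False, False]}
        )
        with pytest.raises(ValueError, match="duplicate"):
            ScreeningDataset(rec, np.zeros((2, 1)), ("f0",), "v1")


class TestNearDuplicateFilter:
    REFERENCE = ["c1ccccc1O", "CCN(CC)CC", "CC(=O)Nc1ccc(O)cc1"]

    def test_identical_sets_fully_removed(self):
        retained, report = near_duplicate_filter(self.REFERENCE, self.REFERENCE)
        assert retained == []
        assert report["removed"].all()

    def test_disjoint_scaffolds_all_retained(self):
        retained, _ = near_duplicate_filter(["c1ccccc1"], ["CCCCCC"])
        assert retained == ["c1ccccc1"]

    def test_partial_overlap(self):
        """2 of 10 queries copied from the reference set → 8 retained."""
        extra = [
            "CCO", "CCCO", "CCCCO", "CC(C)O", "CC(C)CO",
            "CCOC", "CCOCC", "CCCN",
        ]
        query = extra + self.REFERENCE[:2]
        retained, report = near_duplicate_filter(query, self.REFERENCE)
        assert len(retained) == 8
        assert set(retained) == set(extra)

    def test_idempotent(self):
        query = ["CCO", "CCCO", "c1ccccc1O"]
        retained, _ = near_duplicate_filter(query, self.REFERENCE)
        again, report = near_duplicate_filter(retained, self.REFERENCE)
        assert again == retained
        # and filtering a set against itself removes everything
        self_removed, _ = near_duplicate_filter(retained, retained)
        assert self_removed == []

    def test_unparseable_counted_as_removed(self):
        retained, report = near_duplicate_filter(["not_a_smiles(", "CCO"], ["CCCCCC"])
        assert retained == ["CCO"]
        assert report["removed"].sum() == 1
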