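"""Feature catalog composition and tabular IO round trips."""

import logging

import numpy as np
import pytest

import morphonorm as mn
from morphonorm import schema as sc


class TestCatalog:
    def test_total_feature_count(self, schema):
        assert len(schema) == 2976

    def test_surface_and_volume_partition(self, schema):
        assert len(schema.surface_keys) == (34 + 74) * 3 * 9 == 2916
        assert len(schema.volume_keys) == 60
        assert len(schema.measured_keys) + len(schema.asymmetry_keys) == 2976

    def test_assembly_is_deterministic(self):
        a = sc.FeatureSchema(entries=sc._build_entries())
        b = sc.FeatureSchema(entries=sc._build_entries())
        assert a.entries == b.entries

    def test_every_bilateral_region_has_one_asymmetry_key_per_parameter(self, schema):
        asym = {}
        for key in schema.asymmetry_keys:
            asym.setdefault(key.region, []).append(key.parameter)
        for region in sc.BILATERAL_VOLUME_REGIONS:
            assert asym[region] == ["volume"]
        for region in sc.SURFACE_REGIONS:
            assert sorted(asym[region]) == sorted(sc.SURFACE_PARAMETERS)

    def test_global_structures_carry_no_hemisphere(self, schema):
        for key in schema.entries:
            if key.region in sc.GLOBAL_VOLUME_REGIONS:
                assert key.side == sc.GLOBAL

    def test_feature_ids_unique_and_parseable(self, schema):
        ids = schema.ids()
        assert len(set(ids)) == 2976
        key = sc.FeatureKey.from_id(ids[100])
        assert key.id == ids[100]


class TestGenericTsv:
    def _record(self, schema):
        values = {k.id: float(i + 1) for i, k in enumerate(schema.measured_keys)}
        return sc.MorphometricRecord(
            subject_id="s1", session_id="s1_a", age=40.0, sex="female",
            scanner_sequence="scanA", etiv=1500.0, values=values,
        )

    def test_write_read_round_trip(self, schema, tmp_path):
        record = self._record(schema)
        path = tmp_path / "scan.tsv"
        sc.write_record(record, path)
        back = sc.read_stats_table(path, "generic_tsv")
        assert back.values == record.values
        assert back.age == record.age and back.etiv == record.etiv
        assert len(back.values) == 1990  # asymmetry entries computed later

    def test_unknown_region_skipped_with_warning(self, tmp_path, caplog):
        path = tmp_path / "scan.tsv"
        path.write_text(
            "# age: 30\nregion\tparameter\tside\tvalue\n"
            "hippocampus\tvolume\tleft\t4.0\n"
            "not_a_region\tvolume\tleft\t1.0\n"
        )
        with caplog.at_level(logging.WARNING):
            record = sc.read_stats_table(path, "generic_tsv")
        assert "not_a_region" in caplog.text
        assert list(record.values) == ["hippocampus|volume|left"]

    def test_duplicate_row_raises(self, tmp_path):
        path = tmp_path / "scan.tsv"
        path.write_text(
            "region\tparameter\tside\tvalue\n"
            "hippocampus\tvolume\tleft\t4.0\nhippocampus\tvolume\tleft\t4.1\n"
        )
        with pytest.raises(sc.SchemaError, match="duplicate"):
            sc.read_stats_table(path, "generic_tsv")

    def test_malformed_header_names_line(self, tmp_path):
        path = tmp_path / "scan.tsv"
        path.write_text("wrong\theader\nhippocampus\tvolume\tleft\t4.0\n")
        with pytest.raises(sc.SchemaError, match=":1"):
            sc.read_stats_table(path, "generic_tsv")

    def test_missing_file(self):
        with pytest.raises(FileNotFoundError):
            sc.read_stats_table("/nonexistent/scan.tsv")


ASEG_TEXT = """# Title Segmentation Statistics
# Measure EstimatedTotalIntraCranialVol, eTIV, Estimated Total Intracranial Volume, 1512345.0, mm^3
# ColHeaders Index SegId NVoxels Volume_mm3 StructName
 1 17 4100 4100.0 Left-Hippocampus
 2 53 3900 3900.0 Right-Hippocampus
 3 99 10 10.0 Mystery-Structure
"""

APARC_TEXT = """# Table of FreeSurfer cortical parcellation anatomical statistics
# hemi lh
# ColHeaders StructName NumVert SurfArea GrayVol ThickAvg ThickStd MeanCurv GausCurv FoldInd CurvInd
bankssts 1500 980 2530.0 2.47 0.45 0.12 0.025 11 1.6
superiortemporal 5000 3500 11200.0 2.71 0.52 0.11 0.021 35 4.2
"""


class TestFreeSurferDialects:
    def test_aseg_volumes_in_ml_and_etiv(self, tmp_path, caplog):
        path = tmp_path / "aseg.stats"
        path.write_text(ASEG_TEXT)
        with caplog.at_level(logging.WARNING):
            record = sc.read_stats_table(path, "freesurfer_aseg")
        assert record.values["hippocampus|volume|left"] == pytest.approx(4.1)
        assert record.values["hippocampus|volume|right"] == pytest.approx(3.9)
        assert record.etiv == pytest.approx(1512.345)
        assert "Mystery-Structure" in caplog.text

    def test_aparc_parameters(self, tmp_path):
        path = tmp_path / "lh.aparc.stats"
        path.write_text(APARC_TEXT)
        record = sc.read_stats_table(path, "freesurfer_aparc")
        assert record.values["bankssts|thickness|left"] == pytest.approx(2.47)
        assert record.values["bankssts|grayvol|left"] == pytest.approx(2.53)
        assert record.values["superiortemporal|surfarea|left"] == pytest.approx(3500.0)

    def test_merge_partial_records(self, tmp_path):
        p1, p2 = tmp_path / "aseg.stats", tmp_path / "lh.stats"
        p1.write_text(ASEG_TEXT)
        p2.write_text(APARC_TEXT)
        merged = sc.merge_records(
            sc.read_stats_table(p1, "freesurfer_aseg"),
            sc.read_stats_table(p2, "freesurfer_aparc"),
        )
        assert "hippocampus|volume|left" in merged.values
        assert "bankssts|thickness|left" in merged.values


class TestRecordValidation:
    def test_nonpositive_age_rejected(self):
        with pytest.raises(sc.SchemaError):
            sc.MorphometricRecord(age=-1.0)

    def test_negative_volume_rejected(self):
        with pytest.raises(sc.SchemaError):
            sc.MorphometricRecord(values={"hippocampus|volume|left": -2.0})

    def test_unknown_feature_rejected(self):
        with pytest.raises(sc.SchemaError):
            sc.MorphometricRecord(values={"nope|volume|left": 1.0})


class TestGroundTruth:
    def _gts(self):
        return [
            sc.GroundTruth(
                dataset_id="d1", patient_id="p1", subtype="MTLE-HS-left",
                expert_regions={("left", "hippocampus"), ("left", "amygdala")},
                eeg_lateralization="left",
                resection=("left", "temporal", ("hippocampus", "amygdala")),
                engel_class="I", followup_months=24.0,
            ),
            sc.GroundTruth(dataset_id="d2", eeg_lateralization="diffuse"),
        ]

    def test_round_trip(self, tmp_path):
        path = tmp_path / "gt.tsv"
        sc.write_ground_truth(self._gts(), path)
        back = sc.read_ground_truth(path)
        assert back[0].expert_regions == self._gts()[0].expert_regions
        assert back[0].resection == self._gts()[0].resection
        assert back[0].followup_months == 24.0
        assert back[1].resection is None and back[1].engel_class is None

    def test_empty_file_gives_empty_list(self, tmp_path):
        path = tmp_path / "gt.tsv"
        path.write_text("")
        assert sc.read_ground_truth(path) == []

    def test_unknown_enum_rejected(self):
        with pytest.raises(sc.SchemaError):
            sc.GroundTruth(dataset_id="d", eeg_lateralization="sideways")
        with pytest.raises(sc.SchemaError):
            sc.GroundTruth(dataset_id="d", engel_class="V")

    def test_unfavorable_surgery_not_evaluable(self):
        gt = sc.GroundTruth(
            dataset_id="d", resection=("left", "temporal", ("hippocampus",)),
            engel_class="III", followup_months=24.0,
        )
        assert not gt.surgery_evaluable
        short = sc.GroundTruth(
            dataset_id="d", resection=("left", "temporal", ("hippocampus",)),
            engel_class="I", followup_months=3.0,
        )
        assert not short.surgery_evaluable
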