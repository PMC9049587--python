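"""Record I/O: dialect round trips, validation, metadata extraction."""

import json

import numpy as np
import pytest

from ecgfusion.labels import ALL_CLASSES, ClassLabel
from ecgfusion.record_io import (
    ECGRecord,
    LEAD_NAMES,
    RecordFormatError,
    primary_label,
    read_record,
    separate_metadata,
    write_record,
)


def make_record(n=3000, fs=500.0, labels=(ClassLabel.AF, ClassLabel.PVC),
                age=54.0, sex="female", record_id="r1"):
    rng = np.random.default_rng(0)
    return ECGRecord(signals=rng.normal(0, 0.5, size=(12, n)), fs=fs,
                     labels=list(labels), age=age, sex=sex,
                     record_id=record_id)


class TestClassLabel:
    def test_code_index_bijection(self):
        for i, cls in enumerate(ALL_CLASSES):
            assert cls.index == i
            assert ClassLabel.from_code(cls.code) is cls
            assert ClassLabel.from_index(i) is cls

    def test_frozen_order(self):
        assert [c.code for c in ALL_CLASSES] == [
            "N", "AF", "I-AVB", "LBBB", "RBBB", "PAC", "PVC", "STD", "STE"]

    def test_unknown_code_rejected(self):
        with pytest.raises(ValueError, match="unknown class label"):
            ClassLabel.from_code("VF")


class TestECGRecordValidation:
    def test_wrong_lead_count(self):
        with pytest.raises(RecordFormatError, match="12"):
            ECGRecord(signals=np.zeros((11, 100)), fs=500,
                      labels=[ClassLabel.N])

    @pytest.mark.parametrize("labels", [[], [ClassLabel.N] * 2,
                                        [ClassLabel.N, ClassLabel.AF,
                                         ClassLabel.PAC, ClassLabel.PVC]])
    def test_bad_label_lists(self, labels):
        with pytest.raises(ValueError):
            ECGRecord(signals=np.zeros((12, 100)), fs=500, labels=labels)

    def test_nonpositive_fs(self):
        with pytest.raises(ValueError, match="positive"):
            ECGRecord(signals=np.zeros((12, 100)), fs=0, labels=[ClassLabel.N])


class TestPrimaryLabel:
    def test_first_label_rule(self):
        rec = make_record(labels=(ClassLabel.AF, ClassLabel.PVC))
        assert primary_label(rec) is ClassLabel.AF

    def test_order_dependence(self):
        rec = make_record(labels=(ClassLabel.PVC, ClassLabel.AF))
        assert primary_label(rec) is ClassLabel.PVC

    def test_single_label(self):
        assert primary_label(make_record(labels=(ClassLabel.AF,))) is ClassLabel.AF


class TestCsvmatDialect:
    def test_round_trip_exact(self, tmp_path):
        rec = make_record()
        write_record(rec, tmp_path / "r1", format="csvmat")
        back = read_record(tmp_path / "r1", format="csvmat")
        np.testing.assert_allclose(back.signals, rec.signals, atol=1e-9)
        assert back.fs == rec.fs
        assert back.labels == rec.labels
        assert back.age == rec.age
        assert back.sex == rec.sex
        assert back.record_id == rec.record_id

    def test_header_names_leads_in_order(self, tmp_path):
        write_record(make_record(n=50), tmp_path / "r1", format="csvmat")
        header = (tmp_path / "r1.csv").read_text().splitlines()[0]
        assert header.split(",") == list(LEAD_NAMES)

    def test_missing_age_encoded_null(self, tmp_path):
        write_record(make_record(n=50, age=None), tmp_path / "r1",
                     format="csvmat")
        meta = json.loads((tmp_path / "r1.json").read_text())
        assert meta["age"] is None

    def test_missing_lead_column_rejected(self, tmp_path):
        write_record(make_record(n=50), tmp_path / "r1", format="csvmat")
        csv_path = tmp_path / "r1.csv"
        lines = csv_path.read_text().splitlines()
        # drop the V6 column from every row
        lines = [",".join(ln.split(",")[:-1]) for ln in lines]
        csv_path.write_text("\n".join(lines))
        with pytest.raises(RecordFormatError, match="V6"):
            read_record(tmp_path / "r1", format="csvmat")

    def test_non_numeric_sample_rejected(self, tmp_path):
        write_record(make_record(n=50), tmp_path / "r1", format="csvmat")
        csv_path = tmp_path / "r1.csv"
        lines = csv_path.read_text().splitlines()
        lines[3] = lines[3].replace(lines[3].split(",")[0], "abc", 1)
        csv_path.write_text("\n".join(lines))
        with pytest.raises(RecordFormatError, match="non-numeric"):
            read_record(tmp_path / "r1", format="csvmat")


class TestWfdbDialect:
    def test_round_trip_within_quantization(self, tmp_path):
        rec = make_record()
        write_record(rec, tmp_path / "r1", format="wfdb", gain=1000.0)
        back = read_record(tmp_path / "r1", format="wfdb")
        # integer encoding at gain g is accurate to 0.5/g mV
        np.testing.assert_allclose(back.signals, rec.signals, atol=0.5e-3)
        assert back.labels == rec.labels
        assert back.age == rec.age
        assert back.sex == rec.sex

    def test_write_read_idempotent(self, tmp_path):
        rec = make_record()
        write_record(rec, tmp_path / "a", format="wfdb")
        once = read_record(tmp_path / "a", format="wfdb")
        write_record(once, tmp_path / "b", format="wfdb")
        twice = read_record(tmp_path / "b", format="wfdb")
        np.testing.assert_array_equal(once.signals, twice.signals)

    def test_format32_high_gain(self, tmp_path):
        rec = make_record(n=200)
        write_record(rec, tmp_path / "r1", format="wfdb", gain=1e6, fmt=32)
        back = read_record(tmp_path / "r1", format="wfdb")
        np.testing.assert_allclose(back.signals, rec.signals, atol=0.5e-6)

    def test_missing_labels_comment_rejected(self, tmp_path):
        write_record(make_record(n=50), tmp_path / "r1", format="wfdb")
        hea = tmp_path / "r1.hea"
        hea.write_text("\n".join(
            ln for ln in hea.read_text().splitlines()
            if not ln.startswith("# Labels")))
        with pytest.raises(RecordFormatError, match="Labels"):
            read_record(tmp_path / "r1", format="wfdb")


class TestSeparateMetadata:
    def test_table_contents_and_determinism(self, tmp_path):
        recs = [
            make_record(n=40, record_id="b", age=30, sex="male",
                        labels=(ClassLabel.N,)),
            make_record(n=40, record_id="a", age=None, sex=None,
                        labels=(ClassLabel.AF, ClassLabel.PAC)),
            make_record(n=40, record_id="c", labels=(ClassLabel.STE,)),
        ]
        for r in recs:
            write_record(r, tmp_path / r.record_id, format="csvmat")
        out1, out2 = tmp_path / "m1.csv", tmp_path / "m2.csv"
        table = separate_metadata(tmp_path, out1)
        separate_metadata(tmp_path, out2)
        assert list(table["record_id"]) == ["a", "b", "c"]
        assert table.loc[0, "labels"] == "AF|PAC"
        assert table.loc[0, "age"] == ""  # missing -> empty cell, no crash
        assert out1.read_bytes() == out2.read_bytes()

    def test_unreadable_record_skipped(self, tmp_path):
        write_record(make_record(n=40, record_id="ok"), tmp_path / "ok",
                     format="csvmat")
        (tmp_path / "bad.json").write_text("{not json")
        table = separate_metadata(tmp_path)
        assert list(table["record_id"]) == ["ok"]
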