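"""Session CSV dialect, manifest, and clinical table I/O."""

import numpy as np
import pandas as pd
import pytest

from atload import read_recording, write_recording
from atload.insole_io import (
    CLINICAL_ID_COLUMNS,
    CLINICAL_MEASURES,
    CohortManifest,
    FormatError,
    read_clinical_table,
    read_cohort_tables,
    read_manifest,
    write_clinical_table,
    write_manifest,
)

from conftest import make_recording


def _clinical_frame(n=15):
    rng = np.random.default_rng(0)
    data = {"participant_id": [f"P{i + 1:02d}" for i in range(n)]}
    data["mass_kg"] = rng.uniform(60, 120, n)
    data["height_m"] = rng.uniform(1.5, 1.9, n)
    for m in CLINICAL_MEASURES:
        data[m] = rng.uniform(1, 10, n)
    data["visa_a"] = rng.uniform(10, 95, n)
    data["pas"] = rng.uniform(1, 6, n)
    data["age"] = rng.uniform(20, 69, n)
    return pd.DataFrame(data)


class TestRecordingRoundtrip:
    def test_roundtrip_identity(self, tmp_path):
        rng = np.random.default_rng(1)
        rec = make_recording(*rng.uniform(0, 900, (3, 240)), rate=20.0)
        path = tmp_path / "s.csv"
        write_recording(rec, path)
        back = read_recording(path)
        assert back.participant_id == rec.participant_id
        assert (back.day, back.session) == (rec.day, rec.session)
        assert back.sample_rate_hz == rec.sample_rate_hz
        # 6 significant digits serialized precision
        np.testing.assert_allclose(back.f_heel, rec.f_heel, rtol=1e-5)
        np.testing.assert_allclose(back.f_fore, rec.f_fore, rtol=1e-5)

    def test_duration_from_samples_and_rate(self, tmp_path):
        rec = make_recording(np.zeros(1200), np.zeros(1200), np.zeros(1200))
        path = tmp_path / "s.csv"
        write_recording(rec, path)
        text = path.read_text().splitlines()
        assert len(text) == 3 + 1200  # 3 header lines then one row per sample
        assert read_recording(path).duration_s == pytest.approx(60.0)

    def test_empty_recording_roundtrips(self, tmp_path):
        rec = make_recording([], [], [])
        path = tmp_path / "s.csv"
        write_recording(rec, path)
        assert read_recording(path).n_samples == 0

    def test_writes_are_byte_identical(self, tmp_path):
        rng = np.random.default_rng(2)
        rec = make_recording(*rng.uniform(0, 900, (3, 50)))
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        write_recording(rec, p1)
        write_recording(rec, p2)
        assert p1.read_bytes() == p2.read_bytes()


class TestRecordingParseErrors:
    def _write(self, tmp_path, text):
        p = tmp_path / "bad.csv"
        p.write_text(text)
        return p

    def test_missing_channel_column(self, tmp_path):
        p = self._write(
            tmp_path,
            "participant_id,day,session,sample_rate_hz\nP01,1,1,20\n"
            "time_s,f_heel_n,f_fore_n\n0,0,0\n",
        )
        with pytest.raises(FormatError, match="f_mid_n"):
            read_recording(p)

    def test_non_numeric_cell(self, tmp_path):
        p = self._write(
            tmp_path,
            "participant_id,day,session,sample_rate_hz\nP01,1,1,20\n"
            "time_s,f_heel_n,f_mid_n,f_fore_n\n0,0,oops,0\n",
        )
        with pytest.raises(FormatError, match="non-numeric"):
            read_recording(p)

    def test_non_uniform_timestep_names_line(self, tmp_path):
        p = self._write(
            tmp_path,
            "participant_id,day,session,sample_rate_hz\nP01,1,1,20\n"
            "time_s,f_heel_n,f_mid_n,f_fore_n\n0,0,0,0\n0.05,0,0,0\n0.5,0,0,0\n",
        )
        with pytest.raises(FormatError, match="line 6"):
            read_recording(p)


class TestManifest:
    def test_roundtrip_and_path_check(self, tmp_path):
        rec = make_recording([0.0], [0.0], [0.0])
        write_recording(rec, tmp_path / "s.csv")
        table = pd.DataFrame(
            [{"participant_id": "T01", "day": 1, "session": 1, "path": "s.csv",
              "date": "2025-03-01"}]
        )
        write_manifest(CohortManifest(table), tmp_path / "manifest.csv")
        m = read_manifest(tmp_path / "manifest.csv")
        assert len(m) == 1
        assert m.participants == ["T01"]

    def test_missing_file_rejected(self, tmp_path):
        table = pd.DataFrame(
            [{"participant_id": "T01", "day": 1, "session": 1,
              "path": "absent.csv", "date": "2025-03-01"}]
        )
        write_manifest(CohortManifest(table), tmp_path / "manifest.csv")
        with pytest.raises(FormatError, match="missing file"):
            read_manifest(tmp_path / "manifest.csv")

    def test_duplicate_key_rejected(self):
        row = {"participant_id": "T01", "day": 1, "session": 1, "path": "x",
               "date": "d"}
        with pytest.raises(FormatError, match="duplicate"):
            CohortManifest(pd.DataFrame([row, row]))


class TestClinicalTable:
    def test_full_cohort_loads(self, tmp_path):
        write_clinical_table(_clinical_frame(15), tmp_path / "c.csv")
        table = read_clinical_table(tmp_path / "c.csv")
        assert len(table) == 15
        assert set(CLINICAL_MEASURES) <= set(table.columns)
        assert set(CLINICAL_ID_COLUMNS) <= set(table.columns)

    def test_visa_out_of_range_rejected(self, tmp_path):
        frame = _clinical_frame(3)
        frame.loc[1, "visa_a"] = 110.0
        write_clinical_table(frame, tmp_path / "c.csv")
        with pytest.raises(FormatError, match="VISA-A"):
            read_clinical_table(tmp_path / "c.csv")

    def test_pas_out_of_range_rejected(self, tmp_path):
        frame = _clinical_frame(3)
        frame.loc[0, "pas"] = 7.0
        write_clinical_table(frame, tmp_path / "c.csv")
        with pytest.raises(FormatError, match="PAS"):
            read_clinical_table(tmp_path / "c.csv")

    def test_duplicate_participant_rejected(self, tmp_path):
        frame = _clinical_frame(3)
        frame.loc[2, "participant_id"] = frame.loc[0, "participant_id"]
        write_clinical_table(frame, tmp_path / "c.csv")
        with pytest.raises(FormatError, match="duplicate"):
            read_clinical_table(tmp_path / "c.csv")

    def test_unknown_column_warned_and_dropped(self, tmp_path):
        frame = _clinical_frame(3)
        frame["shoe_color"] = "red"
        write_clinical_table(frame, tmp_path / "c.csv")
        with pytest.warns(UserWarning, match="shoe_color"):
            table = read_clinical_table(tmp_path / "c.csv")
        assert "shoe_color" not in table.columns

    def test_missing_values_allowed(self, tmp_path):
        frame = _clinical_frame(4)
        frame.loc[1, "cmj_height"] = np.nan
        write_clinical_table(frame, tmp_path / "c.csv")
        table = read_clinical_table(tmp_path / "c.csv")
        assert table["cmj_height"].isna().sum() == 1

    def test_read_cohort_tables_pairs_both(self, tmp_path):
        rec = make_recording([0.0], [0.0], [0.0])
        write_recording(rec, tmp_path / "s.csv")
        write_manifest(
            CohortManifest(pd.DataFrame([
                {"participant_id": "T01", "day": 1, "session": 1,
                 "path": "s.csv", "date": "2025-03-01"}])),
            tmp_path / "m.csv",
        )
        write_clinical_table(_clinical_frame(2), tmp_path / "c.csv")
        manifest, clinical = read_cohort_tables(tmp_path / "m.csv", tmp_path / "c.csv")
        assert len(manifest) == 1 and len(clinical) == 2
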