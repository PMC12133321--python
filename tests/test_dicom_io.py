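"""Header extraction and hierarchy grouping."""

import logging
import struct

import pytest

from imgstudy import generate_corpus, group_instances, read_instance
from imgstudy.dicom_io import DicomInstanceMeta, DicomReadError, flatten

from conftest import make_mixed_profile


# --- independent oracle: a minimal explicit-VR-little-endian tag scanner ---
# Reads the raw file bytes directly, without pydicom, so header values
# extracted by the package can be checked against the wire format itself.

_LONG_VRS = {b"OB", b"OW", b"OF", b"SQ", b"UT", b"UN"}


def raw_tag_values(path):
    data = path.read_bytes()
    assert data[128:132] == b"DICM", "missing Part-10 magic"
    pos = 132
    values = {}
    while pos + 8 <= len(data):
        group, elem = struct.unpack_from("<HH", data, pos)
        vr = data[pos + 4 : pos + 6]
        if vr in _LONG_VRS:
            (length,) = struct.unpack_from("<I", data, pos + 8)
            body = pos + 12
        else:
            (length,) = struct.unpack_from("<H", data, pos + 6)
            body = pos + 8
        if length == 0xFFFFFFFF:
            break  # undefined length: out of scope for this oracle
        if group != 0x0002:  # skip file-meta values, capture dataset ones
            values[(group, elem)] = data[body : body + length].decode(
                "ascii", errors="replace"
            ).strip("\x00").strip()
        pos = body + length
        if (group, elem) == (0x7FE0, 0x0010):
            break
    return values


def test_read_instance_matches_raw_byte_oracle(tmp_path):
    profile = make_mixed_profile()
    generate_corpus(profile, tmp_path / "c")
    files = sorted((tmp_path / "c").rglob("*.dcm"))
    assert len(files) >= 20
    for path in files[:: max(1, len(files) // 20)][:20]:
        meta = read_instance(path)
        raw = raw_tag_values(path)
        assert meta.sop_instance_uid == raw[(0x0008, 0x0018)]
        assert meta.study_instance_uid == raw[(0x0020, 0x000D)]
        assert meta.series_instance_uid == raw[(0x0020, 0x000E)]
        assert meta.modality == raw[(0x0008, 0x0060)]
        assert meta.accession_number == raw[(0x0008, 0x0050)]
        assert meta.patient_id == raw[(0x0010, 0x0020)]
        assert meta.body_part_examined == raw.get((0x0018, 0x0015))
        assert meta.laterality == (raw.get((0x0020, 0x0060)) or raw.get((0x0020, 0x0062)))


class TestReadInstance:
    def test_round_trips_generator_values(self, tiny_corpus):
        metas = [read_instance(p) for p in sorted(tiny_corpus.dir.rglob("*.dcm"))]
        knees = [m for m in metas if m.body_part_examined == "KNEE"]
        assert knees and all(m.laterality == "L" for m in knees)
        assert all(m.modality == "CT" for m in metas)

    def test_blank_body_part_normalized_to_absent(self, tiny_corpus, tmp_path):
        import pydicom

        src = next(tiny_corpus.dir.rglob("*.dcm"))
        ds = pydicom.dcmread(src)
        ds.BodyPartExamined = "  "
        target = tmp_path / "blank.dcm"
        ds.save_as(target, enforce_file_format=True)
        assert read_instance(target).body_part_examined is None

    def test_non_dicom_file_rejected_with_identity(self, tmp_path):
        bogus = tmp_path / "not_dicom.txt"
        bogus.write_bytes(b"hello world" * 20)
        with pytest.raises(DicomReadError, match="not_dicom.txt"):
            read_instance(bogus)

    def test_missing_hierarchy_uid_rejected(self, tiny_corpus, tmp_path):
        import pydicom

        src = next(tiny_corpus.dir.rglob("*.dcm"))
        ds = pydicom.dcmread(src)
        del ds.StudyInstanceUID
        target = tmp_path / "broken.dcm"
        ds.save_as(target, enforce_file_format=True)
        with pytest.raises(DicomReadError, match="StudyInstanceUID"):
            read_instance(target)


def _meta(study="1.1", series="1.1.1", sop="1.1.1.1", **kw):
    defaults = dict(
        sop_instance_uid=sop,
        sop_class_uid="1.2.840.10008.5.1.4.1.1.2",
        study_instance_uid=study,
        series_instance_uid=series,
        modality="CT",
    )
    defaults.update(kw)
    return DicomInstanceMeta(**defaults)


class TestGrouping:
    def test_two_studies_one_series_each(self):
        metas = [
            _meta("1.1", "1.1.1", "1.1.1.1"),
            _meta("1.1", "1.1.1", "1.1.1.2"),
            _meta("1.2", "1.2.1", "1.2.1.1"),
            _meta("1.2", "1.2.1", "1.2.1.2"),
        ]
        studies = group_instances(metas)
        assert len(studies) == 2
        assert [s.n_instances for s in studies] == [2, 2]

    def test_empty_input(self):
        assert group_instances([]) == []

    def test_duplicate_instance_rejected_with_warning(self, caplog):
        metas = [_meta(), _meta(), _meta(sop="1.1.1.2")]
        with caplog.at_level(logging.WARNING):
            studies = group_instances(metas)
        assert sum(s.n_instances for s in studies) == 2
        assert any("duplicate" in r.message for r in caplog.records)

    def test_count_conservation_and_ordering(self):
        metas = [
            _meta(series="1.1.2", sop="1.1.2.1", series_number=2, instance_number=1),
            _meta(series="1.1.1", sop="1.1.1.2", series_number=1, instance_number=2),
            _meta(series="1.1.1", sop="1.1.1.1", series_number=1, instance_number=1),
        ]
        (study,) = group_instances(metas)
        assert sum(len(s.instances) for s in study.series) == len(metas)
        assert [s.series_number for s in study.series] == [1, 2]
        assert [m.instance_number for m in study.series[0].instances] == [1, 2]

    def test_grouping_idempotent_on_flatten(self):
        metas = [
            _meta("1.2", "1.2.1", "1.2.1.1", series_number=1),
            _meta("1.1", "1.1.2", "1.1.2.5", series_number=2),
            _meta("1.1", "1.1.1", "1.1.1.9", series_number=1),
        ]
        once = group_instances(metas)
        twice = group_instances(flatten(once))
        assert [
            (st.study_instance_uid, [(se.series_instance_uid, [m.sop_instance_uid for m in se.instances]) for se in st.series])
            for st in once
        ] == [
            (st.study_instance_uid, [(se.series_instance_uid, [m.sop_instance_uid for m in se.instances]) for se in st.series])
            for st in twice
        ]

    def test_generated_corpus_regroups_to_profile_topology(self, tiny_corpus):
        metas = [read_instance(p) for p in sorted(tiny_corpus.dir.rglob("*.dcm"))]
        studies = group_instances(metas)
        assert len(studies) == 2
        for study in studies:
            assert len(study.series) == 2
            assert study.n_instances == 4
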