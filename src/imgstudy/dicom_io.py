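"""DICOM Part-10 header extraction and study/series grouping.

Reading stops before the pixel-data element — only header metadata is ever
loaded — and the flat instance list regroups into the study → series →
instance hierarchy of the original DICOM studies.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import pydicom
from pydicom.errors import InvalidDicomError

logger = logging.getLogger(__name__)

__all__ = [
    "DicomInstanceMeta",
    "SeriesGroup",
    "StudySet",
    "DicomReadError",
    "read_instance",
    "group_instances",
    "flatten",
]

_UID_RE = re.compile(r"^[0-9]+(\.[0-9]+)*$")


class DicomReadError(ValueError):
    """A file could not be accepted as a processable DICOM object."""

    def __init__(self, path: str | Path, reason: str):
        super().__init__(f"{path}: {reason}")
        self.path = str(path)
        self.reason = reason


@dataclass(frozen=True)
class DicomInstanceMeta:
    """Header fields of one DICOM object relevant to conversion and QC."""

    sop_instance_uid: str
    sop_class_uid: str
    study_instance_uid: str
    series_instance_uid: str
    modality: str
    body_part_examined: str | None = None
    laterality: str | None = None
    patient_id: str = ""
    accession_number: str = ""
    study_date: str | None = None
    study_time: str | None = None
    series_number: int | None = None
    instance_number: int | None = None
    series_description: str | None = None

    def __post_init__(self) -> None:
        for label, uid in (
            ("SOPInstanceUID", self.sop_instance_uid),
            ("StudyInstanceUID", self.study_instance_uid),
            ("SeriesInstanceUID", self.series_instance_uid),
        ):
            if not uid or len(uid) > 64 or not _UID_RE.match(uid):
                raise ValueError(f"{label} {uid!r} is not a valid DICOM UID")
        if not self.modality:
            raise ValueError("modality must be non-empty")


@dataclass
class SeriesGroup:
    series_instance_uid: str
    modality: str
    body_part_examined: str | None
    laterality: str | None
    series_number: int | None
    instances: list[DicomInstanceMeta] = field(default_factory=list)


@dataclass
class StudySet:
    """One study's instances grouped hierarchically (study → series → instance)."""

    study_instance_uid: str
    accession_number: str
    patient_id: str
    study_date: str | None
    study_time: str | None
    series: list[SeriesGroup] = field(default_factory=list)

    @property
    def n_instances(self) -> int:
        return sum(len(s.instances) for s in self.series)


def _clean(value) -> str | None:
    """Trim; collapse empty strings to absent."""
    if value is None:
        return None
    text = str(value).strip()
    return text or None


def _clean_upper(value) -> str | None:
    text = _clean(value)
    return text.upper() if text is not None else None


def _to_int(value) -> int | None:
    if value in (None, ""):
        return None
    try:
        return int(value)
    except (TypeError, ValueError):
        return None


def read_instance(path: str | Path) -> DicomInstanceMeta:
    """Extract header metadata from one Part-10 file, skipping pixel data.

    Raises :class:`DicomReadError` for files without the DICOM preamble/magic
    or missing any of the three hierarchy UIDs.  Optional tags that are
    absent or blank (after trimming) map to ``None``; body part and
    laterality are uppercased so later mapping and counting are
    case-insensitive.  Laterality (0020,0060) is preferred, with Image
    Laterality (0020,0062) as fallback — the only tag where the bilateral
    and unpaired codes B/U are legal.
    """
    try:
        ds = pydicom.dcmread(path, stop_before_pixels=True)
    except InvalidDicomError as exc:
        raise DicomReadError(path, f"not a DICOM Part-10 file ({exc})") from exc
    except (OSError, ValueError) as exc:
        raise DicomReadError(path, f"unreadable ({exc})") from exc

    uids = {
        "StudyInstanceUID": _clean(ds.get("StudyInstanceUID")),
        "SeriesInstanceUID": _clean(ds.get("SeriesInstanceUID")),
        "SOPInstanceUID": _clean(ds.get("SOPInstanceUID")),
    }
    missing = [k for k, v in uids.items() if v is None]
    if missing:
        raise DicomReadError(path, f"unprocessable object: missing {', '.join(missing)}")

    laterality = _clean_upper(ds.get("Laterality"))
    if laterality is None:
        laterality = _clean_upper(ds.get("ImageLaterality"))

    try:
        return DicomInstanceMeta(
            sop_instance_uid=uids["SOPInstanceUID"],
            sop_class_uid=_clean(ds.get("SOPClassUID")) or "",
            study_instance_uid=uids["StudyInstanceUID"],
            series_instance_uid=uids["SeriesInstanceUID"],
            modality=_clean(ds.get("Modality")) or "",
            body_part_examined=_clean_upper(ds.get("BodyPartExamined")),
            laterality=laterality,
            patient_id=_clean(ds.get("PatientID")) or "",
            accession_number=_clean(ds.get("AccessionNumber")) or "",
            study_date=_clean(ds.get("StudyDate")),
            study_time=_clean(ds.get("StudyTime")),
            series_number=_to_int(ds.get("SeriesNumber")),
            instance_number=_to_int(ds.get("InstanceNumber")),
            series_description=_clean(ds.get("SeriesDescription")),
        )
    except ValueError as exc:
        raise DicomReadError(path, str(exc)) from exc


def group_instances(metas: list[DicomInstanceMeta]) -> list[StudySet]:
    """Group flat instance metadata into ordered StudySets.

    Series-level attributes come from each series' first instance (a warning
    is logged when instances within one series disagree).  A duplicate
    SOPInstanceUID within a series is rejected with a warning, so the total
    instance count across groups equals the input length minus rejected
    duplicates.  Series sort by series number (absent last, then by UID) and
    instances by instance number likewise.
    """
    studies: dict[str, StudySet] = {}
    series_index: dict[tuple[str, str], SeriesGroup] = {}
    seen: set[tuple[str, str, str]] = set()

    for meta in metas:
        key = (meta.study_instance_uid, meta.series_instance_uid, meta.sop_instance_uid)
        if key in seen:
            logger.warning(
                "duplicate SOPInstanceUID %s in series %s: rejected",
                meta.sop_instance_uid,
                meta.series_instance_uid,
            )
            continue
        seen.add(key)

        study = studies.get(meta.study_instance_uid)
        if study is None:
            study = StudySet(
                study_instance_uid=meta.study_instance_uid,
                accession_number=meta.accession_number,
                patient_id=meta.patient_id,
                study_date=meta.study_date,
                study_time=meta.study_time,
            )
            studies[meta.study_instance_uid] = study

        skey = (meta.study_instance_uid, meta.series_instance_uid)
        series = series_index.get(skey)
        if series is None:
            series = SeriesGroup(
                series_instance_uid=meta.series_instance_uid,
                modality=meta.modality,
                body_part_examined=meta.body_part_examined,
                laterality=meta.laterality,
                series_number=meta.series_number,
            )
            series_index[skey] = series
            study.series.append(series)
        elif (
            series.modality != meta.modality
            or series.body_part_examined != meta.body_part_examined
            or series.laterality != meta.laterality
        ):
            logger.warning(
                "instances disagree on series-level attributes in series %s",
                meta.series_instance_uid,
            )
        series.instances.append(meta)

    for study in studies.values():
        study.series.sort(
            key=lambda s: (s.series_number is None, s.series_number or 0, s.series_instance_uid)
        )
        for series in study.series:
            series.instances.sort(
                key=lambda m: (
                    m.instance_number is None,
                    m.instance_number or 0,
                    m.sop_instance_uid,
                )
            )
    return sorted(studies.values(), key=lambda s: s.study_instance_uid)


def flatten(studies: list[StudySet]) -> list[DicomInstanceMeta]:
    """Inverse of grouping: concatenate all instances in hierarchy order."""
    return [m for st in studies for se in st.series for m in se.instances]
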