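"""FHIR R4 ImagingStudy construction, validation and (ND)JSON serialization.

Each DICOM study becomes one ImagingStudy resource mirroring the study →
series → instance hierarchy, wrapped in a transaction bundle whose entry is
a conditional update keyed on the study-UID identifier (so repeated
submissions are idempotent on a server).  Serialization is deterministic:
the same resource always yields the same bytes.

The raw BodyPartExamined and laterality values are carried on each series
as string extensions in addition to the SNOMED codings, because downstream
completeness statistics are assessed on raw values (a present-but-unmapped
region must remain distinguishable from an absent one after conversion).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from .dicom_io import StudySet
from .terminology import (
    CodedConcept,
    MappingTable,
    map_body_part,
    map_laterality,
)

logger = logging.getLogger(__name__)

__all__ = [
    "InstanceComponent",
    "SeriesComponent",
    "ImagingStudyResource",
    "FhirBundle",
    "build_imaging_study",
    "wrap_bundle",
    "validate_resource",
    "dumps_bundle",
    "loads_bundle",
    "write_ndjson",
    "read_ndjson",
]

DICOM_UID_SYSTEM = "urn:dicom:uid"
DCM_MODALITY_SYSTEM = "http://dicom.nema.org/resources/ontology/DCM"
V2_0203_SYSTEM = "http://terminology.hl7.org/CodeSystem/v2-0203"
SOP_CLASS_SYSTEM = "urn:ietf:rfc:3986"
PATIENT_ID_SYSTEM = "https://imgstudy.example.org/fhir/NamingSystem/patient-id"
ACCESSION_SYSTEM = "https://imgstudy.example.org/fhir/NamingSystem/accession"
RAW_BODY_PART_EXT = "https://imgstudy.example.org/fhir/StructureDefinition/body-part-examined"
RAW_LATERALITY_EXT = "https://imgstudy.example.org/fhir/StructureDefinition/raw-laterality"


@dataclass(frozen=True)
class InstanceComponent:
    uid: str
    sop_class: CodedConcept
    number: int | None = None


@dataclass
class SeriesComponent:
    uid: str
    modality: CodedConcept
    number: int | None = None
    description: str | None = None
    number_of_instances: int = 0
    body_site: CodedConcept | None = None
    laterality: CodedConcept | None = None
    body_part_raw: str | None = None
    laterality_raw: str | None = None
    instances: list[InstanceComponent] = field(default_factory=list)


@dataclass
class ImagingStudyResource:
    """Abstract FHIR R4 ImagingStudy representation."""

    study_uid: str
    accession_number: str
    patient_id: str
    status: str = "available"
    started: str | None = None
    modality: list[CodedConcept] = field(default_factory=list)
    number_of_series: int = 0
    number_of_instances: int = 0
    series: list[SeriesComponent] = field(default_factory=list)


@dataclass
class FhirBundle:
    resource: ImagingStudyResource
    type: str = "transaction"


class BuildError(ValueError):
    """A StudySet cannot be converted into a valid ImagingStudy."""


def _compose_started(date: str | None, time: str | None) -> str | None:
    """Compose DICOM date/time into a FHIR dateTime (local, no zone)."""
    if not date or len(date) != 8 or not date.isdigit():
        return None
    iso = f"{date[:4]}-{date[4:6]}-{date[6:]}"
    if time and len(time) >= 6 and time[:6].isdigit():
        return f"{iso}T{time[:2]}:{time[2:4]}:{time[4:6]}"
    return iso


def build_imaging_study(study: StudySet, table: MappingTable) -> ImagingStudyResource:
    """Convert one grouped DICOM study into an ImagingStudy resource.

    Series with zero instances are dropped with a warning; an empty study is
    rejected.  Body site and laterality codings come from the terminology
    mappings; the raw values ride along as extensions.
    """
    kept = [s for s in study.series if s.instances]
    for s in study.series:
        if not s.instances:
            logger.warning("series %s has no instances: dropped", s.series_instance_uid)
    if not kept:
        raise BuildError(f"study {study.study_instance_uid} has no non-empty series")

    modalities: list[CodedConcept] = []
    seen_codes: set[str] = set()
    series_components: list[SeriesComponent] = []
    for s in kept:
        if s.modality not in seen_codes:
            seen_codes.add(s.modality)
            modalities.append(CodedConcept(DCM_MODALITY_SYSTEM, s.modality, s.modality))
        instances = [
            InstanceComponent(
                uid=m.sop_instance_uid,
                sop_class=CodedConcept(
                    SOP_CLASS_SYSTEM, f"urn:oid:{m.sop_class_uid}", m.sop_class_uid
                ),
                number=m.instance_number,
            )
            for m in s.instances
        ]
        series_components.append(
            SeriesComponent(
                uid=s.series_instance_uid,
                modality=CodedConcept(DCM_MODALITY_SYSTEM, s.modality, s.modality),
                number=s.series_number,
                description=s.instances[0].series_description,
                number_of_instances=len(instances),
                body_site=map_body_part(s.body_part_examined, table),
                laterality=map_laterality(s.laterality),
                body_part_raw=s.body_part_examined,
                laterality_raw=s.laterality,
                instances=instances,
            )
        )

    return ImagingStudyResource(
        study_uid=study.study_instance_uid,
        accession_number=study.accession_number,
        patient_id=study.patient_id,
        started=_compose_started(study.study_date, study.study_time),
        modality=modalities,
        number_of_series=len(series_components),
        number_of_instances=sum(c.number_of_instances for c in series_components),
        series=series_components,
    )


def wrap_bundle(resource: ImagingStudyResource) -> FhirBundle:
    """Wrap one ImagingStudy in a transaction bundle (conditional update)."""
    return FhirBundle(resource=resource)


def validate_resource(resource: ImagingStudyResource) -> list[str]:
    """Check structural invariants; an empty report means the resource is valid."""
    violations: list[str] = []
    if not resource.study_uid:
        violations.append("study UID is empty")
    if resource.status != "available":
        violations.append(f"status is {resource.status!r}, expected 'available'")
    if resource.number_of_series != len(resource.series):
        violations.append(
            f"numberOfSeries {resource.number_of_series} != {len(resource.series)} series"
        )
    total = sum(s.number_of_instances for s in resource.series)
    if resource.number_of_instances != total:
        violations.append(
            f"numberOfInstances {resource.number_of_instances} != sum of series counts {total}"
        )
    codes = [c.code for c in resource.modality]
    if len(codes) != len(set(codes)):
        violations.append("duplicate modality codings")
    series_codes = {s.modality.code for s in resource.series}
    if set(codes) != series_codes:
        violations.append("modality list does not equal the set of series modality codes")
    for s in resource.series:
        if not s.uid:
            violations.append("series with empty UID")
        if s.number_of_instances != len(s.instances):
            violations.append(
                f"series {s.uid}: numberOfInstances {s.number_of_instances} != "
                f"{len(s.instances)} instances"
            )
        uids = [i.uid for i in s.instances]
        if len(uids) != len(set(uids)):
            violations.append(f"series {s.uid}: duplicate instance UID")
        if any(not u for u in uids):
            violations.append(f"series {s.uid}: instance with empty UID")
    return violations


# ---------------------------------------------------------------------------
# (De)serialization to FHIR R4 JSON


def _coding(c: CodedConcept) -> dict:
    return {"system": c.system, "code": c.code, "display": c.display}


def _concept_from(d: dict | None) -> CodedConcept | None:
    if d is None:
        return None
    return CodedConcept(d["system"], d["code"], d.get("display") or d["code"])


def resource_to_fhir(resource: ImagingStudyResource) -> dict:
    out: dict = {
        "resourceType": "ImagingStudy",
        "identifier": [
            {"system": DICOM_UID_SYSTEM, "value": f"urn:oid:{resource.study_uid}"},
            {
                "type": {"coding": [{"system": V2_0203_SYSTEM, "code": "ACSN"}]},
                "system": ACCESSION_SYSTEM,
                "value": resource.accession_number,
            },
        ],
        "status": resource.status,
        "modality": [_coding(c) for c in resource.modality],
        "subject": {"identifier": {"system": PATIENT_ID_SYSTEM, "value": resource.patient_id}},
    }
    if resource.started:
        out["started"] = resource.started
    out["numberOfSeries"] = resource.number_of_series
    out["numberOfInstances"] = resource.number_of_instances
    series_out = []
    for s in resource.series:
        entry: dict = {"uid": s.uid, "modality": _coding(s.modality)}
        extensions = []
        if s.body_part_raw is not None:
            extensions.append({"url": RAW_BODY_PART_EXT, "valueString": s.body_part_raw})
        if s.laterality_raw is not None:
            extensions.append({"url": RAW_LATERALITY_EXT, "valueString": s.laterality_raw})
        if extensions:
            entry["extension"] = extensions
        if s.number is not None:
            entry["number"] = s.number
        if s.description is not None:
            entry["description"] = s.description
        entry["numberOfInstances"] = s.number_of_instances
        if s.body_site is not None:
            entry["bodySite"] = _coding(s.body_site)
        if s.laterality is not None:
            entry["laterality"] = _coding(s.laterality)
        entry["instance"] = [
            {
                "uid": i.uid,
                "sopClass": _coding(i.sop_class),
                **({"number": i.number} if i.number is not None else {}),
            }
            for i in s.instances
        ]
        series_out.append(entry)
    out["series"] = series_out
    return out


def resource_from_fhir(data: dict) -> ImagingStudyResource:
    if data.get("resourceType") != "ImagingStudy":
        raise ValueError(f"not an ImagingStudy: {data.get('resourceType')!r}")
    study_uid = ""
    accession = ""
    for ident in data.get("identifier", []):
        if ident.get("system") == DICOM_UID_SYSTEM:
            study_uid = ident.get("value", "").removeprefix("urn:oid:")
        elif ident.get("system") == ACCESSION_SYSTEM:
            accession = ident.get("value", "")
    series = []
    for s in data.get("series", []):
        raw_bp = raw_lat = None
        for ext in s.get("extension", []):
            if ext.get("url") == RAW_BODY_PART_EXT:
                raw_bp = ext.get("valueString")
            elif ext.get("url") == RAW_LATERALITY_EXT:
                raw_lat = ext.get("valueString")
        series.append(
            SeriesComponent(
                uid=s["uid"],
                modality=_concept_from(s["modality"]),
                number=s.get("number"),
                description=s.get("description"),
                number_of_instances=s.get("numberOfInstances", 0),
                body_site=_concept_from(s.get("bodySite")),
                laterality=_concept_from(s.get("laterality")),
                body_part_raw=raw_bp,
                laterality_raw=raw_lat,
                instances=[
                    InstanceComponent(
                        uid=i["uid"],
                        sop_class=_concept_from(i["sopClass"]),
                        number=i.get("number"),
                    )
                    for i in s.get("instance", [])
                ],
            )
        )
    return ImagingStudyResource(
        study_uid=study_uid,
        accession_number=accession,
        patient_id=data.get("subject", {}).get("identifier", {}).get("value", ""),
        status=data.get("status", "available"),
        started=data.get("started"),
        modality=[_concept_from(c) for c in data.get("modality", [])],
        number_of_series=data.get("numberOfSeries", 0),
        number_of_instances=data.get("numberOfInstances", 0),
        series=series,
    )


def bundle_to_fhir(bundle: FhirBundle) -> dict:
    uid = bundle.resource.study_uid
    return {
        "resourceType": "Bundle",
        "type": bundle.type,
        "entry": [
            {
                "fullUrl": f"urn:oid:{uid}",
                "resource": resource_to_fhir(bundle.resource),
                "request": {
                    "method": "PUT",
                    "url": f"ImagingStudy?identifier={DICOM_UID_SYSTEM}|urn:oid:{uid}",
                },
            }
        ],
    }


def bundle_from_fhir(data: dict) -> FhirBundle:
    if data.get("resourceType") != "Bundle":
        raise ValueError(f"not a Bundle: {data.get('resourceType')!r}")
    entries = data.get("entry", [])
    if len(entries) != 1:
        raise ValueError(f"expected exactly one bundle entry, got {len(entries)}")
    return FhirBundle(
        resource=resource_from_fhir(entries[0]["resource"]), type=data.get("type", "transaction")
    )


def dumps_bundle(bundle: FhirBundle) -> str:
    """Serialize a bundle to one compact, deterministic JSON line."""
    return json.dumps(bundle_to_fhir(bundle), separators=(",", ":"), ensure_ascii=False)


def loads_bundle(line: str) -> FhirBundle:
    return bundle_from_fhir(json.loads(line))


def write_ndjson(bundles: Iterable[FhirBundle], path: str | Path) -> int:
    """Write bundles one-per-line; returns the number of lines written."""
    n = 0
    with open(path, "w", encoding="utf-8") as fh:
        for bundle in bundles:
            fh.write(dumps_bundle(bundle))
            fh.write("\n")
            n += 1
    return n


def read_ndjson(path: str | Path) -> Iterator[FhirBundle]:
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                yield loads_bundle(line)
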