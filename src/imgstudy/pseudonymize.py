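"""Deterministic pseudonymization of ImagingStudy bundles.

DICOM hierarchy UIDs (study, series, instance) are replaced by UIDs derived
from a salted 256-bit digest, rendered in the ``2.25.`` decimal-UUID
namespace, which preserves referential consistency across the whole corpus:
equal input UIDs always map to equal output UIDs.  Patient IDs and
accession numbers are replaced through a persisted original→pseudonym map
(the stand-in for an institutional trustee), allocating ``PSN-``/``ACC-``
pseudonyms on first sight.

Standard SOP Class UIDs are not identifying and are left untouched.  Study
dates are retained unshifted — a documented privacy caveat.
"""

from __future__ import annotations

import csv
import hashlib
import logging
from dataclasses import dataclass, replace as dc_replace
from pathlib import Path

from .fhir_model import (
    FhirBundle,
    ImagingStudyResource,
    InstanceComponent,
    SeriesComponent,
    validate_resource,
)

logger = logging.getLogger(__name__)

__all__ = ["HashingPolicy", "PseudonymMap", "hash_uid", "pseudonymize_bundle"]


@dataclass(frozen=True)
class HashingPolicy:
    """Salted-digest UID derivation policy.

    The salt is a secret: it is never written to outputs, logs or the
    pseudonym map.  The derived UID is ``2.25.`` followed by the decimal
    rendering of the low 128 bits of SHA-256(salt ‖ uid) — at most 44
    characters, well inside the 64-character DICOM UID limit.
    """

    salt: str
    algorithm: str = "sha256"
    uid_root: str = "2.25."

    def __post_init__(self) -> None:
        if not self.salt:
            raise ValueError("salt must be non-empty")

    def __repr__(self) -> str:  # keep the salt out of logs/tracebacks
        return f"HashingPolicy(algorithm={self.algorithm!r}, uid_root={self.uid_root!r})"


def hash_uid(uid: str, policy: HashingPolicy) -> str:
    """Derive the pseudonymous UID for ``uid`` under ``policy``."""
    if not uid:
        raise ValueError("uid must be non-empty")
    digest = hashlib.new(policy.algorithm, (policy.salt + uid).encode("utf-8")).digest()
    low128 = int.from_bytes(digest[-16:], "big")
    return f"{policy.uid_root}{low128}"


class PseudonymMap:
    """Persisted original→pseudonym table for patient IDs and accessions.

    Stored as a single-writer CSV (``kind,original,pseudonym``).  Pseudonyms
    are a fixed prefix plus a zero-padded allocation counter, syntactically
    distinguishable from any original.
    """

    def __init__(self, path: str | Path):
        self.path = Path(path)
        self.patient_entries: dict[str, str] = {}
        self.accession_entries: dict[str, str] = {}
        if self.path.exists():
            self._load()

    def _load(self) -> None:
        with open(self.path, newline="") as fh:
            for row in csv.reader(fh):
                if not row or row[0] == "kind":
                    continue
                kind, original, pseudonym = row
                target = self.patient_entries if kind == "patient" else self.accession_entries
                target[original] = pseudonym

    def save(self) -> None:
        with open(self.path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["kind", "original", "pseudonym"])
            for original, pseudonym in self.patient_entries.items():
                writer.writerow(["patient", original, pseudonym])
            for original, pseudonym in self.accession_entries.items():
                writer.writerow(["accession", original, pseudonym])

    def patient(self, original: str) -> str:
        if original not in self.patient_entries:
            self.patient_entries[original] = f"PSN-{len(self.patient_entries) + 1:06d}"
        return self.patient_entries[original]

    def accession(self, original: str) -> str:
        if original not in self.accession_entries:
            self.accession_entries[original] = f"ACC-{len(self.accession_entries) + 1:06d}"
        return self.accession_entries[original]


def pseudonymize_resource(
    resource: ImagingStudyResource, pmap: PseudonymMap, policy: HashingPolicy
) -> ImagingStudyResource:
    series = [
        SeriesComponent(
            uid=hash_uid(s.uid, policy),
            modality=s.modality,
            number=s.number,
            description=s.description,
            number_of_instances=s.number_of_instances,
            body_site=s.body_site,
            laterality=s.laterality,
            body_part_raw=s.body_part_raw,
            laterality_raw=s.laterality_raw,
            instances=[
                InstanceComponent(
                    uid=hash_uid(i.uid, policy), sop_class=i.sop_class, number=i.number
                )
                for i in s.instances
            ],
        )
        for s in resource.series
    ]
    return ImagingStudyResource(
        study_uid=hash_uid(resource.study_uid, policy),
        accession_number=pmap.accession(resource.accession_number),
        patient_id=pmap.patient(resource.patient_id),
        status=resource.status,
        started=resource.started,
        modality=list(resource.modality),
        number_of_series=resource.number_of_series,
        number_of_instances=resource.number_of_instances,
        series=series,
    )


def pseudonymize_bundle(
    bundle: FhirBundle, pmap: PseudonymMap, policy: HashingPolicy
) -> FhirBundle:
    """Return a pseudonymized copy of ``bundle`` and persist new pseudonyms.

    The hierarchy relationships between the hashed UIDs are preserved, the
    count invariants still hold, and the serialized output contains no
    original UID, patient ID or accession number substring.
    """
    violations = validate_resource(bundle.resource)
    if violations:
        raise ValueError(f"refusing to pseudonymize an invalid resource: {violations}")
    resource = pseudonymize_resource(bundle.resource, pmap, policy)
    pmap.save()
    return FhirBundle(resource=resource, type=bundle.type)
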