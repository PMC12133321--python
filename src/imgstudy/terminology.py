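"""Terminology mapping: raw DICOM code values to coded concepts.

Covers the three mappings the conversion and analysis stages rely on:
BodyPartExamined → SNOMED-CT body structures (via a versioned CSV table
derived from the DICOM standard's published correspondence), laterality
codes → the SNOMED qualifier concepts of the FHIR R4 ImagingStudy laterality
binding, and modality codes → acquisition vs non-acquisition class.

DICOM editions revise the permitted BodyPartExamined values (e.g. "LEG" was
valid up to edition 2022d and then replaced by "LOWERLEG"), so each table
row carries an edition-range label and loading a table for a given edition
selects the rows valid in it.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

logger = logging.getLogger(__name__)

__all__ = [
    "SNOMED_URI",
    "CodedConcept",
    "MappingTable",
    "load_body_part_table",
    "map_body_part",
    "map_laterality",
    "classify_modality",
    "DEFAULT_NON_ACQUISITION",
]

SNOMED_URI = "http://snomed.info/sct"

#: Modalities treated as non-acquisition (derived/document objects) unless
#: overridden: structured reports, presentation states, key object
#: selections, segmentations, encapsulated documents, audio.
DEFAULT_NON_ACQUISITION = frozenset({"SR", "PR", "KO", "SEG", "DOC", "AU"})

#: SNOMED qualifier concepts of the FHIR R4 ImagingStudy series.laterality
#: example binding (DICOM CID 244).  "U" (unpaired) has no concept there.
_LATERALITY_CONCEPTS = {
    "L": ("7771000", "Left"),
    "R": ("24028007", "Right"),
    "B": ("51440002", "Right and left"),
}


@dataclass(frozen=True)
class CodedConcept:
    """A coded concept: terminology system URI, code and display text."""

    system: str
    code: str
    display: str

    def __post_init__(self) -> None:
        if not (self.system and self.code and self.display):
            raise ValueError("system, code and display must all be non-empty")


@dataclass
class MappingTable:
    """Raw value → concept lookup for one DICOM edition label."""

    version_label: str
    entries: dict[str, CodedConcept] = field(default_factory=dict)
    #: raw values looked up but not found, in first-seen order
    unmapped_events: list[str] = field(default_factory=list)


def _edition_in_range(edition: str, editions: str) -> bool:
    """True when ``edition`` falls inside a range label like ``-2022d``,
    ``2023a-`` or ``2020a-2022d`` (edition labels sort lexicographically)."""
    if not editions:
        return True
    lo, _, hi = editions.partition("-")
    if lo and edition < lo:
        return False
    if hi and edition > hi:
        return False
    return True


def load_body_part_table(
    path: str | Path | None = None, edition: str = "2024a"
) -> MappingTable:
    """Load the BodyPartExamined → SNOMED table valid for ``edition``.

    The bundled asset is a curated subset (~50 raw values) of the DICOM
    standard's body-part correspondence; supply ``path`` for a fuller or
    site-specific table with the same columns
    (``raw,snomed_code,display,editions``).
    """
    if path is None:
        source = resources.files("imgstudy.data").joinpath("body_part_snomed.csv")
        text = source.read_text()
    else:
        text = Path(path).read_text()
    table = MappingTable(version_label=edition)
    for row in csv.DictReader(text.splitlines()):
        if not _edition_in_range(edition, row.get("editions") or ""):
            continue
        raw = row["raw"].strip().upper()
        if raw in table.entries:
            raise ValueError(f"duplicate raw value {raw!r} in body-part table")
        table.entries[raw] = CodedConcept(SNOMED_URI, row["snomed_code"], row["display"])
    return table


def map_body_part(raw: str | None, table: MappingTable) -> CodedConcept | None:
    """Map a raw BodyPartExamined value to its SNOMED concept.

    Absent input maps to absent output.  A present but unknown value also
    yields no concept, but is recorded as an unmapped-value event on the
    table — the value still counts as *present* in completeness statistics.
    """
    if raw is None:
        return None
    key = raw.strip().upper()
    if not key:
        return None
    concept = table.entries.get(key)
    if concept is None:
        table.unmapped_events.append(key)
        logger.warning("no SNOMED mapping for body part %r (edition %s)", key, table.version_label)
    return concept


def map_laterality(raw: str | None) -> CodedConcept | None:
    """Map a raw laterality code to the SNOMED qualifier concept.

    "L"/"R"/"B" map to left/right/bilateral; "U" (unpaired) is a valid value
    with no concept in the target binding, so it maps to absent — as does
    anything unrecognized.
    """
    if raw is None:
        return None
    key = raw.strip().upper()
    entry = _LATERALITY_CONCEPTS.get(key)
    if entry is None:
        return None
    code, display = entry
    return CodedConcept(SNOMED_URI, code, display)


def is_valid_laterality(raw: str | None) -> bool:
    """Whether a raw value counts as a present, valid laterality (L/R/B/U)."""
    return raw is not None and raw.strip().upper() in ("L", "R", "B", "U")


def classify_modality(
    modality: str, non_acquisition_set: frozenset[str] | set[str] = DEFAULT_NON_ACQUISITION
) -> str:
    """Classify a modality code as ``acquisition`` or ``non_acquisition``.

    Unknown codes default to acquisition (with a warning) so completeness
    denominators stay conservative.
    """
    if not modality:
        raise ValueError("modality must be non-empty")
    code = modality.strip().upper()
    if code in non_acquisition_set:
        return "non_acquisition"
    _KNOWN_ACQ = {
        "CT", "MR", "DX", "CR", "XA", "US", "NM", "PT", "MG", "RF", "XC",
        "OT", "SC", "OP", "OCT", "ES", "IVUS", "PX", "RG", "BI",
    }
    if code not in _KNOWN_ACQ:
        logger.warning("unknown modality %r classified as acquisition", code)
    return "acquisition"
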