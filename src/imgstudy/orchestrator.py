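"""Sequential study-level pipeline orchestration.

Processes an inbox of incoming DICOM objects strictly in transfer-manifest
order: count a study's received objects against the expected count, convert
to a FHIR bundle and pseudonymize only when the transfer is complete, append
the bundle to an NDJSON sink, and delete the study's objects before the next
study starts — which prevents file mixing between studies and keeps storage
bounded.  Completeness is decided by object counting because a folder-based
DICOM endpoint cannot itself signal that a study has fully arrived.
"""

from __future__ import annotations

import logging
import os
import time
from dataclasses import dataclass, field
from pathlib import Path

from .dicom_io import DicomInstanceMeta, DicomReadError, group_instances, read_instance
from .fhir_model import BuildError, build_imaging_study, dumps_bundle, validate_resource, wrap_bundle
from .pseudonymize import HashingPolicy, PseudonymMap, pseudonymize_bundle
from .synthgen import TransferManifest
from .terminology import MappingTable, load_body_part_table
from ._util import pct_round_half_up

logger = logging.getLogger(__name__)

__all__ = ["StudyResult", "RunReport", "process_inbox", "completion_rate"]

SUCCESS = "success"
INCOMPLETE = "incomplete_transfer"
CONVERSION_ERROR = "conversion_error"


@dataclass
class StudyResult:
    accession: str
    status: str
    expected: int
    received: int
    emitted: bool = False
    excluded: int = 0


@dataclass
class RunReport:
    results: list[StudyResult] = field(default_factory=list)

    @property
    def processed_count(self) -> int:
        return len(self.results)

    @property
    def successes(self) -> int:
        return sum(1 for r in self.results if r.status == SUCCESS)

    @property
    def completion_fraction(self) -> float:
        if not self.results:
            raise ValueError("empty report")
        return self.successes / len(self.results)

    def to_csv(self, path: str | Path) -> None:
        import csv

        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["accession", "status", "expected", "received", "emitted", "excluded"])
            for r in self.results:
                writer.writerow(
                    [r.accession, r.status, r.expected, r.received, r.emitted, r.excluded]
                )


def completion_rate(report: RunReport) -> int:
    """Percentage of successfully transferred and converted studies,
    rounded half-up to an integer."""
    if not report.results:
        raise ValueError("empty report")
    return pct_round_half_up(report.successes, len(report.results))


def _scan(inbox: Path, seen: set[Path]) -> list[Path]:
    """New files under the inbox (recursive), in sorted order."""
    found = []
    for root, _dirs, files in os.walk(inbox):
        for name in files:
            p = Path(root) / name
            if p not in seen:
                found.append(p)
    return sorted(found)


def _delete(paths: list[Path], inbox: Path) -> None:
    for p in paths:
        try:
            p.unlink()
        except OSError as exc:  # pragma: no cover - filesystem race
            logger.warning("could not delete %s: %s", p, exc)
    # prune empty study folders
    for root, dirs, files in os.walk(inbox, topdown=False):
        d = Path(root)
        if d != inbox and not any(d.iterdir()):
            d.rmdir()


def process_inbox(
    inbox: str | Path,
    manifest: TransferManifest,
    sink: str | Path,
    pmap: PseudonymMap,
    policy: HashingPolicy,
    wait_timeout: float = 5.0,
    quiescence: float = 2.0,
    sop_whitelist: set[str] | None = None,
    body_part_table: MappingTable | None = None,
) -> RunReport:
    """Run the full transfer-verify → convert → pseudonymize → emit → delete
    cycle over every manifest entry, strictly sequentially.

    A study converts only when its received object count equals the
    manifest's expected count before the timeout; in every terminal state
    the study's files are deleted before the next study starts, so the inbox
    is empty when the run ends.  Objects whose SOP class falls outside an
    optional whitelist are rejected on arrival (never counted as received),
    reproducing the count-shortfall failure mode of DICOM endpoints that
    cannot accept certain SOP classes.
    """
    if not manifest.entries:
        raise ValueError("manifest is empty")
    inbox = Path(inbox)
    table = body_part_table if body_part_table is not None else load_body_part_table()
    report = RunReport()
    t_start = time.monotonic()

    seen: set[Path] = set()
    by_accession: dict[str, list[tuple[Path, DicomInstanceMeta]]] = {}
    excluded_by_accession: dict[str, list[Path]] = {}
    unparseable: list[Path] = []

    def ingest_new() -> int:
        new = _scan(inbox, seen)
        for path in new:
            seen.add(path)
            try:
                meta = read_instance(path)
            except DicomReadError as exc:
                logger.warning("%s", exc)
                unparseable.append(path)
                continue
            if sop_whitelist is not None and meta.sop_class_uid not in sop_whitelist:
                logger.warning(
                    "rejected SOP class %s (%s): outside whitelist", meta.sop_class_uid, path
                )
                excluded_by_accession.setdefault(meta.accession_number, []).append(path)
                continue
            by_accession.setdefault(meta.accession_number, []).append((path, meta))
        return len(new)

    ingest_new()

    with open(sink, "a", encoding="utf-8") as sink_fh:
        for accession, expected in manifest.entries:
            deadline = time.monotonic() + wait_timeout
            last_change = time.monotonic()
            while len(by_accession.get(accession, [])) < expected:
                now = time.monotonic()
                if now >= deadline or now - last_change >= quiescence:
                    break
                time.sleep(0.05)
                if ingest_new():
                    last_change = time.monotonic()

            items = by_accession.pop(accession, [])
            excluded = excluded_by_accession.pop(accession, [])
            received = len(items)
            paths = [p for p, _ in items] + excluded
            if received != expected:
                logger.warning(
                    "%s incomplete_transfer expected=%d received=%d", accession, expected, received
                )
                report.results.append(
                    StudyResult(accession, INCOMPLETE, expected, received, excluded=len(excluded))
                )
                _delete(paths, inbox)
                continue

            try:
                emitted = 0
                for study in group_instances([m for _, m in items]):
                    resource = build_imaging_study(study, table)
                    violations = validate_resource(resource)
                    if violations:
                        raise BuildError(f"invalid resource: {violations}")
                    bundle = pseudonymize_bundle(wrap_bundle(resource), pmap, policy)
                    sink_fh.write(dumps_bundle(bundle))
                    sink_fh.write("\n")
                    emitted += 1
                sink_fh.flush()
                logger.info("%s success objects=%d bundles=%d", accession, received, emitted)
                report.results.append(
                    StudyResult(
                        accession, SUCCESS, expected, received,
                        emitted=emitted > 0, excluded=len(excluded),
                    )
                )
            except (BuildError, ValueError) as exc:
                logger.warning("%s conversion_error: %s", accession, exc)
                report.results.append(
                    StudyResult(
                        accession, CONVERSION_ERROR, expected, received, excluded=len(excluded)
                    )
                )
            finally:
                _delete(paths, inbox)

        # On-disk studies without a manifest entry: conversion errors, deleted.
        for accession in sorted(by_accession):
            items = by_accession.pop(accession)
            logger.warning("%s has no manifest entry: conversion_error", accession)
            report.results.append(
                StudyResult(accession, CONVERSION_ERROR, expected=0, received=len(items))
            )
            _delete([p for p, _ in items], inbox)
        for accession in sorted(excluded_by_accession):
            _delete(excluded_by_accession.pop(accession), inbox)
        _delete(unparseable, inbox)

    elapsed = time.monotonic() - t_start
    if elapsed > 0:
        logger.info(
            "processed %d studies in %.1f s (%.1f studies/min)",
            report.processed_count, elapsed, 60.0 * report.processed_count / elapsed,
        )
    return report
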