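"""Metadata-quality reporting over ImagingStudy bundles.

Computes the completeness/quality statistics of a converted corpus: study,
series and instance counts, series grouped by modality and by raw body
region (including a MISSING bucket), acquisition vs non-acquisition series
fractions, field completion rates for modality, body region and laterality,
per-study averages, and the laterality distribution within paired body
regions.

The unit of analysis is the DICOM *series* throughout; studies enter only
the two per-study means.  Percentages are computed on exact counts and kept
as exact fractions in the report; display values round half-up to integers.
Missingness is assessed on the raw header values carried through conversion
(pre-mapping), so a present-but-unmappable body region still counts as
present.  A raw laterality value is valid when it is one of L, R, B, U;
"U" counts as a valid value for the completion rate but as neither L nor R
in the paired-region table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Union

import pandas as pd

from ._util import pct_round_half_up, round_half_up
from .fhir_model import FhirBundle, read_ndjson
from .terminology import DEFAULT_NON_ACQUISITION, classify_modality, is_valid_laterality

logger = logging.getLogger(__name__)

__all__ = [
    "MetricsReport",
    "LateralityRow",
    "LateralityTable",
    "analyze",
    "laterality_by_region",
    "export_report",
    "MISSING",
]

MISSING = "MISSING"
PAIRED_REGIONS = ("KNEE", "HAND", "FOOT", "ANKLE", "SHOULDER")

BundleSource = Union[str, Path, Iterable[FhirBundle]]


@dataclass
class MetricsReport:
    """Corpus-level metadata-quality statistics (exact fractions retained)."""

    n_studies: int
    n_series: int
    n_instances: int
    series_by_modality: dict[str, int]
    acquisition_count: int
    non_acquisition_count: int
    series_by_body_region: dict[str, int]
    laterality_valid_count: int
    body_region_present_count: int
    modality_present_count: int
    body_region_missing_acquisition_count: int
    rejects: int = 0

    # -- exact fractions -----------------------------------------------------
    @property
    def acquisition_fraction(self) -> float:
        return 100.0 * self.acquisition_count / self.n_series

    @property
    def non_acquisition_fraction(self) -> float:
        return 100.0 * self.non_acquisition_count / self.n_series

    @property
    def completion_rate_modality(self) -> float:
        return 100.0 * self.modality_present_count / self.n_series

    @property
    def completion_rate_body_region(self) -> float:
        return 100.0 * self.body_region_present_count / self.n_series

    @property
    def completion_rate_laterality(self) -> float:
        return 100.0 * self.laterality_valid_count / self.n_series

    @property
    def laterality_missing_fraction(self) -> float:
        return 100.0 - self.completion_rate_laterality

    @property
    def body_region_missing_fraction(self) -> float:
        return 100.0 * self.series_by_body_region.get(MISSING, 0) / self.n_series

    @property
    def body_region_missing_acquisition_only(self) -> float:
        if self.acquisition_count == 0:
            return 0.0
        return 100.0 * self.body_region_missing_acquisition_count / self.acquisition_count

    @property
    def mean_series_per_study(self) -> float:
        return self.n_series / self.n_studies

    @property
    def mean_instances_per_study(self) -> float:
        return self.n_instances / self.n_studies

    def region_fraction(self, region: str) -> float:
        return 100.0 * self.series_by_body_region.get(region, 0) / self.n_series

    def ranked_regions(self) -> list[tuple[str, int]]:
        """Non-missing regions by descending count (ties by name)."""
        return sorted(
            ((r, c) for r, c in self.series_by_body_region.items() if r != MISSING),
            key=lambda rc: (-rc[1], rc[0]),
        )

    def display(self) -> dict[str, float]:
        """Rounded values as printed in a report: integer percentages
        (half-up), means to one decimal.  Acquisition/non-acquisition are
        reconciled to sum to 100 after rounding."""
        acq = pct_round_half_up(self.acquisition_count, self.n_series)
        return {
            "n_studies": self.n_studies,
            "n_series": self.n_series,
            "n_instances": self.n_instances,
            "acquisition_pct": acq,
            "non_acquisition_pct": 100 - acq,
            "modality_completion_pct": pct_round_half_up(self.modality_present_count, self.n_series),
            "body_region_completion_pct": pct_round_half_up(
                self.body_region_present_count, self.n_series
            ),
            "body_region_missing_pct": pct_round_half_up(
                self.series_by_body_region.get(MISSING, 0), self.n_series
            ),
            "laterality_completion_pct": pct_round_half_up(
                self.laterality_valid_count, self.n_series
            ),
            "laterality_missing_pct": pct_round_half_up(
                self.n_series - self.laterality_valid_count, self.n_series
            ),
            "body_region_missing_acquisition_only_pct": (
                pct_round_half_up(
                    self.body_region_missing_acquisition_count, self.acquisition_count
                )
                if self.acquisition_count
                else 0
            ),
            "mean_series_per_study": round_half_up(self.mean_series_per_study, 1),
            "mean_instances_per_study": round_half_up(self.mean_instances_per_study, 1),
        }


@dataclass
class LateralityRow:
    region: str
    n_series: int
    n_missing: int
    n_left: int
    n_right: int
    n_bilateral: int
    n_unpaired: int

    def display(self) -> tuple[int, int, int]:
        """(missing, L, R) integer percentages; B/U tallied but not shown."""
        return (
            pct_round_half_up(self.n_missing, self.n_series),
            pct_round_half_up(self.n_left, self.n_series),
            pct_round_half_up(self.n_right, self.n_series),
        )


@dataclass
class LateralityTable:
    rows: dict[str, LateralityRow] = field(default_factory=dict)


def _iter_bundles(bundles: BundleSource) -> tuple[list[FhirBundle], int]:
    """Materialize bundles, counting (and skipping) malformed NDJSON lines."""
    if isinstance(bundles, (str, Path)):
        out: list[FhirBundle] = []
        rejects = 0
        import json

        with open(bundles, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line:
                    continue
                try:
                    from .fhir_model import loads_bundle

                    out.append(loads_bundle(line))
                except (json.JSONDecodeError, KeyError, ValueError) as exc:
                    logger.warning("skipping malformed bundle at line %d: %s", lineno, exc)
                    rejects += 1
        return out, rejects
    return list(bundles), 0


def analyze(
    bundles: BundleSource,
    non_acquisition: frozenset[str] | set[str] = DEFAULT_NON_ACQUISITION,
) -> MetricsReport:
    """Compute the corpus metrics report from a stream of bundles.

    ``bundles`` may be an NDJSON path or an iterable of parsed bundles.
    Malformed NDJSON lines are skipped with a warning and counted in
    ``rejects``.
    """
    items, rejects = _iter_bundles(bundles)
    if not items:
        raise ValueError("no bundles to analyze")

    n_studies = len(items)
    n_series = 0
    n_instances = 0
    by_modality: dict[str, int] = {}
    by_region: dict[str, int] = {}
    acq = nonacq = 0
    lat_valid = 0
    region_present = 0
    modality_present = 0
    missing_region_acq = 0

    for bundle in items:
        resource = bundle.resource
        n_instances += resource.number_of_instances
        for s in resource.series:
            n_series += 1
            code = (s.modality.code or "").strip().upper()
            by_modality[code] = by_modality.get(code, 0) + 1
            if code:
                modality_present += 1
            klass = classify_modality(code or "OT", non_acquisition)
            is_acq = klass == "acquisition"
            acq += is_acq
            nonacq += not is_acq

            raw_region = (s.body_part_raw or "").strip().upper()
            if raw_region:
                region_present += 1
                by_region[raw_region] = by_region.get(raw_region, 0) + 1
            else:
                by_region[MISSING] = by_region.get(MISSING, 0) + 1
                if is_acq:
                    missing_region_acq += 1

            lat_valid += is_valid_laterality(s.laterality_raw)

    return MetricsReport(
        n_studies=n_studies,
        n_series=n_series,
        n_instances=n_instances,
        series_by_modality=dict(sorted(by_modality.items(), key=lambda kv: (-kv[1], kv[0]))),
        acquisition_count=acq,
        non_acquisition_count=nonacq,
        series_by_body_region=dict(sorted(by_region.items(), key=lambda kv: (-kv[1], kv[0]))),
        laterality_valid_count=lat_valid,
        body_region_present_count=region_present,
        modality_present_count=modality_present,
        body_region_missing_acquisition_count=missing_region_acq,
        rejects=rejects,
    )


def laterality_by_region(
    bundles: BundleSource, regions: Iterable[str] = PAIRED_REGIONS
) -> LateralityTable:
    """Tally laterality values within each requested (paired) body region.

    Percentages are over all series of that region.  A requested region with
    no series in the data is omitted from the table with a warning.
    """
    regions = [r.strip().upper() for r in regions]
    if not regions:
        raise ValueError("regions must be non-empty")
    items, _ = _iter_bundles(bundles)
    tallies: dict[str, dict[str, int]] = {r: {"": 0, "L": 0, "R": 0, "B": 0, "U": 0} for r in regions}
    for bundle in items:
        for s in bundle.resource.series:
            raw_region = (s.body_part_raw or "").strip().upper()
            if raw_region not in tallies:
                continue
            lat = (s.laterality_raw or "").strip().upper()
            if lat not in ("L", "R", "B", "U"):
                lat = ""
            tallies[raw_region][lat] += 1

    table = LateralityTable()
    for region in regions:
        t = tallies[region]
        total = sum(t.values())
        if total == 0:
            logger.warning("region %s not present in data: row omitted", region)
            continue
        table.rows[region] = LateralityRow(
            region=region,
            n_series=total,
            n_missing=t[""],
            n_left=t["L"],
            n_right=t["R"],
            n_bilateral=t["B"],
            n_unpaired=t["U"],
        )
    return table


def export_report(
    report: MetricsReport, table: LateralityTable, out_dir: str | Path
) -> dict[str, Path]:
    """Write the report as CSV files with deterministic column/row order.

    Emits ``summary.csv``, ``series_by_modality.csv``, ``series_by_region.csv``
    and ``laterality_by_region.csv``; each carries both the exact fraction
    and the rounded display value.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    disp = report.display()
    summary_rows = [
        ("n_studies", float(report.n_studies), disp["n_studies"]),
        ("n_series", float(report.n_series), disp["n_series"]),
        ("n_instances", float(report.n_instances), disp["n_instances"]),
        ("acquisition_pct", report.acquisition_fraction, disp["acquisition_pct"]),
        ("non_acquisition_pct", report.non_acquisition_fraction, disp["non_acquisition_pct"]),
        ("modality_completion_pct", report.completion_rate_modality, disp["modality_completion_pct"]),
        (
            "body_region_completion_pct",
            report.completion_rate_body_region,
            disp["body_region_completion_pct"],
        ),
        ("body_region_missing_pct", report.body_region_missing_fraction, disp["body_region_missing_pct"]),
        (
            "laterality_completion_pct",
            report.completion_rate_laterality,
            disp["laterality_completion_pct"],
        ),
        ("laterality_missing_pct", report.laterality_missing_fraction, disp["laterality_missing_pct"]),
        (
            "body_region_missing_acquisition_only_pct",
            report.body_region_missing_acquisition_only,
            disp["body_region_missing_acquisition_only_pct"],
        ),
        ("mean_series_per_study", report.mean_series_per_study, disp["mean_series_per_study"]),
        ("mean_instances_per_study", report.mean_instances_per_study, disp["mean_instances_per_study"]),
        ("rejects", float(report.rejects), report.rejects),
    ]
    paths["summary"] = out / "summary.csv"
    pd.DataFrame(summary_rows, columns=["metric", "exact", "display"]).to_csv(
        paths["summary"], index=False
    )

    paths["series_by_modality"] = out / "series_by_modality.csv"
    pd.DataFrame(
        [
            (m, c, 100.0 * c / report.n_series, pct_round_half_up(c, report.n_series))
            for m, c in report.series_by_modality.items()
        ],
        columns=["modality", "count", "pct_exact", "pct_display"],
    ).to_csv(paths["series_by_modality"], index=False)

    paths["series_by_region"] = out / "series_by_region.csv"
    pd.DataFrame(
        [
            (r, c, 100.0 * c / report.n_series, pct_round_half_up(c, report.n_series))
            for r, c in report.series_by_body_region.items()
        ],
        columns=["body_region", "count", "pct_exact", "pct_display"],
    ).to_csv(paths["series_by_region"], index=False)

    paths["laterality_by_region"] = out / "laterality_by_region.csv"
    lat_rows = []
    for region in sorted(table.rows):
        row = table.rows[region]
        miss, left, right = row.display()
        lat_rows.append(
            (
                region, row.n_series, row.n_missing, row.n_left, row.n_right,
                row.n_bilateral, row.n_unpaired, miss, left, right,
            )
        )
    pd.DataFrame(
        lat_rows,
        columns=[
            "body_region", "n_series", "n_missing", "n_left", "n_right",
            "n_bilateral", "n_unpaired", "missing_pct", "left_pct", "right_pct",
        ],
    ).to_csv(paths["laterality_by_region"], index=False)
    return paths
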