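"""Synthetic DICOM corpus generation.

Builds directories of valid DICOM Part-10 files (tiny dummy pixel payloads)
whose header statistics follow a configurable :class:`CorpusProfile` —
modality mix, body-region distribution including missing values, per-region
laterality splits, series/objects-per-study structure and injectable
incomplete-transfer faults — together with the transfer manifest
(accession → expected object count) that a downstream pipeline verifies
against.

Two modes are supported.  In ``deterministic`` mode category counts are
apportioned exactly by largest remainder and assigned to series in sorted
(study-major) order, so realized counts equal the profile's shares to the
unit.  In ``stochastic`` mode every attribute is sampled from the profile's
distributions with a seeded generator, so repeated runs with the same seed
are byte-identical.
"""

from __future__ import annotations

import csv
import datetime
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian

from ._util import apportion

__all__ = [
    "CorpusProfile",
    "TransferManifest",
    "SeriesPlan",
    "StudyPlan",
    "plan_corpus",
    "generate_corpus",
    "builtin_profile",
    "MISSING",
]

#: Sentinel key used in share maps for "attribute absent".
MISSING = "MISSING"

#: UID root for all synthetic identifiers (deliberately not under 2.25,
#: which is reserved here for pseudonymized UIDs).
UID_ROOT = "1.2.826.0.1.3680043.9.7432"

# Standard storage SOP classes per modality; unknown modalities fall back
# to Secondary Capture.
_SOP_CLASS_BY_MODALITY = {
    "CT": "1.2.840.10008.5.1.4.1.1.2",
    "MR": "1.2.840.10008.5.1.4.1.1.4",
    "DX": "1.2.840.10008.5.1.4.1.1.1.1",
    "CR": "1.2.840.10008.5.1.4.1.1.1",
    "XA": "1.2.840.10008.5.1.4.1.1.12.1",
    "US": "1.2.840.10008.5.1.4.1.1.6.1",
    "NM": "1.2.840.10008.5.1.4.1.1.20",
    "PT": "1.2.840.10008.5.1.4.1.1.128",
    "SR": "1.2.840.10008.5.1.4.1.1.88.11",
    "PR": "1.2.840.10008.5.1.4.1.1.11.1",
    "KO": "1.2.840.10008.5.1.4.1.1.88.59",
}
_SECONDARY_CAPTURE = "1.2.840.10008.5.1.4.1.1.7"
#: SOP classes that carry no pixel payload.
_NON_IMAGE_MODALITIES = {"SR", "PR", "KO"}

_SHARE_TOL = 1e-9


class ProfileError(ValueError):
    """Raised when a corpus profile violates its invariants."""


@dataclass(frozen=True)
class CorpusProfile:
    """Statistical recipe for a synthetic multi-department radiology corpus.

    Parameters
    ----------
    n_studies:
        Number of DICOM studies (one patient per study).
    series_per_study:
        Series count per study (a fixed integer).
    objects_per_study:
        Mixture of (objects-per-study, weight) components; the weight is the
        fraction of studies drawing that object count.
    modality_shares:
        Map modality code → fraction of all series.
    body_region_shares:
        Map raw BodyPartExamined value (or ``MISSING``) → fraction of all
        series.  Series of modalities listed in ``missing_region_modalities``
        always have no body region and consume part of the ``MISSING`` share.
    laterality_splits:
        Map region → (missing, L, R, B, U) fractions over that region's
        series.  Regions not listed default to all-missing.
    fault_fraction:
        Fraction of studies with one withheld object (incomplete transfer);
        the manifest keeps the full expected count.
    """

    name: str
    n_studies: int
    series_per_study: int
    objects_per_study: tuple[tuple[int, float], ...]
    modality_shares: Mapping[str, float]
    body_region_shares: Mapping[str, float]
    laterality_splits: Mapping[str, tuple[float, float, float, float, float]]
    missing_region_modalities: tuple[str, ...] = ()
    fault_fraction: float = 0.0
    seed: int = 0
    mode: str = "deterministic"

    def __post_init__(self) -> None:
        if self.n_studies < 1:
            raise ProfileError("n_studies must be >= 1")
        if self.series_per_study < 1:
            raise ProfileError("series_per_study must be >= 1")
        if not 0.0 <= self.fault_fraction <= 1.0:
            raise ProfileError("fault_fraction must lie in [0, 1]")
        if self.mode not in ("deterministic", "stochastic"):
            raise ProfileError(f"unknown mode {self.mode!r}")
        for label, shares in (
            ("modality_shares", self.modality_shares.values()),
            ("body_region_shares", self.body_region_shares.values()),
            ("objects_per_study weights", [w for _, w in self.objects_per_study]),
        ):
            total = float(sum(shares))
            if abs(total - 1.0) > _SHARE_TOL:
                raise ProfileError(f"{label} sum to {total!r}, expected 1")
        for region, split in self.laterality_splits.items():
            if len(split) != 5:
                raise ProfileError(f"laterality split for {region} must have 5 entries")
            if abs(sum(split) - 1.0) > _SHARE_TOL:
                raise ProfileError(f"laterality split for {region} does not sum to 1")
        forced = sum(
            self.modality_shares.get(m, 0.0) for m in self.missing_region_modalities
        )
        if forced - self.body_region_shares.get(MISSING, 0.0) > _SHARE_TOL:
            raise ProfileError(
                "MISSING body-region share is smaller than the share of "
                "modalities that never carry a body region"
            )


@dataclass(frozen=True)
class TransferManifest:
    """Expected object count per accession, standing in for a PACS query."""

    entries: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        accessions = [a for a, _ in self.entries]
        if len(set(accessions)) != len(accessions):
            raise ValueError("accession numbers must be unique")
        if any(c < 1 for _, c in self.entries):
            raise ValueError("expected counts must be >= 1")

    def expected(self, accession: str) -> int | None:
        for acc, count in self.entries:
            if acc == accession:
                return count
        return None

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["accession", "expected_count"])
            writer.writerows(self.entries)

    @classmethod
    def from_csv(cls, path: str | Path) -> "TransferManifest":
        with open(path, newline="") as fh:
            rows = list(csv.reader(fh))
        return cls(tuple((acc, int(count)) for acc, count in rows[1:]))


@dataclass(frozen=True)
class SeriesPlan:
    series_uid: str
    series_number: int
    modality: str
    body_part: str | None
    laterality: str | None
    n_instances: int
    sop_class_uid: str


@dataclass(frozen=True)
class StudyPlan:
    index: int
    study_uid: str
    accession: str
    patient_id: str
    study_date: str
    study_time: str
    faulted: bool
    series: tuple[SeriesPlan, ...]

    @property
    def n_objects(self) -> int:
        return sum(s.n_instances for s in self.series)


def _study_identity(index: int) -> tuple[str, str, str, str, str]:
    """Deterministic identifiers for study ``index`` (0-based)."""
    uid = f"{UID_ROOT}.1.{index + 1}"
    accession = f"A{index + 1:05d}"
    patient_id = f"P{index + 1:05d}"
    date = datetime.date(2022, 1, 1) + datetime.timedelta(days=index % 365)
    time = f"{8 + index % 10:02d}0000"
    return uid, accession, patient_id, date.strftime("%Y%m%d"), time


def _fault_indices(profile: CorpusProfile, rng: np.random.Generator | None) -> set[int]:
    n = profile.n_studies
    k = int(np.floor(profile.fault_fraction * n + 0.5))
    if k == 0:
        return set()
    if rng is None:  # deterministic: evenly spaced study indices
        return {i * n // k for i in range(k)}
    return set(rng.choice(n, size=k, replace=False).tolist())


def _plan_deterministic(profile: CorpusProfile) -> list[StudyPlan]:
    n_studies = profile.n_studies
    n_series = n_studies * profile.series_per_study

    # Objects per study: apportion studies across mixture components, then
    # assign component object counts to studies in index order.
    comp_counts = apportion(n_studies, [w for _, w in profile.objects_per_study])
    objects_per_study: list[int] = []
    for (count, _), n_comp in zip(profile.objects_per_study, comp_counts):
        objects_per_study.extend([count] * n_comp)

    # Modality: apportion over all series, assign in blocks by flat index.
    mod_keys = list(profile.modality_shares)
    mod_counts = apportion(n_series, [profile.modality_shares[m] for m in mod_keys])
    modality_of = np.empty(n_series, dtype=object)
    pos = 0
    for m, c in zip(mod_keys, mod_counts):
        modality_of[pos : pos + c] = m
        pos += c

    # Body region: apportion over all series; series of forced modalities
    # always take MISSING, consuming part of the MISSING budget; named
    # regions and the residual MISSING fill the unconstrained series.
    reg_keys = list(profile.body_region_shares)
    reg_counts = dict(
        zip(reg_keys, apportion(n_series, [profile.body_region_shares[r] for r in reg_keys]))
    )
    forced = set(profile.missing_region_modalities)
    forced_idx = [i for i in range(n_series) if modality_of[i] in forced]
    free_idx = [i for i in range(n_series) if modality_of[i] not in forced]
    residual_missing = reg_counts.get(MISSING, 0) - len(forced_idx)
    if residual_missing < 0:
        raise ProfileError(
            "realized MISSING body-region count is smaller than the number of "
            "series whose modality never carries a body region"
        )
    region_of = np.empty(n_series, dtype=object)
    for i in forced_idx:
        region_of[i] = None
    cursor = 0
    for r in reg_keys:
        c = residual_missing if r == MISSING else reg_counts[r]
        for i in free_idx[cursor : cursor + c]:
            region_of[i] = None if r == MISSING else r
        cursor += c

    # Laterality: apportion the 5-way split within each region's series.
    lat_of = np.empty(n_series, dtype=object)
    lat_codes = (None, "L", "R", "B", "U")
    by_region: dict[str | None, list[int]] = {}
    for i in range(n_series):
        by_region.setdefault(region_of[i], []).append(i)
    for region, indices in by_region.items():
        split = profile.laterality_splits.get(region, (1.0, 0.0, 0.0, 0.0, 0.0)) if region else (
            1.0,
            0.0,
            0.0,
            0.0,
            0.0,
        )
        counts = apportion(len(indices), list(split))
        cur = 0
        for code, c in zip(lat_codes, counts):
            for i in indices[cur : cur + c]:
                lat_of[i] = code
            cur += c

    return _assemble(profile, objects_per_study, modality_of, region_of, lat_of, rng=None)


def _plan_stochastic(profile: CorpusProfile, rng: np.random.Generator) -> list[StudyPlan]:
    n_studies = profile.n_studies
    n_series = n_studies * profile.series_per_study

    comp_sizes = [c for c, _ in profile.objects_per_study]
    comp_weights = [w for _, w in profile.objects_per_study]
    objects_per_study = [
        comp_sizes[j] for j in rng.choice(len(comp_sizes), size=n_studies, p=comp_weights)
    ]

    mod_keys = list(profile.modality_shares)
    mod_p = [profile.modality_shares[m] for m in mod_keys]
    modality_of = np.array(
        [mod_keys[j] for j in rng.choice(len(mod_keys), size=n_series, p=mod_p)], dtype=object
    )

    forced = set(profile.missing_region_modalities)
    forced_share = sum(profile.modality_shares.get(m, 0.0) for m in forced)
    reg_keys = [r for r in profile.body_region_shares if r != MISSING]
    residual_missing_share = profile.body_region_shares.get(MISSING, 0.0) - forced_share
    cond_keys = reg_keys + [MISSING]
    denom = 1.0 - forced_share
    cond_p = np.array(
        [profile.body_region_shares[r] for r in reg_keys] + [max(residual_missing_share, 0.0)]
    )
    cond_p = cond_p / cond_p.sum() if denom > 0 else cond_p

    region_of = np.empty(n_series, dtype=object)
    lat_of = np.empty(n_series, dtype=object)
    lat_codes = (None, "L", "R", "B", "U")
    for i in range(n_series):
        if modality_of[i] in forced:
            region_of[i] = None
        else:
            r = cond_keys[rng.choice(len(cond_keys), p=cond_p)]
            region_of[i] = None if r == MISSING else r
        split = (
            profile.laterality_splits.get(region_of[i], (1.0, 0.0, 0.0, 0.0, 0.0))
            if region_of[i]
            else (1.0, 0.0, 0.0, 0.0, 0.0)
        )
        lat_of[i] = lat_codes[rng.choice(5, p=np.asarray(split) / sum(split))]

    return _assemble(profile, objects_per_study, modality_of, region_of, lat_of, rng=rng)


def _assemble(
    profile: CorpusProfile,
    objects_per_study: Sequence[int],
    modality_of: Sequence[str],
    region_of: Sequence[str | None],
    lat_of: Sequence[str | None],
    rng: np.random.Generator | None,
) -> list[StudyPlan]:
    fault_idx = _fault_indices(profile, rng)
    plans: list[StudyPlan] = []
    sps = profile.series_per_study
    for i in range(profile.n_studies):
        uid, accession, patient_id, date, time = _study_identity(i)
        per_series = apportion(objects_per_study[i], [1.0] * sps)
        series = []
        for j in range(sps):
            flat = i * sps + j
            modality = modality_of[flat]
            series.append(
                SeriesPlan(
                    series_uid=f"{UID_ROOT}.2.{i + 1}.{j + 1}",
                    series_number=j + 1,
                    modality=modality,
                    body_part=region_of[flat],
                    laterality=lat_of[flat],
                    n_instances=per_series[j],
                    sop_class_uid=_SOP_CLASS_BY_MODALITY.get(modality, _SECONDARY_CAPTURE),
                )
            )
        plans.append(
            StudyPlan(
                index=i,
                study_uid=uid,
                accession=accession,
                patient_id=patient_id,
                study_date=date,
                study_time=time,
                faulted=i in fault_idx,
                series=tuple(series),
            )
        )
    return plans


def plan_corpus(profile: CorpusProfile) -> list[StudyPlan]:
    """Lay out the full corpus as per-series attribute plans, without I/O.

    This is the ground-truth assignment list: tests can tally it directly
    and compare against what the pipeline reports after the DICOM and FHIR
    round trip.
    """
    if profile.mode == "deterministic":
        return _plan_deterministic(profile)
    return _plan_stochastic(profile, np.random.default_rng(profile.seed))


def _instance_dataset(study: StudyPlan, series: SeriesPlan, k: int) -> Dataset:
    ds = Dataset()
    ds.SOPClassUID = series.sop_class_uid
    ds.SOPInstanceUID = f"{series.series_uid}.{k + 1}"
    ds.StudyInstanceUID = study.study_uid
    ds.SeriesInstanceUID = series.series_uid
    ds.Modality = series.modality
    ds.PatientID = study.patient_id
    ds.AccessionNumber = study.accession
    ds.StudyDate = study.study_date
    ds.StudyTime = study.study_time
    ds.SeriesNumber = series.series_number
    ds.InstanceNumber = k + 1
    ds.SeriesDescription = f"{series.modality} {series.body_part or 'series'}"
    if series.body_part is not None:
        ds.BodyPartExamined = series.body_part
    if series.laterality in ("L", "R"):
        ds.Laterality = series.laterality
    elif series.laterality in ("B", "U"):
        # B/U are only legal in Image Laterality (0020,0062).
        ds.ImageLaterality = series.laterality
    if series.modality not in _NON_IMAGE_MODALITIES:
        ds.Rows = 2
        ds.Columns = 2
        ds.BitsAllocated = 8
        ds.BitsStored = 8
        ds.HighBit = 7
        ds.PixelRepresentation = 0
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.PixelData = bytes([0, 1, 2, 3])
    else:
        ds.ConceptNameCodeSequence = []

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = ds.SOPClassUID
    meta.MediaStorageSOPInstanceUID = ds.SOPInstanceUID
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    meta.ImplementationClassUID = f"{UID_ROOT}.0.1"
    ds.file_meta = meta
    return ds


def generate_corpus(
    profile: CorpusProfile,
    out_dir: str | Path,
    *,
    seed: int | None = None,
    mode: str | None = None,
) -> TransferManifest:
    """Materialize a corpus on disk, one folder per study, one file per object.

    Returns the transfer manifest whose expected counts include objects
    withheld from faulted studies (so the on-disk count falls one short for
    each faulted study, mirroring an incomplete PACS transfer).
    """
    if seed is not None or mode is not None:
        profile = replace(
            profile,
            seed=profile.seed if seed is None else seed,
            mode=profile.mode if mode is None else mode,
        )
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    plans = plan_corpus(profile)
    entries = []
    for study in plans:
        study_dir = out / study.accession
        study_dir.mkdir(exist_ok=True)
        written = 0
        total = study.n_objects
        for series in study.series:
            for k in range(series.n_instances):
                written += 1
                if study.faulted and written == total:
                    continue  # withhold the last object by instance order
                ds = _instance_dataset(study, series, k)
                ds.save_as(study_dir / f"{ds.SOPInstanceUID}.dcm", enforce_file_format=True)
        entries.append((study.accession, total))
    return TransferManifest(tuple(entries))


def _uhe2022_shares() -> dict:
    return dict(
        modality_shares={
            "CT": 0.40,
            "MR": 0.33,
            "DX": 0.12,
            "XA": 0.08,
            "SR": 0.05,
            "PR": 0.02,
        },
        body_region_shares={
            "HEAD": 0.19,
            "CHEST": 0.14,
            "BRAIN": 0.09,
            "HEART": 0.08,
            "KNEE": 0.05,
            "HAND": 0.03,
            "FOOT": 0.02,
            "ANKLE": 0.02,
            "SHOULDER": 0.03,
            "ABDOMEN": 0.03,
            MISSING: 0.32,
        },
        laterality_splits={
            "KNEE": (0.46, 0.29, 0.25, 0.0, 0.0),
            "HAND": (0.88, 0.03, 0.09, 0.0, 0.0),
            "FOOT": (0.78, 0.09, 0.13, 0.0, 0.0),
            "ANKLE": (0.70, 0.15, 0.15, 0.0, 0.0),
            "SHOULDER": (0.60, 0.20, 0.20, 0.0, 0.0),
        },
        missing_region_modalities=("SR", "PR", "XA"),
        objects_per_study=((80, 0.5), (150, 0.5)),
    )


_BUILTINS = {
    "uhe2022": lambda: CorpusProfile(
        name="uhe2022",
        n_studies=200,
        series_per_study=10,
        fault_fraction=0.0,
        **_uhe2022_shares(),
    ),
    "uhe2022-faults": lambda: CorpusProfile(
        name="uhe2022-faults",
        n_studies=100,
        series_per_study=1,
        fault_fraction=0.04,
        **_uhe2022_shares(),
    ),
}


def builtin_profile(name: str) -> CorpusProfile:
    """Return a named builtin corpus profile.

    ``uhe2022`` pins a 200-study / 2,000-series corpus whose realized header
    statistics reproduce a published university-hospital metadata-quality
    evaluation (modality mix, body-region distribution with 32% missing,
    per-region laterality splits, 115 objects per study on average).
    ``uhe2022-faults`` is the same recipe over 100 single-series studies
    with a 4% incomplete-transfer fault rate.
    """
    try:
        factory = _BUILTINS[name]
    except KeyError:
        raise KeyError(
            f"unknown builtin profile {name!r}; available: {sorted(_BUILTINS)}"
        ) from None
    return factory()
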