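# Methods

This note records the models, conventions and numerical choices behind
`imgstudy`, and what the synthetic corpora do and do not establish about
real archives.

## Pipeline model

The pipeline treats one DICOM *study* (keyed by accession number) as the
unit of transfer and processing, mirroring how studies leave a PACS one
accession at a time. Processing is strictly sequential by design: a
folder-based DICOM endpoint cannot signal "study completely received", so
completeness is decided by **object counting** against a transfer manifest
(accession → expected object count). A study is complete when the number of
parseable received objects equals the expected count; otherwise the
orchestrator waits until either a wall-clock timeout (`wait_timeout`,
default 5 s) or a quiescence interval with no new files (`quiescence`,
default 2 s) elapses, then records an `incomplete_transfer`. Both intervals
are configurable; the defaults suit file-system corpora that are already
fully written. In every terminal state the study's files are deleted before
the next study begins — this prevents instances of different studies from
mixing and keeps storage bounded.

An optional SOP-class whitelist models endpoints that cannot accept certain
object types: non-whitelisted objects are rejected on arrival and never
count as received, so their absence surfaces as a count shortfall — the
characteristic failure mode of such endpoints. Rejected objects are tallied
separately (`excluded`) for diagnosis.

## FHIR representation

Each study becomes one FHIR R4 **ImagingStudy** (status `available`) with:

- two identifiers — the study UID as `urn:dicom:uid` / `urn:oid:<uid>`, and
  the accession number typed `ACSN`;
- a logical subject reference carrying the patient ID as an identifier;
- `started` composed from StudyDate + StudyTime in local time with no zone
  designator (the zone is unknown at the archive level);
- the distinct series modality codes (DICOM modality code system);
- per-series components with UID, number, modality, description, instance
  count, SNOMED `bodySite` and `laterality` codings, and per-instance UID,
  SOP class (`urn:ietf:rfc:3986` system, `urn:oid:<uid>` code) and number.

Two string extensions on each series carry the *raw* `BodyPartExamined` and
laterality values. This is deliberate: completeness statistics are defined
on raw header values (pre-mapping), and without the raw value a
present-but-unmappable region would be indistinguishable from an absent one
after conversion. Counts are validated structurally
(`validate_resource`): series/instance count fields must equal the actual
list lengths, modality lists must be duplicate-free and match the series,
instance UIDs must be unique. Builder output always validates; the
validator exists to catch hand-built or corrupted resources.

Bundles are FHIR `transaction` bundles with a single entry whose request is
a conditional `PUT` on the study-UID identifier, so repeated submission is
idempotent on a server. Serialization is deterministic (compact JSON, fixed
key order), which makes byte-level regression comparisons meaningful.

## Terminology

- **Body part → SNOMED-CT.** The bundled table is a curated ~50-row subset
  of the DICOM standard's BodyPartExamined ↔ SNOMED correspondence,
  covering all values the generator emits plus common clinical values; full
  coverage of the >300 standard regions is deliberately deferred, and sites
  can supply their own CSV (`raw,snomed_code,display,editions`). Each row
  carries an edition-range label (`-2022d`, `2023a-`, empty = all) so one
  asset serves multiple DICOM edition labels; lookups against an edition
  outside a row's range record an *unmapped-value event* while still
  counting the value as present.
- **Laterality.** `L`/`R`/`B` map to the SNOMED qualifier concepts 7771000 /
  24028007 / 51440002 used by the FHIR R4 ImagingStudy laterality binding.
  `U` (unpaired) has no concept in that binding: it is treated as a *valid*
  value for completion rates but yields no coding and counts as neither L
  nor R in the paired-region table.
- **Modality classes.** Non-acquisition modalities default to
  {SR, PR, KO, SEG, DOC, AU}; the set is configurable since institutional
  conventions differ. Unknown modality codes are classed as acquisition
  (with a warning) so that completeness denominators err on the
  conservative side.

## Pseudonymization

Derived UIDs are `2.25.` + the decimal rendering of the low 128 bits of
SHA-256(salt ‖ uid) — the standard UUID-derived UID namespace, ≤ 44
characters. The construction is deterministic per salt, so referential
integrity (the same series UID appearing in many instances) is preserved
corpus-wide without any lookup state. Patient IDs and accession numbers use
a persisted allocation-counter map (`PSN-000001`, `ACC-000001`) standing in
for an institutional trustee; the CSV map is the re-identification key and
must be protected accordingly. The salt is supplied via configuration or
environment and is never written to outputs, logs or the map.

Known privacy caveats, stated explicitly: study dates are retained
unshifted, and instance counts and series descriptions pass through
verbatim. The tool pseudonymizes identifiers; it is not a full
de-identification profile.

## Synthetic corpus generator

The generator emulates one year of imaging from two hospital departments at
a 1:100 scale chosen to keep a full round trip in the minutes range while
realizing every printed aggregate exactly. Profile `uhe2022`: 200 studies ×
10 series = 2,000 series; objects-per-study mixture of 100×80 + 100×150
(mean 115, total 23,000); modality shares CT 0.40, MR 0.33, DX 0.12,
XA 0.08, SR 0.05, PR 0.02 (93% acquisition); body-region shares HEAD 0.19,
CHEST 0.14, BRAIN 0.09, HEART 0.08, KNEE 0.05, HAND/SHOULDER/ABDOMEN 0.03,
FOOT/ANKLE 0.02, MISSING 0.32. All SR, PR and XA series carry no body
region (structured reports and presentation states have none; angiography
systems frequently write none), consuming 0.15 of the MISSING share; the
remaining 0.17 falls on ordinary acquisition series. Laterality splits
(missing, L, R) per paired region: KNEE .46/.29/.25, HAND .88/.03/.09,
FOOT .78/.09/.13, ANKLE .70/.15/.15, SHOULDER .60/.20/.20; all other
regions all-missing. `uhe2022-faults` reuses the shares over 100
single-series studies with `fault_fraction` 0.04.

Two arithmetic facts about this composition are worth recording. First, at
60 hand series no integer count rounds to the triple 88/3/9: the realized
counts 53/2/5 display as 88/3/8 (and 40 foot series give 78/10/13). The
missing-value columns — the quantities of interest — are exact. Second, a
24% missing-body-region rate *among acquisition series only* is not
simultaneously satisfiable with 32% overall missing, 93% acquisition share
and 7% fully-missing non-acquisition share (those three force
(32−7)/93 ≈ 26.9%); the profile realizes 27% for that secondary figure.

**Determinism.** In deterministic mode every categorical assignment uses
largest-remainder (Hamilton) apportionment — floor the quotas, give
leftover units to the largest fractional remainders, ties broken by
position — and categories are assigned to series in sorted study-major
index order. Realized counts therefore equal the shares exactly and two
runs are byte-identical. Stochastic mode samples every attribute from the
profile's distributions with a seeded NumPy generator (region sampling is
conditional on the modality-forced MISSING assignments); identical seeds
give byte-identical corpora. Fault injection withholds exactly the last
object (by instance number) of each faulted study while the manifest keeps
the full count; faulted studies are chosen at evenly spaced indices
(deterministic) or by seeded draw (stochastic).

Generated files are minimal valid Part-10: explicit VR little endian, the
hierarchy UIDs, modality-appropriate storage SOP class, patient/accession/
date/time identifiers, `BodyPartExamined` when present, `Laterality`
(0020,0060) for L/R and `ImageLaterality` (0020,0062) for B/U (the only tag
where those codes are legal), and a 2×2 dummy pixel payload for image
classes. One patient per study, derived from the study index.

**What passing tests do and do not show.** The synthetic corpus has clean,
consistent headers: no private tags, no character-set quirks, no
conflicting series-level attributes, no compressed transfer syntaxes, no
multi-frame objects, and missingness injected exactly at the configured
rates rather than correlated with device or protocol. Pipeline correctness
on it demonstrates that grouping, mapping, conversion, pseudonymization,
denominators and rounding are right — not that real-archive parsing edge
cases are all handled, nor anything about real transfer throughput.

## Analysis conventions

The unit of analysis is the DICOM **series** for every percentage; studies
enter only the two per-study means. "Present laterality" means the raw
value is one of L/R/B/U; "present body region" means any non-empty raw
value (mappability does not matter). Region distributions are keyed by raw
uppercased strings, with MISSING as an explicit bucket, and use all series
as denominator. Percentages are computed on exact integer counts and
rounded **half-up** to integers for display (banker's rounding would
misprint e.g. 94.5% as 94%); exact fractions are retained in the report
object and in the CSV export, and acquisition/non-acquisition displays are
reconciled to sum to 100. Analysis of a pseudonymized corpus equals
analysis of the same corpus un-pseudonymized, since pseudonymization
touches only identifiers.

## Numerical and degenerate-input choices

- Apportionment ties break by category insertion order (stable, documented).
- `pct_round_half_up` uses pure integer arithmetic
  (`(200n + d) // 2d`), avoiding float-representation surprises at exact
  .5 boundaries.
- Empty-after-trim header values normalize to absent; body part and
  laterality are uppercased before any counting or mapping.
- Duplicate SOPInstanceUIDs within a series are dropped with a warning;
  conflicting series-level attributes keep the first instance's values with
  a warning.
- Empty studies, empty manifests and empty bundle streams are rejected with
  explicit errors rather than producing degenerate statistics.

## Limitations

- The bundled terminology table is a subset; unmapped regions are recorded
  but not coded. Mapping via Anatomic Region Sequence is out of scope.
- The pipeline is sequential by design; no parallel processing.
- DICOM network services, message brokers and FHIR-server upload are out of
  scope — the inbox folder, CSV manifest and NDJSON sink are their
  file-based equivalents.
- Pseudonymized output retains dates and other quasi-identifiers (above).
- Throughput figures logged by the orchestrator describe this host only and
  are never part of any reported statistic.
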