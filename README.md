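# imgstudy

A toolkit for turning hospital DICOM metadata into pseudonymized HL7 FHIR R4
**ImagingStudy** resources and for profiling the quality of that metadata.

Routine radiology archives (PACS) hold enormous volumes of imaging studies
whose header metadata — modality, examined body region, laterality, series
and instance structure — could drive research feasibility queries and cohort
selection, if it were available in an interoperable, de-identified form.
`imgstudy` implements the complete desk-scale pipeline for that task:

1. **Header extraction** from DICOM Part-10 files without decoding pixel data
   (`imgstudy.dicom_io`), regrouped into the study → series → instance
   hierarchy.
2. **Terminology mapping** (`imgstudy.terminology`): raw `BodyPartExamined`
   (0018,0015) values to SNOMED-CT body structures via a versioned mapping
   table (DICOM editions revise the value set — e.g. `LEG` was valid up to
   edition 2022d, later replaced by `LOWERLEG`); laterality codes L/R/B to
   the SNOMED qualifier concepts of the FHIR R4 laterality binding; and
   modality codes into *acquisition* vs *non-acquisition* classes.
3. **FHIR conversion** (`imgstudy.fhir_model`): one ImagingStudy resource per
   study, wrapped in a transaction bundle with a conditional update keyed on
   the study-UID identifier, serialized deterministically to JSON/NDJSON.
4. **Pseudonymization** (`imgstudy.pseudonymize`): study/series/instance UIDs
   are replaced by `2.25.<decimal of low 128 bits of SHA-256(salt ‖ uid)>`;
   patient IDs and accession numbers go through a persisted trustee-style
   original→pseudonym map (`PSN-…` / `ACC-…`).
5. **Orchestration** (`imgstudy.orchestrator`): strictly sequential per-study
   processing of an inbox against a transfer manifest — count received
   objects, convert and emit only when the expected count is met, delete the
   study's files before the next study starts, and report the transfer
   **completion rate**.
6. **Metadata-quality analysis** (`imgstudy.analysis`): series-level
   completion rates for modality, body region and laterality, series
   distributions by modality and region (with a MISSING bucket), per-study
   means, and the laterality distribution within paired body regions
   (knees, hands, feet, ankles, shoulders). Percentages are computed on
   exact counts and rounded half-up for display; CSV export included.

Because real accession-level hospital data cannot be shipped, the package
includes a first-class **synthetic corpus generator** (`imgstudy.synthgen`)
that materializes valid DICOM files with a pinned statistical profile —
modality mix, body-region distribution including missing values, per-region
laterality splits, objects-per-study mixture, and injectable
incomplete-transfer faults — in exact (largest-remainder) deterministic mode
or seeded stochastic mode.

## Worked example

The builtin profile `uhe2022` pins a 200-study / 2,000-series corpus whose
realized statistics match a published university-hospital metadata
evaluation. Running it through the full pipeline
(`examples/analyze_corpus.py`):

```text
200 studies / 2000 series / 23000 instances
mean 10.0 series and 115.0 objects per study
acquisition modalities: 93% of series (non-acquisition 7%)
body region missing: 32% of all series
laterality missing: 95% of all series

top body regions (% of all series):
  HEAD     19%
  CHEST    14%
  BRAIN    9%
  HEART    8%

laterality in paired regions (% missing / L / R; B and U suppressed):
  KNEE       46 / 29 / 25   (n=100)
  HAND       88 /  3 /  8   (n=60)
  FOOT       78 / 10 / 13   (n=40)
  ANKLE      70 / 15 / 15   (n=40)
  SHOULDER   60 / 20 / 20   (n=60)
```

Reading: only 5% of series carry a valid laterality value overall; even in
body regions where laterality should always be present, 46–88% of series
lack it. A third of series have no `BodyPartExamined` entry — partly
expected (structured reports, presentation states and angiography series
carry none), but a large share of ordinary acquisition series is also blank.

`examples/run_pipeline.py` exercises the orchestrator on the fault-injected
variant (`uhe2022-faults`, 100 single-series studies, 4% of transfers one
object short of the manifest):

```text
processed 100 studies: 96 converted, 4 failed
completion rate: 96%
inbox empty after run: True
bundles emitted: 96
```

The other scripts in `examples/` cover corpus generation, header parsing +
FHIR conversion, and pseudonymization individually.

## Command line

```bash
imgstudy generate --profile uhe2022 --out DIR [--seed N --mode stochastic]
imgstudy convert  --in DIR --ndjson OUT [--body-part-table CSV --edition 2024a]
imgstudy pseudonymize --in IN.ndjson --out OUT.ndjson --map MAP.csv --salt-env IMGSTUDY_SALT
imgstudy run     --inbox DIR --manifest CSV --sink OUT.ndjson --map MAP.csv --salt-env IMGSTUDY_SALT
imgstudy analyze --in IN.ndjson --out DIR [--regions KNEE,HAND,FOOT,ANKLE,SHOULDER]
```

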