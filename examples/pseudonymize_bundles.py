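"""Pseudonymize ImagingStudy bundles with salted UID hashing and a trustee map.

Hierarchy UIDs are replaced by salted-digest UIDs in the 2.25 namespace;
patient IDs and accession numbers go through a persisted original→pseudonym
map so the same patient keeps the same pseudonym across studies.
"""

from pathlib import Path
import tempfile

from imgstudy import (
    CorpusProfile, HashingPolicy, PseudonymMap, generate_corpus,
    group_instances, read_instance, load_body_part_table,
    build_imaging_study, wrap_bundle, pseudonymize_bundle, hash_uid,
)
from imgstudy.fhir_model import dumps_bundle

policy = HashingPolicy(salt="demo-secret")  # keep the salt out of outputs/logs
print("hash of 1.2.3:", hash_uid("1.2.3", policy))

profile = CorpusProfile(
    name="demo", n_studies=2, series_per_study=1, objects_per_study=((2, 1.0),),
    modality_shares={"CT": 1.0}, body_region_shares={"HAND": 1.0},
    laterality_splits={"HAND": (0.0, 0.0, 1.0, 0.0, 0.0)},
)
tmp = Path(tempfile.mkdtemp())
generate_corpus(profile, tmp / "corpus")
metas = [read_instance(p) for p in sorted((tmp / "corpus").rglob("*.dcm"))]
table = load_body_part_table()
pmap = PseudonymMap(tmp / "pseudonyms.csv")

for study in group_instances(metas):
    bundle = wrap_bundle(build_imaging_study(study, table))
    out = pseudonymize_bundle(bundle, pmap, policy)
    print(f"{study.patient_id} / {study.accession_number}  ->  "
          f"{out.resource.patient_id} / {out.resource.accession_number}")
    assert study.study_instance_uid not in dumps_bundle(out)  # leak check

print(f"trustee map persisted at {pmap.path}:")
print(pmap.path.read_text())
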