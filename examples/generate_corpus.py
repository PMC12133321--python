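"""Generate a synthetic DICOM corpus with a pinned statistical profile.

Builds the builtin 200-study / 2,000-series corpus in deterministic mode and
prints what landed on disk.  Each study is a folder of Part-10 files with
tiny dummy pixels; the transfer manifest records how many objects the
downstream pipeline should expect per accession.
"""

from pathlib import Path
import tempfile

from imgstudy import builtin_profile, generate_corpus, plan_corpus

profile = builtin_profile("uhe2022")
print(f"profile {profile.name}: {profile.n_studies} studies x {profile.series_per_study} series")

# inspect the layout before writing anything: the plan is the ground truth
plans = plan_corpus(profile)
knees = [s for p in plans for s in p.series if s.body_part == "KNEE"]
print(f"planned knee series: {len(knees)}, of which "
      f"{sum(1 for s in knees if s.laterality is None)} lack laterality")

out = Path(tempfile.mkdtemp()) / "corpus"
manifest = generate_corpus(profile, out)
n_files = sum(1 for _ in out.rglob("*.dcm"))
total_expected = sum(c for _, c in manifest.entries)
print(f"wrote {n_files} DICOM files into {len(manifest.entries)} study folders under {out}")
print(f"manifest expects {total_expected} objects "
      f"({total_expected / len(manifest.entries):.0f} per study on average)")
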