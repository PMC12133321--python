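"""Run the sequential study-processing cycle against a transfer manifest.

Generates a fault-injected corpus (some studies arrive one object short of
what the manifest expects), then processes the inbox: count received
objects, convert + pseudonymize complete studies into an NDJSON sink, and
delete each study's files before the next study starts.
"""

from pathlib import Path
import tempfile

from imgstudy import (
    HashingPolicy, PseudonymMap, builtin_profile, generate_corpus,
    process_inbox, completion_rate,
)

tmp = Path(tempfile.mkdtemp())
profile = builtin_profile("uhe2022-faults")  # 100 studies, 4% faulted
inbox = tmp / "inbox"
manifest = generate_corpus(profile, inbox)

report = process_inbox(
    inbox, manifest, tmp / "bundles.ndjson",
    PseudonymMap(tmp / "pseudonyms.csv"), HashingPolicy(salt="demo-secret"),
    wait_timeout=0.2, quiescence=0.1,
)

ok = sum(1 for r in report.results if r.status == "success")
bad = [r for r in report.results if r.status != "success"]
print(f"processed {report.processed_count} studies: {ok} converted, {len(bad)} failed")
for r in bad:
    print(f"  {r.accession}: {r.status} (expected {r.expected}, received {r.received})")
print(f"completion rate: {completion_rate(report)}%")
print(f"inbox empty after run: {not any(inbox.rglob('*'))}")
# Every success appended exactly one pseudonymized bundle to the sink.
print(f"bundles emitted: {sum(1 for _ in open(tmp / 'bundles.ndjson'))}")
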