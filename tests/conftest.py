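from types import SimpleNamespace

import pytest
from hypothesis import settings

from imgstudy import (
    HashingPolicy,
    PseudonymMap,
    builtin_profile,
    generate_corpus,
    process_inbox,
)
from imgstudy.synthgen import MISSING, CorpusProfile

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


def make_tiny_profile(**overrides) -> CorpusProfile:
    """2 studies x 2 series x 2 objects, CT only, half KNEE-left half HEAD."""
    kwargs = dict(
        name="tiny",
        n_studies=2,
        series_per_study=2,
        objects_per_study=((4, 1.0),),
        modality_shares={"CT": 1.0},
        body_region_shares={"KNEE": 0.5, "HEAD": 0.5},
        laterality_splits={"KNEE": (0.0, 1.0, 0.0, 0.0, 0.0)},
        fault_fraction=0.0,
    )
    kwargs.update(overrides)
    return CorpusProfile(**kwargs)


def make_mixed_profile(**overrides) -> CorpusProfile:
    """A 40-series corpus exercising every attribute pathway: forced-missing
    modalities, a MISSING region budget and non-trivial laterality splits."""
    kwargs = dict(
        name="mixed",
        n_studies=10,
        series_per_study=4,
        objects_per_study=((6, 0.5), (10, 0.5)),
        modality_shares={"CT": 0.4, "MR": 0.3, "SR": 0.2, "XA": 0.1},
        body_region_shares={"KNEE": 0.25, "HAND": 0.20, "CHEST": 0.15, MISSING: 0.40},
        laterality_splits={
            "KNEE": (0.5, 0.25, 0.25, 0.0, 0.0),
            "HAND": (0.25, 0.25, 0.25, 0.125, 0.125),
        },
        missing_region_modalities=("SR", "XA"),
        fault_fraction=0.0,
    )
    kwargs.update(overrides)
    return CorpusProfile(**kwargs)


def run_pipeline(corpus_dir, manifest, workdir, salt="test-salt"):
    """Convert + pseudonymize a generated corpus through the orchestrator."""
    workdir.mkdir(parents=True, exist_ok=True)
    sink = workdir / "bundles.ndjson"
    report = process_inbox(
        corpus_dir,
        manifest,
        sink,
        PseudonymMap(workdir / "pseudonyms.csv"),
        HashingPolicy(salt=salt),
        wait_timeout=0.2,
        quiescence=0.1,
    )
    return SimpleNamespace(sink=sink, report=report)


@pytest.fixture()
def tiny_profile():
    return make_tiny_profile()


@pytest.fixture()
def tiny_corpus(tmp_path, tiny_profile):
    corpus = tmp_path / "corpus"
    manifest = generate_corpus(tiny_profile, corpus)
    return SimpleNamespace(dir=corpus, manifest=manifest, profile=tiny_profile)


@pytest.fixture(scope="session")
def uhe_roundtrip(tmp_path_factory):
    """Full generate -> parse -> convert -> pseudonymize round trip of the
    pinned 200-study corpus; shared across the session because it builds
    23,000 files."""
    workdir = tmp_path_factory.mktemp("uhe2022")
    profile = builtin_profile("uhe2022")
    corpus = workdir / "corpus"
    manifest = generate_corpus(profile, corpus)
    result = run_pipeline(corpus, manifest, workdir)
    return SimpleNamespace(sink=result.sink, report=result.report, manifest=manifest)


@pytest.fixture(scope="session")
def faults_roundtrip(tmp_path_factory):
    """Round trip of the fault-injected 100-study single-series corpus."""
    workdir = tmp_path_factory.mktemp("uhe2022_faults")
    profile = builtin_profile("uhe2022-faults")
    corpus = workdir / "corpus"
    manifest = generate_corpus(profile, corpus)
    result = run_pipeline(corpus, manifest, workdir)
    return SimpleNamespace(sink=result.sink, report=result.report, manifest=manifest)
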