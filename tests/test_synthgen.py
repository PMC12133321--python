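"""Corpus generator: apportionment exactness, manifests, faults, determinism."""

import filecmp

import pytest
from hypothesis import given
from hypothesis import strategies as st

from imgstudy import builtin_profile, generate_corpus, plan_corpus
from imgstudy._util import apportion
from imgstudy.synthgen import MISSING, CorpusProfile, ProfileError, TransferManifest

from conftest import make_mixed_profile, make_tiny_profile


class TestApportionment:
    @given(
        total=st.integers(0, 500),
        weights=st.lists(st.floats(0.01, 10.0), min_size=1, max_size=8),
    )
    def test_conserves_total_and_stays_within_one_of_quota(self, total, weights):
        counts = apportion(total, weights)
        assert sum(counts) == total
        wsum = sum(weights)
        for c, w in zip(counts, weights):
            assert abs(c - total * w / wsum) < 1.0

    def test_exact_shares_realize_exactly(self):
        assert apportion(2000, [0.40, 0.33, 0.12, 0.08, 0.05, 0.02]) == [
            800, 660, 240, 160, 100, 40,
        ]


class TestProfileValidation:
    def test_shares_must_sum_to_one(self):
        with pytest.raises(ProfileError, match="sum"):
            make_tiny_profile(modality_shares={"CT": 0.5, "MR": 0.4})

    def test_fault_fraction_bounds(self):
        with pytest.raises(ProfileError):
            make_tiny_profile(fault_fraction=1.5)

    def test_forced_missing_must_fit_in_missing_share(self):
        with pytest.raises(ProfileError, match="MISSING"):
            make_tiny_profile(
                modality_shares={"SR": 0.8, "CT": 0.2},
                body_region_shares={"KNEE": 0.5, MISSING: 0.5},
                missing_region_modalities=("SR",),
            )

    def test_unknown_builtin_rejected(self):
        with pytest.raises(KeyError):
            builtin_profile("nope")


class TestDeterministicPlan:
    def test_tiny_corpus_counts_and_manifest(self, tmp_path, tiny_profile):
        manifest = generate_corpus(tiny_profile, tmp_path / "c")
        files = list((tmp_path / "c").rglob("*.dcm"))
        assert len(files) == 8
        assert manifest.entries == (("A00001", 4), ("A00002", 4))

    def test_uhe2022_knee_block(self):
        plans = plan_corpus(builtin_profile("uhe2022"))
        series = [s for p in plans for s in p.series]
        assert len(series) == 2000
        knees = [s for s in series if s.body_part == "KNEE"]
        assert len(knees) == 100
        assert sum(1 for s in knees if s.laterality is None) == 46
        assert sum(1 for s in knees if s.laterality == "L") == 29
        assert sum(1 for s in knees if s.laterality == "R") == 25

    def test_uhe2022_acquisition_fraction_and_mean_objects(self):
        profile = builtin_profile("uhe2022")
        plans = plan_corpus(profile)
        series = [s for p in plans for s in p.series]
        non_acq = sum(1 for s in series if s.modality in ("SR", "PR"))
        assert (len(series) - non_acq) / len(series) == pytest.approx(0.93)
        assert sum(p.n_objects for p in plans) / len(plans) == pytest.approx(115.0)

    def test_forced_modalities_never_carry_body_region(self):
        plans = plan_corpus(make_mixed_profile())
        for p in plans:
            for s in p.series:
                if s.modality in ("SR", "XA"):
                    assert s.body_part is None

    def test_category_counts_conserved(self):
        profile = make_mixed_profile()
        series = [s for p in plan_corpus(profile) for s in p.series]
        n = profile.n_studies * profile.series_per_study
        assert len(series) == n
        by_mod = {m: sum(1 for s in series if s.modality == m) for m in profile.modality_shares}
        assert by_mod == {"CT": 16, "MR": 12, "SR": 8, "XA": 4}
        missing = sum(1 for s in series if s.body_part is None)
        assert missing == round(0.40 * n)


class TestFaults:
    def test_faulted_studies_withhold_exactly_one_object(self, tmp_path):
        profile = builtin_profile("uhe2022-faults")
        manifest = generate_corpus(profile, tmp_path / "c")
        plans = plan_corpus(profile)
        faulted = [p for p in plans if p.faulted]
        assert len(faulted) == 4
        for p in plans:
            on_disk = len(list((tmp_path / "c" / p.accession).glob("*.dcm")))
            assert manifest.expected(p.accession) == p.n_objects
            assert on_disk == p.n_objects - (1 if p.faulted else 0)


class TestDeterminism:
    def test_repeated_deterministic_runs_are_byte_identical(self, tmp_path, tiny_profile):
        generate_corpus(tiny_profile, tmp_path / "a")
        generate_corpus(tiny_profile, tmp_path / "b")
        rel = sorted(p.relative_to(tmp_path / "a") for p in (tmp_path / "a").rglob("*.dcm"))
        assert rel
        match, mismatch, errors = filecmp.cmpfiles(
            tmp_path / "a", tmp_path / "b", [str(p) for p in rel], shallow=False
        )
        assert not mismatch and not errors

    def test_same_seed_stochastic_runs_are_byte_identical(self, tmp_path):
        profile = make_mixed_profile(mode="stochastic", seed=7)
        generate_corpus(profile, tmp_path / "a")
        generate_corpus(profile, tmp_path / "b")
        rel = sorted(p.relative_to(tmp_path / "a") for p in (tmp_path / "a").rglob("*.dcm"))
        match, mismatch, errors = filecmp.cmpfiles(
            tmp_path / "a", tmp_path / "b", [str(p) for p in rel], shallow=False
        )
        assert not mismatch and not errors

    def test_different_seeds_differ(self):
        a = plan_corpus(make_mixed_profile(mode="stochastic", seed=1))
        b = plan_corpus(make_mixed_profile(mode="stochastic", seed=2))
        assert a != b


class TestManifest:
    def test_duplicate_accessions_rejected(self):
        with pytest.raises(ValueError):
            TransferManifest((("A1", 2), ("A1", 3)))

    def test_csv_round_trip(self, tmp_path, tiny_corpus):
        path = tmp_path / "manifest.csv"
        tiny_corpus.manifest.to_csv(path)
        assert TransferManifest.from_csv(path) == tiny_corpus.manifest
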