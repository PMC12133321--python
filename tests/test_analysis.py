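"""Metadata-quality report: denominators, rounding, oracle equivalence, export."""

import logging

import pytest

from imgstudy import (
    analyze,
    export_report,
    generate_corpus,
    laterality_by_region,
    plan_corpus,
)
from imgstudy._util import pct_round_half_up, round_half_up
from imgstudy.analysis import MISSING
from imgstudy.fhir_model import read_ndjson
from imgstudy.terminology import DEFAULT_NON_ACQUISITION

from conftest import make_mixed_profile, make_tiny_profile, run_pipeline


@pytest.fixture(scope="module")
def mixed(tmp_path_factory):
    """A 40-series corpus run through the full pipeline, plus its plan."""
    tmp = tmp_path_factory.mktemp("mixed")
    profile = make_mixed_profile()
    corpus = tmp / "corpus"
    manifest = generate_corpus(profile, corpus)
    result = run_pipeline(corpus, manifest, tmp)
    return result.sink, plan_corpus(profile)


class TestRounding:
    def test_half_up_on_exact_integer_counts(self):
        assert pct_round_half_up(1, 2) == 50
        assert pct_round_half_up(1, 200) == 1  # 0.5% rounds up
        assert pct_round_half_up(189, 200) == 95  # 94.5 rounds up, not to even
        assert pct_round_half_up(0, 7) == 0

    def test_float_half_up(self):
        assert round_half_up(2.5) == 3.0
        assert round_half_up(114.95, 1) == 115.0


class TestAnalyze:
    def test_single_study_body_region_completion_50pct(self, tmp_path):
        profile = make_tiny_profile(
            n_studies=1,
            body_region_shares={"HEAD": 0.5, MISSING: 0.5},
            laterality_splits={},
        )
        corpus = tmp_path / "c"
        manifest = generate_corpus(profile, corpus)
        result = run_pipeline(corpus, manifest, tmp_path)
        report = analyze(result.sink)
        assert report.n_series == 2
        assert report.completion_rate_body_region == pytest.approx(50.0)
        assert report.display()["body_region_missing_pct"] == 50

    def test_oracle_equivalence_on_small_corpus(self, mixed):
        """Every report value equals a brute-force tally of the generator's
        own assignment plan, bypassing the DICOM and FHIR layers."""
        sink, plans = mixed
        report = analyze(sink)
        series = [s for p in plans for s in p.series]

        assert report.n_studies == len(plans)
        assert report.n_series == len(series)
        assert report.n_instances == sum(p.n_objects for p in plans)

        by_mod = {}
        for s in series:
            by_mod[s.modality] = by_mod.get(s.modality, 0) + 1
        assert report.series_by_modality == by_mod

        by_region = {}
        for s in series:
            key = s.body_part or MISSING
            by_region[key] = by_region.get(key, 0) + 1
        assert report.series_by_body_region == by_region

        acq = sum(1 for s in series if s.modality not in DEFAULT_NON_ACQUISITION)
        assert report.acquisition_count == acq
        assert report.non_acquisition_count == len(series) - acq

        lat_valid = sum(1 for s in series if s.laterality in ("L", "R", "B", "U"))
        assert report.laterality_valid_count == lat_valid
        assert report.body_region_present_count == sum(1 for s in series if s.body_part)
        assert report.modality_present_count == len(series)
        assert report.body_region_missing_acquisition_count == sum(
            1
            for s in series
            if s.body_part is None and s.modality not in DEFAULT_NON_ACQUISITION
        )
        assert report.mean_series_per_study == pytest.approx(len(series) / len(plans))

    def test_pseudonymization_never_changes_statistics(self, tmp_path):
        """The report over pseudonymized bundles equals the report computed
        from the same corpus converted without pseudonymization."""
        from imgstudy import (
            build_imaging_study,
            group_instances,
            load_body_part_table,
            read_instance,
            wrap_bundle,
        )

        profile = make_mixed_profile(n_studies=5)
        corpus = tmp_path / "c"
        manifest = generate_corpus(profile, corpus)

        table = load_body_part_table()
        metas = [read_instance(p) for p in sorted(corpus.rglob("*.dcm"))]
        plain = [wrap_bundle(build_imaging_study(s, table)) for s in group_instances(metas)]
        plain_report = analyze(plain)
        plain_table = laterality_by_region(plain)

        result = run_pipeline(corpus, manifest, tmp_path)
        pseudo_report = analyze(result.sink)
        pseudo_table = laterality_by_region(result.sink)

        assert pseudo_report.display() == plain_report.display()
        assert pseudo_report.series_by_body_region == plain_report.series_by_body_region
        assert {r: row.display() for r, row in pseudo_table.rows.items()} == {
            r: row.display() for r, row in plain_table.rows.items()
        }

    def test_malformed_bundle_skipped_and_counted(self, tmp_path, tiny_profile):
        corpus = tmp_path / "c"
        manifest = generate_corpus(tiny_profile, corpus)
        result = run_pipeline(corpus, manifest, tmp_path)
        with open(result.sink, "a") as fh:
            fh.write('{"resourceType":"Bundle"}\n')  # entry-less bundle
            fh.write("not json at all\n")
        report = analyze(result.sink)
        assert report.n_studies == 2
        assert report.rejects == 2

    def test_empty_stream_rejected(self, tmp_path):
        empty = tmp_path / "empty.ndjson"
        empty.write_text("")
        with pytest.raises(ValueError):
            analyze(empty)


class TestLateralityTable:
    def test_single_left_series_region(self, tmp_path):
        profile = make_tiny_profile(
            n_studies=1,
            series_per_study=1,
            objects_per_study=((2, 1.0),),
            body_region_shares={"KNEE": 1.0},
        )
        corpus = tmp_path / "c"
        manifest = generate_corpus(profile, corpus)
        result = run_pipeline(corpus, manifest, tmp_path)
        table = laterality_by_region(result.sink, ["KNEE"])
        assert table.rows["KNEE"].display() == (0, 100, 0)

    def test_unpaired_counts_neither_left_nor_right(self, tmp_path):
        profile = make_tiny_profile(
            n_studies=2,
            series_per_study=1,
            objects_per_study=((2, 1.0),),
            body_region_shares={"HAND": 1.0},
            laterality_splits={"HAND": (0.0, 0.5, 0.0, 0.0, 0.5)},
        )
        corpus = tmp_path / "c"
        manifest = generate_corpus(profile, corpus)
        result = run_pipeline(corpus, manifest, tmp_path)
        report = analyze(result.sink)
        assert report.completion_rate_laterality == pytest.approx(100.0)
        row = laterality_by_region(result.sink, ["HAND"]).rows["HAND"]
        assert (row.n_left, row.n_right, row.n_unpaired) == (1, 0, 1)
        assert row.display() == (0, 50, 0)

    def test_absent_region_row_omitted_with_warning(self, mixed, caplog):
        sink, _ = mixed
        with caplog.at_level(logging.WARNING):
            table = laterality_by_region(sink, ["KNEE", "SPLEEN"])
        assert "KNEE" in table.rows
        assert "SPLEEN" not in table.rows
        assert any("SPLEEN" in r.message for r in caplog.records)

    def test_row_counts_sum_to_region_series(self, mixed):
        sink, plans = mixed
        table = laterality_by_region(sink, ["KNEE", "HAND"])
        for region, row in table.rows.items():
            expected = sum(1 for p in plans for s in p.series if s.body_part == region)
            assert row.n_series == expected
            assert (
                row.n_missing + row.n_left + row.n_right + row.n_bilateral + row.n_unpaired
                == row.n_series
            )


class TestExport:
    def test_csv_round_trip_and_determinism(self, mixed, tmp_path):
        import pandas as pd

        sink, _ = mixed
        report = analyze(sink)
        table = laterality_by_region(sink)
        paths = export_report(report, table, tmp_path / "out1")
        again = export_report(report, table, tmp_path / "out2")
        for name in paths:
            assert paths[name].read_bytes() == again[name].read_bytes()

        summary = pd.read_csv(paths["summary"]).set_index("metric")
        assert summary.loc["n_series", "display"] == report.n_series
        assert summary.loc["laterality_missing_pct", "display"] == report.display()["laterality_missing_pct"]
        regions = pd.read_csv(paths["series_by_region"])
        assert dict(zip(regions.body_region, regions["count"])) == report.series_by_body_region
        assert regions["count"].sum() == report.n_series
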