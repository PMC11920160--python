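"""Parsing, deduplication, delete filtering and report normalization."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from ncdia import (apply_deletes, build_case_reports, deduplicate,
                   ingest_bundle, parse_bundle)
from ncdia.ingest import (BundleInputError, BundleSchemaError, RawRecordSet,
                          parse_faers_date)


def _raw(demo_rows, drug_rows=None, reac_rows=None, outc_rows=None,
         ther_rows=None, delete_ids=()):
    def f(rows, cols):
        return pd.DataFrame(rows, columns=cols).astype(str) if rows else \
            pd.DataFrame(columns=cols)

    return RawRecordSet(
        demo=f(demo_rows, ["primaryid", "caseid", "fda_dt", "event_dt",
                           "age", "age_cod", "sex"]),
        drug=f(drug_rows, ["primaryid", "caseid", "drug_seq", "role_cod",
                           "drugname"]),
        reac=f(reac_rows, ["primaryid", "caseid", "pt"]),
        outc=f(outc_rows, ["primaryid", "caseid", "outc_cod"]),
        ther=f(ther_rows, ["primaryid", "caseid", "dsg_drug_seq", "start_dt"]),
        delete_ids=set(delete_ids))


class TestParsing:
    def test_parses_dollar_delimited_bundle(self, tiny_bundle_dir):
        raw = parse_bundle(tiny_bundle_dir)
        assert len(raw.demo) == 3
        assert len(raw.drug) == 4

    def test_trailing_delimiter_yields_missing_final_field(self, tiny_bundle_dir):
        raw = parse_bundle(tiny_bundle_dir)
        row = raw.demo[raw.demo["primaryid"] == "10031"].iloc[0]
        assert row["occp_cod"] == "" and row["sex"] == ""

    def test_missing_mandatory_file_is_named(self, tiny_bundle_dir):
        (tiny_bundle_dir / "2023q1" / "OUTC23Q1.txt").unlink()
        with pytest.raises(BundleInputError, match="OUTC"):
            parse_bundle(tiny_bundle_dir)

    def test_missing_mandatory_column_is_schema_error(self, tiny_bundle_dir):
        p = tiny_bundle_dir / "2023q1" / "REAC23Q1.txt"
        p.write_text("primaryid$caseid\n10011$1001\n")
        with pytest.raises(BundleSchemaError, match="pt"):
            parse_bundle(tiny_bundle_dir)

    def test_roundtrip_counts_match_generator_bookkeeping(
            self, small_bundle, tmp_path):
        root = small_bundle.write(tmp_path / "b")
        raw = parse_bundle(root)
        assert len(raw.demo) == len(small_bundle.demo)
        assert raw.delete_ids == small_bundle.delete_ids
        reports, log = ingest_bundle(root)
        assert len(reports) == small_bundle.truth.n_final_cases

    @pytest.mark.parametrize("value, expected", [
        ("20230110", dt.date(2023, 1, 10)),
        ("202301", dt.date(2023, 1, 15)),
        ("2023", dt.date(2023, 7, 1)),
        ("", None), ("N/A", None), ("20231345", None),
    ])
    def test_partial_date_completion(self, value, expected):
        assert parse_faers_date(value) == expected


class TestDeduplication:
    def test_latest_fda_date_wins(self):
        raw = _raw([("7", "100", "20230101", "", "", "", ""),
                    ("5", "100", "20230301", "", "", "", "")])
        out = deduplicate(raw)
        assert list(out.demo["primaryid"]) == ["5"]

    def test_tie_broken_by_highest_numeric_primaryid(self):
        raw = _raw([("11", "200", "20230101", "", "", "", ""),
                    ("12", "200", "20230101", "", "", "", ""),
                    ("9", "200", "20230101", "", "", "", "")])
        out = deduplicate(raw)
        assert list(out.demo["primaryid"]) == ["12"]

    def test_matches_bruteforce_groupby_oracle(self):
        """1,000 randomly ordered versioned cases against an independent
        per-case max over (fda_dt, numeric primaryid)."""
        rng = np.random.default_rng(5)
        rows = []
        for case in range(1000):
            for version in range(rng.integers(1, 4)):
                pid = str(case * 100 + rng.integers(0, 90))
                fda = f"202{rng.integers(0, 4)}0{rng.integers(1, 10)}15"
                rows.append((pid, str(case), fda, "", "", "", ""))
        rng.shuffle(rows)
        # oracle: plain-python group-by maximum
        best: dict[str, tuple] = {}
        for pid, case, fda, *_ in rows:
            key = (int(fda), int(pid))
            if case not in best or key > best[case][0]:
                best[case] = (key, pid)
        expected = {pid for _, pid in best.values()}
        out = deduplicate(_raw(rows))
        assert set(out.demo["primaryid"]) == expected

    def test_dedup_and_deletes_are_idempotent(self):
        raw = _raw([("1", "1", "20230101", "", "", "", ""),
                    ("2", "1", "20230201", "", "", "", ""),
                    ("3", "2", "20230101", "", "", "", "")],
                   delete_ids={"3"})
        once = apply_deletes(deduplicate(raw))
        twice = apply_deletes(deduplicate(once))
        pd.testing.assert_frame_equal(once.demo, twice.demo)
        assert len(once.demo) == 1

    def test_child_rows_of_dropped_versions_removed(self):
        raw = _raw([("1", "1", "20230101", "", "", "", ""),
                    ("2", "1", "20230201", "", "", "", "")],
                   reac_rows=[("1", "1", "Nausea"), ("2", "1", "Rash")])
        out = deduplicate(raw)
        assert list(out.reac["primaryid"]) == ["2"]


class TestDeletes:
    def test_empty_delete_list_is_identity(self):
        raw = _raw([("1", "1", "20230101", "", "", "", "")])
        out = apply_deletes(raw)
        pd.testing.assert_frame_equal(out.demo, raw.demo)

    def test_deleting_sole_version_removes_case(self):
        raw = _raw([("1", "1", "20230101", "", "", "", "")], delete_ids={"1"})
        assert apply_deletes(raw).demo.empty

    def test_delete_applied_after_dedup_removes_whole_case(self):
        # delete list names the retained (latest) version only: the case
        # must vanish, not fall back to the older version
        raw = _raw([("1", "1", "20230101", "", "", "", ""),
                    ("2", "1", "20230201", "", "", "", "")],
                   delete_ids={"2"})
        assert apply_deletes(deduplicate(raw)).demo.empty
        # the documented order differs from delete-then-dedup:
        reversed_order = deduplicate(apply_deletes(raw))
        assert list(reversed_order.demo["primaryid"]) == ["1"]

    def test_monotone_case_counts_through_funnel(self, small_bundle):
        from ncdia.ingest import from_bundle
        raw = from_bundle(small_bundle)
        d = deduplicate(raw)
        f = apply_deletes(d)
        assert len(raw.demo) >= len(d.demo) >= len(f.demo)


class TestCaseReports:
    @pytest.mark.parametrize("age, unit, expected", [
        ("24", "MON", 2.0),
        ("5", "DEC", 50.0),
        ("365.25", "DY", 1.0),
        ("52.18", "WK", 1.0),
        ("8766", "HR", 1.0),
        ("30", "YR", 30.0),
    ])
    def test_age_unit_conversion(self, age, unit, expected):
        raw = _raw([("1", "1", "20230101", "", age, unit, "F")],
                   drug_rows=[("1", "1", "1", "PS", "Widgetol")])
        (report,) = build_case_reports(raw)
        assert report.age_years == pytest.approx(expected)

    @pytest.mark.parametrize("age, unit", [("700", "YR"), ("16", "DEC"),
                                           ("40", "QQ")])
    def test_implausible_or_unknown_unit_age_becomes_missing(self, age, unit):
        raw = _raw([("1", "1", "20230101", "", age, unit, "F")],
                   drug_rows=[("1", "1", "1", "PS", "Widgetol")])
        (report,) = build_case_reports(raw)
        assert report.age_years is None

    def test_only_primary_suspect_drug_carried(self):
        raw = _raw([("1", "1", "20230101", "", "", "", "")],
                   drug_rows=[("1", "1", "1", "PS", "Widgetol"),
                              ("1", "1", "2", "SS", "Gadgetin"),
                              ("1", "1", "3", "SS", "Sprocketol")])
        (report,) = build_case_reports(raw)
        assert report.drug_name == "Widgetol"

    def test_report_without_ps_drug_excluded_and_counted(self):
        raw = _raw([("1", "1", "20230101", "", "", "", ""),
                    ("2", "2", "20230101", "", "", "", "")],
                   drug_rows=[("1", "1", "1", "SS", "Widgetol"),
                              ("2", "2", "1", "PS", "Widgetol")])
        reports = build_case_reports(raw)
        assert [r.primary_id for r in reports] == ["2"]
        assert raw.log["n_no_ps_drug"] == 1

    def test_multiple_ps_drugs_keep_lowest_sequence(self):
        raw = _raw([("1", "1", "20230101", "", "", "", "")],
                   drug_rows=[("1", "1", "9", "PS", "Gadgetin"),
                              ("1", "1", "2", "PS", "Widgetol")])
        (report,) = build_case_reports(raw)
        assert report.drug_name == "Widgetol"
        assert raw.log["n_multiple_ps"] == 1

    def test_earliest_therapy_start_for_ps_drug(self):
        raw = _raw([("1", "1", "20230601", "20230501", "", "", "")],
                   drug_rows=[("1", "1", "1", "PS", "Widgetol")],
                   ther_rows=[("1", "1", "1", "20230301"),
                              ("1", "1", "1", "20230201"),
                              ("1", "1", "2", "20220101")])
        (report,) = build_case_reports(raw)
        # sequence-2 therapy row belongs to a different drug: ignored
        assert report.therapy_start == dt.date(2023, 2, 1)
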