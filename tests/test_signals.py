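"""Contingency tables, ROR estimation and the positive-signal rule."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ncdia import (ContingencyTable, build_cohort, class_signals, contingency,
                   detect_signals, ror_estimate, signal_from_table)
from ncdia.cohort import AtcMap
from tests.conftest import atc_map_from_bundle, make_report


def _hp_ror_ci(a, b, c, d, digits=50):
    """High-precision closed-form oracle via mpmath."""
    import mpmath
    with mpmath.workdps(digits):
        ror = mpmath.mpf(a) * d / (mpmath.mpf(b) * c)
        se = mpmath.sqrt(sum(mpmath.mpf(1) / x for x in (a, b, c, d)))
        z = mpmath.sqrt(2) * mpmath.erfinv(mpmath.mpf("0.95"))
        lo = mpmath.e ** (mpmath.log(ror) - z * se)
        hi = mpmath.e ** (mpmath.log(ror) + z * se)
        return float(ror), float(lo), float(hi)


class TestRorEstimate:
    def test_balanced_table_is_symmetric_about_one(self):
        est = ror_estimate(ContingencyTable(5, 5, 5, 5))
        assert est.ror == pytest.approx(1.0)
        assert est.ci_low * est.ci_high == pytest.approx(1.0)

    @pytest.mark.parametrize("cells", [(10, 90, 100, 9900), (3, 7, 50, 10000),
                                       (262, 1937, 188, 2395)])
    def test_matches_high_precision_oracle(self, cells):
        est = ror_estimate(ContingencyTable(*cells))
        ror, lo, hi = _hp_ror_ci(*cells)
        assert est.ror == pytest.approx(ror, rel=1e-12)
        assert est.ci_low == pytest.approx(lo, rel=1e-12)
        assert est.ci_high == pytest.approx(hi, rel=1e-12)

    def test_printed_precision_examples(self):
        est = ror_estimate(ContingencyTable(10, 90, 100, 9900))
        assert round(est.ror, 2) == 11.00
        assert (round(est.ci_low, 2), round(est.ci_high, 2)) == (5.56, 21.76)
        est = ror_estimate(ContingencyTable(3, 7, 50, 10000))
        assert round(est.ror, 2) == 85.71
        assert (round(est.ci_low, 2), round(est.ci_high, 2)) == (21.55, 340.96)

    @pytest.mark.parametrize("cells", [(0, 5, 5, 5), (5, 0, 5, 5),
                                       (5, 5, 0, 5), (5, 5, 5, 0)])
    def test_zero_cell_leaves_estimate_undefined(self, cells):
        est = ror_estimate(ContingencyTable(*cells))
        assert not est.defined and math.isnan(est.ror)

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(-1, 2, 3, 4)

    def test_ror_invariant_under_cell_scaling_and_ci_narrows(self):
        base = ContingencyTable(4, 16, 25, 400)
        e1 = ror_estimate(base)
        widths = []
        for k in (1, 3, 9):
            ek = ror_estimate(ContingencyTable(4 * k, 16 * k, 25 * k, 400 * k))
            assert ek.ror == pytest.approx(e1.ror)
            widths.append(math.log(ek.ci_high) - math.log(ek.ci_low))
        assert widths[0] > widths[1] > widths[2]

    @given(st.tuples(*[st.integers(1, 10_000)] * 4))
    @settings(max_examples=200, deadline=None)
    def test_point_estimate_inside_interval(self, cells):
        est = ror_estimate(ContingencyTable(*cells))
        assert est.ci_low < est.ror < est.ci_high


class TestSignalRule:
    @pytest.mark.parametrize("table, positive", [
        (ContingencyTable(3, 10, 20, 5000), True),    # a=3, ci_low>1
        (ContingencyTable(2, 1, 20, 5000), False),    # only 2 reports
        (ContingencyTable(100, 5000, 100, 5000), False),  # ci_low < 1
    ])
    def test_three_reports_and_lower_ci_above_one(self, table, positive):
        res = signal_from_table("X", table)
        if positive:
            assert res.ci_low > 1
        assert res.is_positive is positive

    def test_boundary_a_equals_min_reports(self):
        t = ContingencyTable(3, 10, 20, 5000)
        assert signal_from_table("X", t, min_reports=3).is_positive
        assert not signal_from_table("X", t, min_reports=4).is_positive


MAP = AtcMap({f"Drug{i}": (f"N0{i % 3}AA{i:02d}",) for i in range(6)})


def _random_cohort(rng, n):
    reports = []
    for i in range(n):
        drug = f"Drug{rng.integers(0, 6)}"
        rx = ("Agranulocytosis",) if rng.random() < 0.3 else ("Nausea",)
        reports.append(make_report(primary_id=str(i), drug=drug, reactions=rx))
    return build_cohort(reports, MAP)


class TestContingency:
    def test_matches_exhaustive_enumeration_on_small_cohorts(self):
        rng = np.random.default_rng(7)
        for trial in range(20):
            cohort = _random_cohort(rng, int(rng.integers(4, 51)))
            for drug in {r.drug_name for r in cohort.reports}:
                t = contingency(cohort, drug=drug)
                # brute-force count over all reports
                a = b = c = d = 0
                for r, case in zip(cohort.reports, cohort.is_case):
                    hit = r.drug_name == drug
                    if hit and case:
                        a += 1
                    elif hit:
                        b += 1
                    elif case:
                        c += 1
                    else:
                        d += 1
                assert (t.a, t.b, t.c, t.d) == (a, b, c, d)
                assert t.total == cohort.n_reports

    def test_absent_drug_gives_empty_index_margin(self, small_cohort):
        t = contingency(small_cohort, drug="No Such Drug")
        assert (t.a, t.b) == (0, 0)

    def test_case_counts_partition_by_drug(self, small_cohort):
        total = sum(contingency(small_cohort, drug=d).a
                    for d in {r.drug_name for r in small_cohort.reports})
        assert total == small_cohort.n_cases


class TestRankings:
    def test_detect_signals_sorted_with_deterministic_ties(self, small_cohort):
        res = detect_signals(small_cohort)
        keys = [(-r.n_reports, r.name) for r in res]
        assert keys == sorted(keys)

    def test_planted_drug_detected(self, small_cohort):
        by_name = {r.name: r for r in detect_signals(small_cohort)}
        assert by_name["SIGNALOL"].is_positive
        assert by_name["SIGNALOL"].ci_low > 1


class TestClassSignals:
    def test_single_class_table_equals_union_of_members(self):
        one_class = AtcMap({"Drug0": ("N05AA00",), "Drug1": ("N05AB01",)})
        reports = [make_report(primary_id=str(i),
                               drug=f"Drug{i % 2}",
                               reactions=("Agranulocytosis",) if i < 3
                               else ("Rash",))
                   for i in range(10)]
        cohort = build_cohort(reports, one_class)
        (cls,) = class_signals(cohort)
        assert cls.name == "N05"
        assert (cls.table.a, cls.table.b) == (3, 7)
        assert cls.table.c == 0 and cls.table.d == 0

    def test_planted_class_ror_within_its_interval(self, small_bundle,
                                                   small_cohort):
        results = {r.name: r for r in class_signals(small_cohort)}
        planted = results["N05"]
        assert planted.ci_low <= 8.0 <= planted.ci_high
        assert planted.n_member_positive >= 1

    def test_unmapped_drugs_absent_from_class_results(self):
        amap = AtcMap({"Drug0": ("N05AA00",)})
        reports = [make_report(primary_id="1", drug="Drug0"),
                   make_report(primary_id="2", drug="Mysteron")]
        cohort = build_cohort(reports, amap)
        names = [r.name for r in class_signals(cohort)]
        assert names == ["N05"]
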