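"""Disproportionality signal detection with the reporting odds ratio (ROR).

For each primary-suspect drug (or ATC level-2 drug class) the 2x2 table

    a = index drug & target event        b = index drug & other events
    c = other drugs & target event       d = other drugs & other events

is formed over the chemotherapy-excluded cohort, and

    ROR = (a*d) / (b*c)
    95% CI = exp( ln ROR ± z * sqrt(1/a + 1/b + 1/c + 1/d) ),  z = 1.96.

A drug is a positive signal when it has at least ``min_reports`` (default 3)
target-event reports and the lower CI bound exceeds 1.  Zero cells leave the
estimate undefined (no continuity correction): the report-count floor in the
signal rule makes a corrected estimate unnecessary.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd

from .cohort import Cohort

Z_95 = 1.959963984540054  # standard normal 97.5% quantile


@dataclasses.dataclass(frozen=True)
class ContingencyTable:
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be nonnegative")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclasses.dataclass(frozen=True)
class RorEstimate:
    ror: float
    ci_low: float
    ci_high: float
    defined: bool


@dataclasses.dataclass
class SignalResult:
    name: str
    table: ContingencyTable
    ror: float
    ci_low: float
    ci_high: float
    is_positive: bool
    n_member_positive: int | None = None  # class-level results only

    @property
    def n_reports(self) -> int:
        return self.table.a


def ror_estimate(t: ContingencyTable, z: float = Z_95) -> RorEstimate:
    """Closed-form ROR and Woolf (log-normal) confidence interval.

    Any zero cell makes all three values undefined (NaN, ``defined=False``).
    """
    if min(t.a, t.b, t.c, t.d) == 0:
        return RorEstimate(math.nan, math.nan, math.nan, False)
    ror = (t.a * t.d) / (t.b * t.c)
    se = math.sqrt(1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d)
    log_ror = math.log(ror)
    return RorEstimate(ror, math.exp(log_ror - z * se),
                       math.exp(log_ror + z * se), True)


def _cells(n_index_case: int, n_index: int, n_cases: int,
           n_total: int) -> ContingencyTable:
    a = n_index_case
    b = n_index - a
    c = n_cases - a
    d = n_total - n_index - c
    return ContingencyTable(a, b, c, d)


def contingency(cohort: Cohort, drug: str | None = None,
                atc_class: str | None = None) -> ContingencyTable:
    """2x2 table for one index drug (normalized name) or ATC level-2 class."""
    if (drug is None) == (atc_class is None):
        raise ValueError("give exactly one of drug= or atc_class=")
    n_total, n_cases = cohort.n_reports, cohort.n_cases
    if drug is not None:
        from .ingest import normalize_drug_name
        key = normalize_drug_name(drug)
        sel = [r.drug_name_norm == key for r in cohort.reports]
    else:
        cls = atc_class.upper()
        sel = [cls in cohort.atc_map.classes(r.drug_name_norm)
               for r in cohort.reports]
    sel = np.asarray(sel, dtype=bool)
    return _cells(int((sel & cohort.is_case).sum()), int(sel.sum()),
                  n_cases, n_total)


def signal_from_table(name: str, t: ContingencyTable, min_reports: int = 3,
                      z: float = Z_95) -> SignalResult:
    """Apply the ROR estimate and positive-signal rule to a prebuilt table."""
    est = ror_estimate(t, z)
    positive = bool(t.a >= min_reports and est.defined and est.ci_low > 1.0)
    return SignalResult(name=name, table=t, ror=est.ror, ci_low=est.ci_low,
                        ci_high=est.ci_high, is_positive=positive)


_result = signal_from_table


def detect_signals(cohort: Cohort, min_reports: int = 3,
                   z: float = Z_95) -> list[SignalResult]:
    """One result per distinct PS drug with at least one target-event report,
    sorted by target-report count (descending, name tie-break)."""
    frame = pd.DataFrame({
        "drug": [r.drug_name_norm for r in cohort.reports],
        "is_case": cohort.is_case,
    })
    if frame.empty:
        return []
    g = frame.groupby("drug")["is_case"].agg(["sum", "count"])
    n_cases, n_total = cohort.n_cases, cohort.n_reports
    out = []
    for name, row in g.iterrows():
        a = int(row["sum"])
        if a < 1:
            continue
        t = _cells(a, int(row["count"]), n_cases, n_total)
        out.append(_result(name, t, min_reports, z))
    return rank_by_reports(out)


def class_signals(cohort: Cohort, level: int = 2, min_reports: int = 3,
                  z: float = Z_95,
                  drug_results: list[SignalResult] | None = None
                  ) -> list[SignalResult]:
    """Per-ATC-class signals (level 2 = first three code characters).

    Drugs without an ATC assignment are absent from every class but still
    count in the reference totals.  ``n_member_positive`` counts the class's
    member drugs that are individually positive.
    """
    if drug_results is None:
        drug_results = detect_signals(cohort, min_reports, z)
    positive_drugs = {r.name for r in drug_results if r.is_positive}
    n_cases, n_total = cohort.n_cases, cohort.n_reports

    per_class: dict[str, dict] = {}
    for r, case in zip(cohort.reports, cohort.is_case):
        for cls in cohort.atc_map.classes(r.drug_name_norm, level=level):
            rec = per_class.setdefault(cls, {"n": 0, "a": 0, "drugs": set()})
            rec["n"] += 1
            rec["a"] += int(case)
            rec["drugs"].add(r.drug_name_norm)
    out = []
    for cls, rec in per_class.items():
        if rec["a"] < 1:
            continue
        t = _cells(rec["a"], rec["n"], n_cases, n_total)
        res = _result(cls, t, min_reports, z)
        res.n_member_positive = len(rec["drugs"] & positive_drugs)
        out.append(res)
    return rank_by_reports(out)


def rank_by_reports(results: list[SignalResult]) -> list[SignalResult]:
    return sorted(results, key=lambda r: (-r.n_reports, r.name))


def rank_by_ror(results: list[SignalResult]) -> list[SignalResult]:
    """Defined estimates first, by descending ROR; ties broken by name."""
    return sorted(results,
                  key=lambda r: (math.isnan(r.ror), -(r.ror if not math.isnan(r.ror) else 0),
                                 r.name))


def signals_frame(results: list[SignalResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "name": r.name, "a": r.table.a, "b": r.table.b, "c": r.table.c,
        "d": r.table.d, "ror": r.ror, "ci_low": r.ci_low, "ci_high": r.ci_high,
        "positive": r.is_positive,
        **({"n_member_positive": r.n_member_positive}
           if r.n_member_positive is not None else {}),
    } for r in results])
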