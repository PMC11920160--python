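"""Time-to-onset analysis for target-event case reports.

Onset is the whole-day difference between the event date and the
primary-suspect drug's (earliest) therapy start date; negative or
unresolvable intervals are excluded and counted.  Strata follow the
conventional pharmacovigilance age bins (<18, 18-44, 45-64, >=65) and sex;
unknown strata are tabulated but excluded from hypothesis tests.

Group comparisons use the standard nonparametric battery: Mann-Whitney U for
two groups (exact for tiny tie-free samples, otherwise the tie- and
continuity-corrected normal approximation), Kruskal-Wallis for several
groups, and Dunn's rank-sum post-hoc test with Bonferroni adjustment.
"""

from __future__ import annotations

import dataclasses
import itertools
import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import Cohort

AGE_GROUPS = ("<18", "18-44", "45-64", ">=65")
UNKNOWN = "UNK"


def age_group(age_years: float | None) -> str:
    if age_years is None or (isinstance(age_years, float) and math.isnan(age_years)):
        return UNKNOWN
    if age_years < 18:
        return "<18"
    if age_years < 45:
        return "18-44"
    if age_years < 65:
        return "45-64"
    return ">=65"


@dataclasses.dataclass(frozen=True)
class OnsetRecord:
    report_id: str
    onset_days: int
    sex: str
    age_group: str
    drug: str


@dataclasses.dataclass(frozen=True)
class StratumSummary:
    stratum: str
    n: int
    median: float
    q1: float
    q3: float


@dataclasses.dataclass(frozen=True)
class TestResult:
    comparison: str
    statistic: float
    p_value: float
    adjusted_p: float | None = None
    defined: bool = True
    note: str = ""


def compute_onsets(cohort: Cohort) -> tuple[list[OnsetRecord], dict]:
    """Onset records for case reports with both dates resolved.

    Returns the records and a counter dict: ``n_cases``, ``n_no_dates``
    (either date missing/unparseable), ``n_negative`` (start after event).
    """
    records: list[OnsetRecord] = []
    n_no_dates = n_negative = 0
    for r, is_case in zip(cohort.reports, cohort.is_case):
        if not is_case:
            continue
        if r.event_date is None or r.therapy_start is None:
            n_no_dates += 1
            continue
        days = (r.event_date - r.therapy_start).days
        if days < 0:
            n_negative += 1
            continue
        records.append(OnsetRecord(
            report_id=r.primary_id, onset_days=days, sex=r.sex,
            age_group=age_group(r.age_years), drug=r.drug_name_norm))
    return records, {"n_cases": int(cohort.is_case.sum()),
                     "n_no_dates": n_no_dates, "n_negative": n_negative,
                     "n_onset_records": len(records)}


def _summary(label: str, values: Sequence[float]) -> StratumSummary:
    v = np.asarray(values, dtype=float)
    q1, med, q3 = np.percentile(v, [25, 50, 75])  # linear interpolation
    return StratumSummary(stratum=label, n=len(v), median=float(med),
                          q1=float(q1), q3=float(q3))


def mann_whitney(group_a: Sequence[float], group_b: Sequence[float]
                 ) -> TestResult:
    """Two-sided Mann-Whitney U.

    Exact null distribution when both groups have n <= 8 and no cross-group
    ties; otherwise the normal approximation with tie correction and
    continuity correction.
    """
    a, b = np.asarray(group_a, float), np.asarray(group_b, float)
    if len(a) == 0 or len(b) == 0:
        return TestResult("Mann-Whitney", math.nan, math.nan, defined=False,
                          note="empty group")
    pooled = np.concatenate([a, b])
    exact_ok = len(a) <= 8 and len(b) <= 8 and len(np.unique(pooled)) == len(pooled)
    method = "exact" if exact_ok else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=True)
    return TestResult("Mann-Whitney", float(res.statistic), float(res.pvalue))


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> TestResult:
    """Tie-corrected Kruskal-Wallis H with chi-square approximation."""
    groups = [np.asarray(g, float) for g in groups if len(g) > 0]
    if len(groups) < 2:
        return TestResult("Kruskal-Wallis", math.nan, math.nan, defined=False,
                          note="fewer than 2 nonempty groups")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return TestResult("Kruskal-Wallis", 0.0, 1.0, defined=False,
                          note="all observations identical (zero variance)")
    h, p = stats.kruskal(*groups)
    return TestResult("Kruskal-Wallis", float(h), float(p))


def dunn_bonferroni(groups: Sequence[Sequence[float]],
                    labels: Sequence[str] | None = None) -> list[TestResult]:
    """Dunn's post-hoc z tests on pooled mean ranks, tie-corrected, with
    Bonferroni multiplication by k(k-1)/2 (capped at 1)."""
    arrays = [np.asarray(g, float) for g in groups]
    if labels is None:
        labels = [f"group{i + 1}" for i in range(len(arrays))]
    if any(len(g) == 0 for g in arrays):
        raise ValueError("dunn_bonferroni requires nonempty groups")
    pooled = np.concatenate(arrays)
    n_total = len(pooled)
    ranks = stats.rankdata(pooled)
    # tie correction term: sum(t^3 - t) / (12 (N - 1))
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts ** 3 - counts)) / (12.0 * (n_total - 1))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term

    mean_ranks, sizes, offset = [], [], 0
    for g in arrays:
        mean_ranks.append(ranks[offset:offset + len(g)].mean())
        sizes.append(len(g))
        offset += len(g)

    n_pairs = len(arrays) * (len(arrays) - 1) // 2
    out = []
    for i, j in itertools.combinations(range(len(arrays)), 2):
        se = math.sqrt(base_var * (1.0 / sizes[i] + 1.0 / sizes[j]))
        if se == 0:
            z, p = 0.0, 1.0
        else:
            z = (mean_ranks[i] - mean_ranks[j]) / se
            p = 2.0 * stats.norm.sf(abs(z))
        out.append(TestResult(comparison=f"{labels[i]} vs {labels[j]}",
                              statistic=z, p_value=p,
                              adjusted_p=min(1.0, p * n_pairs)))
    return out


def stratum_summaries(records: Iterable[OnsetRecord]
                      ) -> tuple[list[StratumSummary], list[TestResult]]:
    """Onset medians/IQRs by sex and age group plus the test battery:
    Mann-Whitney across sexes, Kruskal-Wallis + Dunn-Bonferroni across the
    four age groups.  Unknown strata are summarized but not tested."""
    recs = list(records)
    onsets = [r.onset_days for r in recs]
    summaries = []
    tests: list[TestResult] = []
    if recs:
        summaries.append(_summary("Overall", onsets))
    by_sex = {s: [r.onset_days for r in recs if r.sex == s]
              for s in ("F", "M", UNKNOWN)}
    for s, v in by_sex.items():
        if v:
            summaries.append(_summary(f"Sex:{s}", v))
    if by_sex["F"] and by_sex["M"]:
        t = mann_whitney(by_sex["F"], by_sex["M"])
        tests.append(dataclasses.replace(t, comparison="Sex: F vs M"))
    by_age = {g: [r.onset_days for r in recs if r.age_group == g]
              for g in AGE_GROUPS + (UNKNOWN,)}
    for g in AGE_GROUPS + (UNKNOWN,):
        if by_age[g]:
            summaries.append(_summary(f"Age:{g}", by_age[g]))
    tested = [g for g in AGE_GROUPS if by_age[g]]
    if len(tested) >= 2:
        kw = kruskal_wallis([by_age[g] for g in tested])
        tests.append(dataclasses.replace(kw, comparison="Age groups"))
        if kw.defined:
            tests.extend(dunn_bonferroni([by_age[g] for g in tested],
                                         labels=[f"Age {g}" for g in tested]))
    return summaries, tests


def drug_onset_summaries(records: Iterable[OnsetRecord], cohort: Cohort,
                         min_reports: int = 20, by: str = "drug"
                         ) -> list[StratumSummary]:
    """Median (IQR) onset per drug or per ATC level-2 class, restricted to
    strata with at least ``min_reports`` onset records."""
    groups: dict[str, list[int]] = {}
    for r in records:
        if by == "drug":
            keys: tuple[str, ...] = (r.drug,)
        elif by == "class":
            keys = cohort.atc_map.classes(r.drug, level=2)
        else:
            raise ValueError("by must be 'drug' or 'class'")
        for k in keys:
            groups.setdefault(k, []).append(r.onset_days)
    return [_summary(k, v) for k, v in sorted(groups.items())
            if len(v) >= min_reports]


def cumulative_curve(records: Iterable[OnsetRecord]) -> pd.DataFrame:
    """Cumulative percentage of onsets occurring by each observed day."""
    days = np.sort([r.onset_days for r in records])
    if len(days) == 0:
        return pd.DataFrame(columns=["onset_days", "cumulative_pct"])
    uniq, counts = np.unique(days, return_counts=True)
    return pd.DataFrame({"onset_days": uniq,
                         "cumulative_pct": 100.0 * np.cumsum(counts) / len(days)})


def summaries_frame(summaries: Iterable[StratumSummary]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(s) for s in summaries])


def tests_frame(tests: Iterable[TestResult]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(t) for t in tests])
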