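"""Death-outcome analysis of target-event case reports.

A case is a death when its outcome set contains the FAERS outcome code
``DE``.  Mortality proportions carry exact (Clopper-Pearson) binomial 95%
confidence intervals; the Wilson score interval is available as an
alternative.  Period trends are tested with a Pearson chi-square on the
k x 2 death / non-death table (no continuity correction, standard for
df > 1), followed by pairwise 2x2 chi-square tests WITH Yates continuity
correction, Bonferroni-multiplied by the number of pairs.  Adjusted p-values
are reported both uncapped and capped at 1; machine-readable output uses the
capped value.

Because spontaneous-report extracts are rarely shippable, every entry point
here also accepts pre-aggregated counts (fixture mode) so published summary
tables can be re-analyzed directly.
"""

from __future__ import annotations

import dataclasses
import itertools
import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .cohort import Cohort
from .ingest import CaseReport
from .onset import OnsetRecord, TestResult, mann_whitney

DEATH_CODE = "DE"

#: Default study-period bins: (label, first year, last year inclusive).
DEFAULT_PERIODS = (("2004-2010", 2004, 2010), ("2011-2015", 2011, 2015),
                   ("2016-2020", 2016, 2020), ("2021-2024", 2021, 2024))


@dataclasses.dataclass(frozen=True)
class PeriodBins:
    bins: tuple[tuple[str, int, int], ...] = DEFAULT_PERIODS

    def __post_init__(self):
        years = [(y0, y1) for _, y0, y1 in self.bins]
        if any(y0 > y1 for y0, y1 in years):
            raise ValueError("each bin needs first year <= last year")
        for (a0, a1), (b0, b1) in itertools.combinations(years, 2):
            if a0 <= b1 and b0 <= a1:
                raise ValueError("period bins must be disjoint")

    def label_for(self, year: int) -> str | None:
        for label, y0, y1 in self.bins:
            if y0 <= year <= y1:
                return label
        return None

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(label for label, _, _ in self.bins)

    @classmethod
    def parse(cls, spec: str) -> "PeriodBins":
        """Parse e.g. ``"2004-2010,2011-2015"``."""
        bins = []
        for part in spec.split(","):
            y0, y1 = part.strip().split("-")
            bins.append((part.strip(), int(y0), int(y1)))
        return cls(tuple(bins))


@dataclasses.dataclass(frozen=True)
class MortalitySummary:
    stratum: str
    deaths: int
    non_deaths: int
    rate: float
    ci_low: float
    ci_high: float

    @property
    def total(self) -> int:
        return self.deaths + self.non_deaths


def binomial_ci(k: int, n: int, method: str = "clopper-pearson",
                alpha: float = 0.05) -> tuple[float, float]:
    """Exact (Clopper-Pearson, beta quantiles) or Wilson score interval."""
    sm_method = {"clopper-pearson": "beta", "wilson": "wilson"}[method]
    lo, hi = proportion_confint(k, n, alpha=alpha, method=sm_method)
    return float(lo), float(hi)


def make_summary(stratum: str, deaths: int, non_deaths: int,
                 ci_method: str = "clopper-pearson") -> MortalitySummary:
    n = deaths + non_deaths
    if n == 0:
        return MortalitySummary(stratum, 0, 0, math.nan, math.nan, math.nan)
    lo, hi = binomial_ci(deaths, n, method=ci_method)
    return MortalitySummary(stratum, deaths, non_deaths, deaths / n, lo, hi)


def summaries_from_counts(counts: Iterable[tuple[str, int, int]],
                          ci_method: str = "clopper-pearson"
                          ) -> list[MortalitySummary]:
    """Fixture mode: (stratum, deaths, non_deaths) triples -> summaries."""
    return [make_summary(s, d, nd, ci_method) for s, d, nd in counts]


def flag_deaths(cases: Iterable[CaseReport]) -> np.ndarray:
    """Death indicator per report: outcome set contains ``DE``."""
    return np.array([DEATH_CODE in r.outcomes for r in cases], dtype=bool)


def case_reports(cohort: Cohort) -> list[CaseReport]:
    return [r for r, c in zip(cohort.reports, cohort.is_case) if c]


def period_rates(cases: Sequence[CaseReport], bins: PeriodBins = PeriodBins(),
                 ci_method: str = "clopper-pearson",
                 use_event_date: bool = False
                 ) -> tuple[list[MortalitySummary], int]:
    """Per-period mortality summaries binned by FDA receipt year (or event
    year when ``use_event_date``).  Returns the summaries and the count of
    cases falling outside every bin."""
    death = flag_deaths(cases)
    counts = {label: [0, 0] for label in bins.labels}
    out_of_window = 0
    for r, d in zip(cases, death):
        date = r.event_date if use_event_date else r.fda_date
        label = bins.label_for(date.year) if date is not None else None
        if label is None:
            out_of_window += 1
            continue
        counts[label][int(not d)] += 1
    summaries = [make_summary(label, de, nd, ci_method)
                 for label, (de, nd) in counts.items()]
    return summaries, out_of_window


def omnibus_period_test(summaries: Sequence[MortalitySummary]) -> TestResult:
    """Pearson chi-square on the k x 2 death/non-death table (df = k-1)."""
    rows = [(s.deaths, s.non_deaths) for s in summaries if s.total > 0]
    if len(rows) < 2:
        return TestResult("Period omnibus", math.nan, math.nan, defined=False,
                          note="fewer than 2 nonempty periods")
    table = np.asarray(rows)
    res = stats.chi2_contingency(table, correction=False)
    note = ""
    if (res.expected_freq < 1).any():
        note = "expected cell < 1"
    return TestResult("Period omnibus", float(res.statistic),
                      float(res.pvalue), note=note)


@dataclasses.dataclass(frozen=True)
class PairwiseResult:
    comparison: str
    statistic: float
    p_value: float
    adjusted_p_uncapped: float
    adjusted_p: float         # capped at 1


def pairwise_period_tests(summaries: Sequence[MortalitySummary]
                          ) -> list[PairwiseResult]:
    """All pairwise 2x2 chi-square tests with Yates correction, Bonferroni-
    multiplied by the number of pairs (both uncapped and capped reported)."""
    usable = [s for s in summaries if s.total > 0]
    n_pairs = len(usable) * (len(usable) - 1) // 2
    out = []
    for s1, s2 in itertools.combinations(usable, 2):
        table = [[s1.deaths, s1.non_deaths], [s2.deaths, s2.non_deaths]]
        res = stats.chi2_contingency(table, correction=True)
        adj = float(res.pvalue) * n_pairs
        out.append(PairwiseResult(
            comparison=f"{s1.stratum} vs {s2.stratum}",
            statistic=float(res.statistic), p_value=float(res.pvalue),
            adjusted_p_uncapped=adj, adjusted_p=min(1.0, adj)))
    return out


def gender_death_test(f_deaths: int, f_non: int, m_deaths: int,
                      m_non: int) -> TestResult:
    """2x2 (death x sex) chi-square with Yates correction, unknowns excluded."""
    table = np.array([[f_deaths, f_non], [m_deaths, m_non]])
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return TestResult("Gender: death vs non-death", math.nan, math.nan,
                          defined=False, note="empty margin")
    res = stats.chi2_contingency(table, correction=True)
    return TestResult("Gender: death vs non-death", float(res.statistic),
                      float(res.pvalue))


def death_vs_nondeath_comparisons(
        cases: Sequence[CaseReport],
        onsets: Iterable[OnsetRecord] | None = None) -> list[TestResult]:
    """Compare death vs non-death cases: gender (2x2 Yates chi-square, UNK
    excluded), age (Mann-Whitney on available ages) and, when onset records
    are supplied, time to onset (Mann-Whitney)."""
    death = flag_deaths(cases)
    tests: list[TestResult] = []

    counts = {(s, d): 0 for s in ("F", "M") for d in (True, False)}
    for r, d in zip(cases, death):
        if r.sex in ("F", "M"):
            counts[(r.sex, bool(d))] += 1
    tests.append(gender_death_test(counts[("F", True)], counts[("F", False)],
                                   counts[("M", True)], counts[("M", False)]))

    ages_d = [r.age_years for r, d in zip(cases, death)
              if d and r.age_years is not None]
    ages_n = [r.age_years for r, d in zip(cases, death)
              if not d and r.age_years is not None]
    t = mann_whitney(ages_d, ages_n)
    tests.append(dataclasses.replace(t, comparison="Age: death vs non-death"))

    if onsets is not None:
        death_ids = {r.primary_id for r, d in zip(cases, death) if d}
        on_d = [o.onset_days for o in onsets if o.report_id in death_ids]
        on_n = [o.onset_days for o in onsets if o.report_id not in death_ids]
        t = mann_whitney(on_d, on_n)
        tests.append(dataclasses.replace(
            t, comparison="Time to onset: death vs non-death"))
    return tests


def gender_balance_test(n_female: int, n_male: int) -> TestResult:
    """1-df goodness-of-fit chi-square of (F, M) counts against a 50:50
    split, unknowns excluded, no continuity correction."""
    if n_female <= 0 or n_male <= 0:
        return TestResult("Gender balance", math.nan, math.nan, defined=False,
                          note="need positive F and M counts")
    res = stats.chisquare([n_female, n_male])
    return TestResult("Gender balance", float(res.statistic),
                      float(res.pvalue))


def drug_mortality(cases: Sequence[CaseReport], min_deaths: int = 20,
                   ci_method: str = "clopper-pearson"
                   ) -> list[MortalitySummary]:
    """Per-drug mortality among case reports, restricted to drugs with at
    least ``min_deaths`` death reports."""
    death = flag_deaths(cases)
    per_drug: dict[str, list[int]] = {}
    for r, d in zip(cases, death):
        rec = per_drug.setdefault(r.drug_name_norm, [0, 0])
        rec[int(not d)] += 1
    return [make_summary(drug, de, nd, ci_method)
            for drug, (de, nd) in sorted(per_drug.items())
            if de >= min_deaths]


def summaries_frame(summaries: Iterable[MortalitySummary]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(s) for s in summaries])


def pairwise_frame(results: Iterable[PairwiseResult]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(r) for r in results])
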