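"""End-to-end orchestration: generate/ingest -> cohort -> signals ->
classification -> onset -> mortality, with a stage-by-stage run report.

All stages are deterministic given the input bundle (or generator seed), so
two runs of the same configuration produce identical output tables.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Any

import pandas as pd
import yaml
from pydantic import BaseModel, Field, model_validator

from . import classify as _classify
from . import mortality as _mortality
from . import onset as _onset
from . import signals as _signals
from .cohort import AtcMap, build_cohort
from .ingest import ingest_bundle, reports_to_frame
from .synthetic_faers import GeneratorConfig, generate_bundle

logger = logging.getLogger("ncdia")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, code: str, message: str):
        super().__init__(f"[{stage}:{code}] {message}")
        self.stage = stage
        self.code = code


class RunConfig(BaseModel):
    """Flat run configuration (loadable from YAML)."""

    bundle_dir: str | None = None
    generator: GeneratorConfig | None = None
    target_pt: str = "Agranulocytosis"
    atc_map_path: str | None = None
    annotations_path: str | None = None
    min_signal_reports: int = Field(ge=1, default=3)
    min_onset_reports: int = Field(ge=1, default=20)
    min_deaths: int = Field(ge=1, default=20)
    periods: str = "2004-2010,2011-2015,2016-2020,2021-2024"
    seed: int = 0
    out_dir: str | None = None

    @model_validator(mode="after")
    def _one_source(self):
        if (self.bundle_dir is None) == (self.generator is None):
            raise ValueError("exactly one of bundle_dir or generator required")
        return self

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.model_validate(yaml.safe_load(fh))


@dataclasses.dataclass
class RunReport:
    stage_counts: dict[str, Any]
    tables: dict[str, pd.DataFrame]

    def write(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, table in self.tables.items():
            table.to_csv(out / f"{name}.tsv", sep="\t", index=False)
        lines = [f"{k}\t{v}" for k, v in self.stage_counts.items()]
        (out / "run_report.tsv").write_text("\n".join(lines) + "\n")
        return out


def _atc_map_for(config: RunConfig, bundle) -> AtcMap:
    if config.atc_map_path:
        return AtcMap.from_tsv(config.atc_map_path)
    if bundle is not None:
        truth = bundle.truth.drug_table
        return AtcMap({row.drug: (row.atc_code,)
                       for row in truth.itertuples(index=False)})
    raise PipelineError("cohort", "no_atc_map",
                        "atc_map_path required when ingesting an external bundle")


def run_all(config: RunConfig) -> RunReport:
    """Run every stage; returns (and optionally writes) all output tables
    plus a funnel of input/retained counts per stage."""
    counts: dict[str, Any] = {}
    tables: dict[str, pd.DataFrame] = {}

    bundle = None
    if config.generator is not None:
        gen_cfg = config.generator.model_copy(update={"seed": config.seed})
        bundle = generate_bundle(gen_cfg)
        source: Any = bundle
        counts["generated_reports"] = gen_cfg.n_reports
    else:
        source = config.bundle_dir

    try:
        reports, ingest_log = ingest_bundle(source)
    except (FileNotFoundError, ValueError) as exc:
        raise PipelineError("ingest", "input_error", str(exc)) from exc
    counts.update({f"ingest.{k}": v for k, v in ingest_log.items()
                   if not isinstance(v, dict)})
    tables["cases"] = reports_to_frame(reports)

    atc_map = _atc_map_for(config, bundle)
    cohort = build_cohort(reports, atc_map, target_pt=config.target_pt)
    counts["cohort.n_reports"] = cohort.n_reports
    counts["cohort.n_cases"] = cohort.n_cases
    counts["cohort.n_excluded_chemo"] = cohort.n_excluded_chemo

    drug_sig = _signals.detect_signals(cohort,
                                       min_reports=config.min_signal_reports)
    class_sig = _signals.class_signals(cohort, drug_results=drug_sig,
                                       min_reports=config.min_signal_reports)
    tables["signals_drug"] = _signals.signals_frame(drug_sig)
    tables["signals_class"] = _signals.signals_frame(class_sig)
    counts["signals.n_drugs"] = len(drug_sig)
    counts["signals.n_positive"] = sum(r.is_positive for r in drug_sig)

    annotations = (_classify.read_annotations(config.annotations_path)
                   if config.annotations_path else {})
    tier_table = _classify.classify_all(drug_sig, annotations)
    tables["risk_tiers"] = tier_table.frame()
    for tier, n in tier_table.counts.items():
        counts[f"classify.{tier}"] = n

    onset_records, onset_log = _onset.compute_onsets(cohort)
    counts.update({f"onset.{k}": v for k, v in onset_log.items()})
    summaries, tests = _onset.stratum_summaries(onset_records)
    tables["onset_strata"] = _onset.summaries_frame(summaries)
    tables["onset_tests"] = _onset.tests_frame(tests)
    tables["onset_drugs"] = _onset.summaries_frame(
        _onset.drug_onset_summaries(onset_records, cohort,
                                    min_reports=config.min_onset_reports))
    tables["onset_classes"] = _onset.summaries_frame(
        _onset.drug_onset_summaries(onset_records, cohort, by="class",
                                    min_reports=config.min_onset_reports))
    tables["onset_cumulative"] = _onset.cumulative_curve(onset_records)

    cases = _mortality.case_reports(cohort)
    bins = _mortality.PeriodBins.parse(config.periods)
    period, out_of_window = _mortality.period_rates(cases, bins)
    counts["mortality.n_deaths"] = int(_mortality.flag_deaths(cases).sum())
    counts["mortality.out_of_window"] = out_of_window
    tables["mortality_periods"] = _mortality.summaries_frame(period)
    mort_tests = [_mortality.omnibus_period_test(period)]
    mort_tests += _mortality.death_vs_nondeath_comparisons(cases, onset_records)
    f = sum(1 for r in cases if r.sex == "F")
    m = sum(1 for r in cases if r.sex == "M")
    mort_tests.append(_mortality.gender_balance_test(f, m))
    tables["mortality_tests"] = _onset.tests_frame(mort_tests)
    tables["mortality_pairwise"] = _mortality.pairwise_frame(
        _mortality.pairwise_period_tests(period))
    tables["mortality_drugs"] = _mortality.summaries_frame(
        _mortality.drug_mortality(cases, min_deaths=config.min_deaths))

    report = RunReport(stage_counts=counts, tables=tables)
    if config.out_dir:
        report.write(config.out_dir)
    return report


def fixture_mortality_report(
        period_counts: list[tuple[str, int, int]],
        gender_counts: dict[str, tuple[int, int]] | None = None,
        ci_method: str = "clopper-pearson") -> dict[str, Any]:
    """Fixture mode: analyze pre-aggregated count tables directly.

    ``period_counts``: (label, deaths, non_deaths) per period;
    ``gender_counts``: {"F": (deaths, non_deaths), "M": (deaths, non_deaths)}.
    Returns summaries, the omnibus and pairwise period tests, and — when
    gender counts are given — the death-vs-gender and gender-balance tests.
    """
    summaries = _mortality.summaries_from_counts(period_counts, ci_method)
    out: dict[str, Any] = {
        "period_summaries": summaries,
        "omnibus": _mortality.omnibus_period_test(summaries),
        "pairwise": _mortality.pairwise_period_tests(summaries),
        "overall": _mortality.make_summary(
            "Overall", sum(s.deaths for s in summaries),
            sum(s.non_deaths for s in summaries), ci_method),
    }
    if gender_counts:
        (fd, fn), (md, mn) = gender_counts["F"], gender_counts["M"]
        out["gender_test"] = _mortality.gender_death_test(fd, fn, md, mn)
        out["gender_balance"] = _mortality.gender_balance_test(fd + fn, md + mn)
    return out
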