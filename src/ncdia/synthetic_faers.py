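"""Synthetic FAERS-style quarterly bundle generator with known ground truth.

Emulates the record structure of FDA Adverse Event Reporting System (FAERS)
quarterly ASCII extracts — DEMO / DRUG / REAC / OUTC / THER tables keyed by
PRIMARYID, case versions sharing a CASEID, and post-2019 delete lists — with
planted drug-event odds multipliers so that every downstream stage
(deduplication, cohort construction, disproportionality, onset and mortality
analysis) can be validated against a known generative model.

The generative model for the target event is a logistic-odds mixture: a
background event probability ``background_event_prob`` defines baseline odds
``o0 = p/(1-p)``; a drug with ``event_odds_multiplier`` m produces the event
with probability ``m*o0 / (1 + m*o0)``.  When one drug's multiplier differs
from a background of 1 and that drug is a minority of reports, the reporting
odds ratio of the drug-vs-rest 2x2 table converges to m.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

DEFAULT_TARGET_PT = "Agranulocytosis"

# Background MedDRA preferred terms for non-target reactions.
BACKGROUND_PTS = (
    "Nausea", "Headache", "Rash", "Dizziness", "Pyrexia",
    "Fatigue", "Diarrhoea", "Vomiting", "Pruritus", "Insomnia",
)
COUNTRIES = ("US", "FR", "GB", "DE", "JP", "CA")
COUNTRY_WEIGHTS = (0.35, 0.25, 0.12, 0.12, 0.08, 0.08)
# FAERS occp_cod values: physician, pharmacist, other health professional,
# lawyer, consumer.
OCCUPATIONS = ("MD", "PH", "OT", "LW", "CN")
OCCUPATION_WEIGHTS = (0.45, 0.15, 0.2, 0.02, 0.18)

OUTCOME_HOSPITALIZATION_P = 0.15
OUTCOME_LIFE_THREATENING_P = 0.05
OUTCOME_OTHER_P = 0.20
EXTRA_REACTION_P = 0.30


class DrugProfile(BaseModel):
    """One drug in the synthetic population and its planted parameters.

    ``event_odds_multiplier`` is the true odds ratio of the target event for
    this drug relative to the background odds; ``onset_log_mean`` /
    ``onset_log_sd`` parameterize a log-normal time-to-onset in days
    (FAERS onset distributions are heavy-tailed and right-skewed);
    ``death_prob_given_event`` is the conditional death probability for
    target-event reports.
    """

    name: str = Field(min_length=1)
    atc_code: str = Field(min_length=1)
    base_report_prob: float = Field(gt=0)
    event_odds_multiplier: float = Field(ge=0, default=1.0)
    onset_log_mean: float = 3.0  # median ~ e^3 ≈ 20 days
    onset_log_sd: float = Field(gt=0, default=1.0)
    death_prob_given_event: float = Field(ge=0, le=1, default=0.1)


class Demographics(BaseModel):
    """Distributions for patient-level fields."""

    sex_probs: tuple[float, float, float] = (0.46, 0.46, 0.08)  # F, M, UNK
    age_mean: float = 57.0
    age_sd: float = 20.0
    age_missing_frac: float = Field(ge=0, lt=1, default=0.15)

    @field_validator("sex_probs")
    @classmethod
    def _probs_sum_to_one(cls, v: tuple[float, float, float]):
        if abs(sum(v) - 1.0) > 1e-9 or min(v) < 0:
            raise ValueError("sex_probs must be nonnegative and sum to 1")
        return v


class GeneratorConfig(BaseModel):
    """Full configuration of one synthetic bundle."""

    n_reports: int = Field(ge=1)
    drugs: list[DrugProfile] = Field(min_length=1)
    quarters: list[tuple[int, int]] = [(2023, 1), (2023, 2)]
    duplicate_rate: float = Field(ge=0, lt=1, default=0.0)
    same_fda_dt_fraction: float = Field(ge=0, le=1, default=0.25)
    delete_rate: float = Field(ge=0, lt=1, default=0.0)
    seed: int = 0
    background_event_prob: float = Field(gt=0, lt=1, default=0.02)
    background_death_prob: float = Field(ge=0, le=1, default=0.02)
    partial_date_fraction: float = Field(ge=0, lt=1, default=0.0)
    missing_therapy_frac: float = Field(ge=0, lt=1, default=0.1)
    target_pt: str = DEFAULT_TARGET_PT
    demographics: Demographics = Demographics()

    @field_validator("quarters")
    @classmethod
    def _valid_quarters(cls, v):
        if not v:
            raise ValueError("quarters must be nonempty")
        for y, q in v:
            if q not in (1, 2, 3, 4) or y < 1990:
                raise ValueError(f"invalid quarter ({y}, {q})")
        return v

    @model_validator(mode="after")
    def _weights_positive(self):
        if sum(d.base_report_prob for d in self.drugs) <= 0:
            raise ValueError("drugs: total base_report_prob must be positive")
        return self


@dataclasses.dataclass
class GroundTruth:
    """Generator bookkeeping used as the oracle by downstream tests."""

    drug_table: pd.DataFrame         # name, atc_code, multiplier, n_reports, n_events
    report_table: pd.DataFrame       # per unique case: caseid, drug, is_event, death, onset_days, retained_primaryid, deleted
    n_unique_cases: int
    n_duplicated_cases: int
    n_deleted_cases: int

    @property
    def n_final_cases(self) -> int:
        return self.n_unique_cases - self.n_deleted_cases


@dataclasses.dataclass
class FaersBundle:
    """In-memory quarterly bundle: string-typed tables in FAERS ASCII dialect."""

    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    outc: pd.DataFrame
    ther: pd.DataFrame
    deletes: pd.DataFrame            # columns: quarter, primaryid
    truth: GroundTruth
    quarters: list[tuple[int, int]]

    @property
    def delete_ids(self) -> set[str]:
        return set(self.deletes["primaryid"])

    def write(self, out_dir: str | Path) -> Path:
        """Write one directory per quarter with $-delimited ASCII files plus
        (for quarters >= 2019Q1) a delete list, and a ground-truth TSV."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        tables = {"DEMO": self.demo, "DRUG": self.drug, "REAC": self.reac,
                  "OUTC": self.outc, "THER": self.ther}
        for year, q in self.quarters:
            label = f"{year}q{q}"
            qdir = out / label
            qdir.mkdir(exist_ok=True)
            yy = f"{year % 100:02d}"
            for name, frame in tables.items():
                sub = frame[frame["quarter"] == label].drop(columns="quarter")
                path = qdir / f"{name}{yy}Q{q}.txt"
                sub.to_csv(path, sep="$", index=False)
            if (year, q) >= (2019, 1):
                dels = self.deletes.loc[self.deletes["quarter"] == label,
                                        "primaryid"]
                (qdir / f"DELETED{yy}Q{q}.txt").write_text(
                    "\n".join(dels) + ("\n" if len(dels) else ""))
        self.truth.drug_table.to_csv(out / "ground_truth.tsv", sep="\t",
                                     index=False)
        return out


def _quarter_bounds(year: int, q: int) -> tuple[int, int]:
    """Ordinal day range [start, end) of a calendar quarter."""
    start = _dt.date(year, 3 * q - 2, 1).toordinal()
    if q == 4:
        end = _dt.date(year + 1, 1, 1).toordinal()
    else:
        end = _dt.date(year, 3 * q + 1, 1).toordinal()
    return start, end


_UNIX_EPOCH_ORDINAL = _dt.date(1970, 1, 1).toordinal()


def _dates_to_str(ordinals: np.ndarray) -> np.ndarray:
    days = np.asarray(ordinals, dtype="int64") - _UNIX_EPOCH_ORDINAL
    iso = np.datetime_as_string(days.astype("datetime64[D]"), unit="D")
    return np.char.replace(iso, "-", "").astype(object)


def _truncate_dates(rng: np.random.Generator, dates: np.ndarray,
                    frac: float) -> np.ndarray:
    """Truncate a random fraction of YYYYMMDD strings to YYYYMM or YYYY."""
    if frac <= 0:
        return dates
    dates = dates.copy()
    mask = (rng.random(len(dates)) < frac) & (dates != "")
    to_month = mask & (rng.random(len(dates)) < 0.5)
    to_year = mask & ~to_month
    for i in np.nonzero(to_month)[0]:
        dates[i] = dates[i][:6]
    for i in np.nonzero(to_year)[0]:
        dates[i] = dates[i][:4]
    return dates


def generate_bundle(config: GeneratorConfig) -> FaersBundle:
    """Generate one synthetic quarterly bundle.

    Fixed seed gives byte-identical output.  Every case has exactly one DEMO
    row per version, exactly one primary-suspect (PS) drug, and therapy start
    dates never after the event date.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_reports
    drugs = config.drugs
    demo_cfg = config.demographics

    weights = np.array([d.base_report_prob for d in drugs], dtype=float)
    weights /= weights.sum()
    drug_idx = rng.choice(len(drugs), size=n, p=weights)

    # Target event via the logistic-odds mixture.
    p0 = config.background_event_prob
    o0 = p0 / (1.0 - p0)
    mult = np.array([d.event_odds_multiplier for d in drugs])[drug_idx]
    odds = o0 * mult
    p_event = odds / (1.0 + odds)
    is_event = rng.random(n) < p_event

    # Demographics.
    sex = rng.choice(np.array(["F", "M", "UNK"]), size=n,
                     p=np.array(demo_cfg.sex_probs))
    age = np.clip(rng.normal(demo_cfg.age_mean, demo_cfg.age_sd, n), 0.0, 100.0)
    age_missing = rng.random(n) < demo_cfg.age_missing_frac
    country = rng.choice(np.array(COUNTRIES), size=n,
                         p=np.array(COUNTRY_WEIGHTS))
    occupation = rng.choice(np.array(OCCUPATIONS), size=n,
                            p=np.array(OCCUPATION_WEIGHTS))

    # Dates: FDA receipt date uniform in the assigned quarter; event date a
    # short reporting lag before receipt; therapy start = event - onset.
    q_idx = rng.integers(0, len(config.quarters), size=n)
    bounds = np.array([_quarter_bounds(y, q) for y, q in config.quarters])
    q_start, q_end = bounds[q_idx, 0], bounds[q_idx, 1]
    fda_ord = q_start + rng.integers(0, q_end - q_start)
    report_lag = rng.integers(0, 61, size=n)
    event_ord = fda_ord - report_lag

    mu = np.array([d.onset_log_mean for d in drugs])[drug_idx]
    sg = np.array([d.onset_log_sd for d in drugs])[drug_idx]
    onset_days = np.rint(rng.lognormal(mu, sg)).astype(int)
    # non-event reports get a generic exposure interval
    bg_onset = np.rint(rng.exponential(30.0, n)).astype(int)
    onset = np.where(is_event, onset_days, bg_onset)
    ther_ord = event_ord - onset
    ther_missing = rng.random(n) < config.missing_therapy_frac

    # Outcomes.
    death_p = np.array([d.death_prob_given_event for d in drugs])[drug_idx]
    death = np.where(is_event, rng.random(n) < death_p,
                     rng.random(n) < config.background_death_prob)
    hosp = rng.random(n) < OUTCOME_HOSPITALIZATION_P
    life_thr = rng.random(n) < OUTCOME_LIFE_THREATENING_P
    other_out = rng.random(n) < OUTCOME_OTHER_P

    # Reactions: target PT for events, plus background PTs.
    extra_pt = rng.random(n) < EXTRA_REACTION_P
    bg_pt = rng.choice(np.array(BACKGROUND_PTS), size=n)

    # Case identity and versioning.  PRIMARYID = CASEID || version digit, so
    # numeric PRIMARYID ordering matches version ordering (FAERS convention).
    caseid = 10_000_000 + np.arange(n)
    dup = rng.random(n) < config.duplicate_rate
    same_dt = dup & (rng.random(n) < config.same_fda_dt_fraction)
    retained_pid = (caseid * 10 + 2).astype(str)
    single_pid = (caseid * 10 + 1).astype(str)
    pid = np.where(dup, retained_pid, single_pid)
    # earlier version for duplicated cases
    v1_lag = rng.integers(1, 91, size=n)
    v1_ord = np.where(same_dt, fda_ord, np.maximum(fda_ord - v1_lag, q_start))

    quarter_label = np.array([f"{y}q{q}" for y, q in config.quarters])[q_idx]
    fda_str = _dates_to_str(fda_ord)
    event_str = _dates_to_str(event_ord)
    ther_str = _dates_to_str(ther_ord)
    age_str = np.where(age_missing, "", np.char.mod("%d", np.rint(age)))

    event_str_out = _truncate_dates(rng, event_str, config.partial_date_fraction)
    ther_str_out = _truncate_dates(rng, ther_str, config.partial_date_fraction)
    ther_str_out = np.where(ther_missing, "", ther_str_out)

    def demo_rows(pids, fda_ords, versions):
        return pd.DataFrame({
            "primaryid": pids,
            "caseid": caseid.astype(str),
            "caseversion": versions,
            "fda_dt": _dates_to_str(fda_ords),
            "event_dt": event_str_out,
            "age": age_str,
            "age_cod": np.where(age_str == "", "", "YR"),
            "sex": np.where(sex == "UNK", "", sex),
            "occr_country": country,
            "occp_cod": occupation,
            "quarter": quarter_label,
        })

    demo = demo_rows(pid, fda_ord, np.full(n, "2", dtype=object))
    demo_v1 = demo_rows(single_pid, v1_ord,
                        np.full(n, "1", dtype=object))[dup]
    demo = pd.concat([demo, demo_v1], ignore_index=True)

    drug_names = np.array([d.name for d in drugs])[drug_idx]

    def child(pids, sel=slice(None)):
        """Replicate per-report child rows for a given primaryid vector."""
        base = {
            "drug": pd.DataFrame({
                "primaryid": pids, "caseid": caseid.astype(str)[sel],
                "drug_seq": "1", "role_cod": "PS",
                "drugname": drug_names[sel], "quarter": quarter_label[sel]}),
            "ther": pd.DataFrame({
                "primaryid": pids, "caseid": caseid.astype(str)[sel],
                "dsg_drug_seq": "1", "start_dt": ther_str_out[sel],
                "quarter": quarter_label[sel]}),
        }
        return base

    main = child(pid)
    dup_child = child(single_pid[dup], dup)
    drug_t = pd.concat([main["drug"], dup_child["drug"]], ignore_index=True)
    ther_t = pd.concat([main["ther"], dup_child["ther"]], ignore_index=True)

    def reac_rows(pids, sel):
        frames = []
        tgt = is_event[sel]
        frames.append(pd.DataFrame({
            "primaryid": pids[tgt], "caseid": caseid.astype(str)[sel][tgt],
            "pt": config.target_pt, "quarter": quarter_label[sel][tgt]}))
        bg_mask = (~is_event[sel]) | extra_pt[sel]
        frames.append(pd.DataFrame({
            "primaryid": pids[bg_mask],
            "caseid": caseid.astype(str)[sel][bg_mask],
            "pt": bg_pt[sel][bg_mask], "quarter": quarter_label[sel][bg_mask]}))
        return pd.concat(frames, ignore_index=True)

    all_idx = np.ones(n, dtype=bool)
    reac_t = pd.concat([reac_rows(pid, all_idx),
                        reac_rows(single_pid[dup], dup)], ignore_index=True)

    def outc_rows(pids, sel):
        frames = []
        for code, mask in (("DE", death), ("HO", hosp), ("LT", life_thr),
                           ("OT", other_out)):
            m = mask[sel]
            frames.append(pd.DataFrame({
                "primaryid": pids[m], "caseid": caseid.astype(str)[sel][m],
                "outc_cod": code, "quarter": quarter_label[sel][m]}))
        return pd.concat(frames, ignore_index=True)

    outc_t = pd.concat([outc_rows(pid, all_idx),
                        outc_rows(single_pid[dup], dup)], ignore_index=True)

    # Delete lists: only quarters >= 2019Q1 carry delete files.
    q_arr = np.array(config.quarters)
    deletable_q = (q_arr[:, 0] > 2019) | ((q_arr[:, 0] == 2019) & (q_arr[:, 1] >= 1))
    in_deletable = deletable_q[q_idx]
    deleted = in_deletable & (rng.random(n) < config.delete_rate)
    deletes = pd.DataFrame({"quarter": quarter_label[deleted],
                            "primaryid": pid[deleted]})

    drug_table = pd.DataFrame({
        "drug": [d.name for d in drugs],
        "atc_code": [d.atc_code for d in drugs],
        "event_odds_multiplier": [d.event_odds_multiplier for d in drugs],
        "n_reports": np.bincount(drug_idx, minlength=len(drugs)),
        "n_events": np.bincount(drug_idx, weights=is_event,
                                minlength=len(drugs)).astype(int),
    })
    report_table = pd.DataFrame({
        "caseid": caseid.astype(str),
        "drug": drug_names,
        "is_event": is_event,
        "death": death,
        "onset_days": np.where(ther_missing, -1, onset),
        "retained_primaryid": pid,
        "duplicated": dup,
        "deleted": deleted,
    })
    truth = GroundTruth(drug_table=drug_table, report_table=report_table,
                        n_unique_cases=n, n_duplicated_cases=int(dup.sum()),
                        n_deleted_cases=int(deleted.sum()))
    return FaersBundle(demo=demo, drug=drug_t, reac=reac_t, outc=outc_t,
                       ther=ther_t, deletes=deletes, truth=truth,
                       quarters=list(config.quarters))


def default_drug_panel(n_background: int = 20,
                       planted: Sequence[tuple[str, str, float]] = ()) \
        -> list[DrugProfile]:
    """A convenience panel: ``n_background`` null drugs (multiplier 1) plus
    planted (name, atc_code, multiplier) entries."""
    atc_letters = ["A02", "C03", "J01", "M01", "N02", "N06", "R06", "B01"]
    panel = [
        DrugProfile(name=f"Backgroundin-{i:02d}",
                    atc_code=f"{atc_letters[i % len(atc_letters)]}A{i:02d}",
                    base_report_prob=1.0)
        for i in range(n_background)
    ]
    panel += [DrugProfile(name=name, atc_code=atc, base_report_prob=1.0,
                          event_odds_multiplier=m)
              for name, atc, m in planted]
    return panel
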