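"""FAERS bundle ingestion: parsing, deduplication, delete-list filtering and
normalization to one primary-suspect case report per patient.

The cleaning procedure mirrors standard FAERS practice: case versions share a
CASEID; for each CASEID the version with the latest FDA receipt date (FDA_DT)
is retained, ties broken by the highest (numeric) PRIMARYID; quarterly delete
lists (published since 2019Q1) are applied after versioning, so a deleted
latest version removes the case entirely; and only the primary-suspect (PS)
drug of each retained report is carried forward.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import logging
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

logger = logging.getLogger("ncdia")

#: FAERS age-unit codes -> factor converting the stored value to years.
AGE_UNIT_TO_YEARS = {
    "DEC": 10.0,
    "YR": 1.0,
    "MON": 1.0 / 12.0,
    "WK": 1.0 / 52.18,
    "DY": 1.0 / 365.25,
    "HR": 1.0 / 8766.0,
}
MAX_PLAUSIBLE_AGE = 150.0

MANDATORY_FILES = ("DEMO", "DRUG", "REAC", "OUTC", "THER")
MANDATORY_COLUMNS = {
    "DEMO": ["primaryid", "caseid", "fda_dt"],
    "DRUG": ["primaryid", "role_cod", "drugname"],
    "REAC": ["primaryid", "pt"],
    "OUTC": ["primaryid", "outc_cod"],
    "THER": ["primaryid", "start_dt"],
}


class BundleInputError(FileNotFoundError):
    """A mandatory bundle file is missing."""


class BundleSchemaError(ValueError):
    """A mandatory column is missing from a bundle table."""


@dataclasses.dataclass
class RawRecordSet:
    """Raw string-typed FAERS tables plus the union of quarterly delete lists."""

    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    outc: pd.DataFrame
    ther: pd.DataFrame
    delete_ids: set[str] = dataclasses.field(default_factory=set)
    log: dict = dataclasses.field(default_factory=dict)

    def child_tables(self) -> dict[str, pd.DataFrame]:
        return {"drug": self.drug, "reac": self.reac, "outc": self.outc,
                "ther": self.ther}


@dataclasses.dataclass
class CaseReport:
    """One deduplicated, delete-filtered safety report restricted to its
    primary-suspect drug."""

    primary_id: str
    case_id: str
    fda_date: _dt.date
    event_date: _dt.date | None
    sex: str                      # "F", "M" or "UNK"
    age_years: float | None
    country: str | None
    reporter_occupation: str | None
    outcomes: frozenset[str]
    drug_name: str
    drug_name_norm: str
    therapy_start: _dt.date | None
    reactions: frozenset[str]


def normalize_drug_name(name: str) -> str:
    """Trim, uppercase and collapse internal whitespace."""
    return " ".join(str(name).split()).upper()


def parse_faers_date(value: str) -> _dt.date | None:
    """Parse a FAERS date field.

    Full dates are YYYYMMDD; partial dates are completed deterministically:
    YYYYMM -> the 15th of the month, YYYY -> July 1st (midpoint conventions,
    unbiased within their period).  Anything else is missing.
    """
    s = str(value).strip()
    if not s.isdigit():
        return None
    try:
        if len(s) == 8:
            return _dt.date(int(s[:4]), int(s[4:6]), int(s[6:8]))
        if len(s) == 6:
            return _dt.date(int(s[:4]), int(s[4:6]), 15)
        if len(s) == 4:
            return _dt.date(int(s), 7, 1)
    except ValueError:
        return None
    return None


def _parse_date_series(s: pd.Series) -> pd.Series:
    """Vectorized :func:`parse_faers_date`: returns a Series of
    ``datetime.date`` / ``None``."""
    raw = s.astype(str).str.strip()
    digits = raw.str.fullmatch(r"\d+").fillna(False)
    length = raw.str.len()
    completed = pd.Series(
        np.select([digits & (length == 8), digits & (length == 6),
                   digits & (length == 4)],
                  [raw, raw + "15", raw + "0701"], default=""),
        index=s.index)
    dt = pd.to_datetime(completed, format="%Y%m%d", errors="coerce")
    out = pd.Series(dt.dt.date, index=s.index, dtype=object)
    return out.where(dt.notna(), None)


def _read_table(path: Path, log: dict) -> pd.DataFrame:
    bad = {"n": 0}

    def _on_bad(row):  # count, keep a trace, drop the row
        bad["n"] += 1
        return None

    frame = pd.read_csv(path, sep="$", dtype=str, keep_default_na=False,
                        engine="python", on_bad_lines=_on_bad)
    if bad["n"]:
        logger.warning("%s: %d malformed rows dropped", path.name, bad["n"])
    log.setdefault("malformed_rows", {})[path.name] = bad["n"]
    frame.columns = [c.strip().lower() for c in frame.columns]
    return frame


def parse_bundle(bundle_dir: str | Path) -> RawRecordSet:
    """Read a quarterly bundle directory tree into a :class:`RawRecordSet`.

    Accepts either a single quarter directory or a parent directory holding
    one subdirectory per quarter.  Files match ``DEMO*.txt`` etc.; any file
    whose name starts with ``DELETE`` (or contains ``deleted``) is read as a
    delete list of PRIMARYIDs, one per line.
    """
    root = Path(bundle_dir)
    if not root.is_dir():
        raise BundleInputError(f"bundle directory not found: {root}")
    log: dict = {}
    tables: dict[str, list[pd.DataFrame]] = {k: [] for k in MANDATORY_FILES}
    delete_ids: set[str] = set()
    dirs = sorted(d for d in root.iterdir() if d.is_dir()) or [root]
    for qdir in dirs:
        for key in MANDATORY_FILES:
            hits = sorted(qdir.glob(f"{key}*.txt")) + sorted(qdir.glob(f"{key.lower()}*.txt"))
            for h in hits:
                tables[key].append(_read_table(h, log))
        for dfile in sorted(qdir.glob("*.txt")):
            name = dfile.name.lower()
            if name.startswith("delete") or "deleted" in name:
                delete_ids.update(
                    line.strip() for line in dfile.read_text().splitlines()
                    if line.strip() and line.strip().lower() != "primaryid")
    missing = [k for k in MANDATORY_FILES if not tables[k]]
    if missing:
        raise BundleInputError(
            f"missing mandatory bundle file(s): {', '.join(missing)} under {root}")
    merged = {k: pd.concat(v, ignore_index=True) for k, v in tables.items()}
    for key, cols in MANDATORY_COLUMNS.items():
        absent = [c for c in cols if c not in merged[key].columns]
        if absent:
            raise BundleSchemaError(
                f"{key} table is missing mandatory column(s): {absent}")
    log["n_raw_demo"] = len(merged["DEMO"])
    log["n_delete_ids"] = len(delete_ids)
    return RawRecordSet(demo=merged["DEMO"], drug=merged["DRUG"],
                        reac=merged["REAC"], outc=merged["OUTC"],
                        ther=merged["THER"], delete_ids=delete_ids, log=log)


def from_bundle(bundle) -> RawRecordSet:
    """Build a :class:`RawRecordSet` directly from an in-memory
    :class:`~ncdia.synthetic_faers.FaersBundle` (no file round trip)."""
    def strip_q(f: pd.DataFrame) -> pd.DataFrame:
        return f.drop(columns="quarter").astype(str)

    return RawRecordSet(demo=strip_q(bundle.demo), drug=strip_q(bundle.drug),
                        reac=strip_q(bundle.reac), outc=strip_q(bundle.outc),
                        ther=strip_q(bundle.ther),
                        delete_ids=set(bundle.deletes["primaryid"]),
                        log={"n_raw_demo": len(bundle.demo)})


def _numeric_pid_key(pid: pd.Series) -> pd.Series:
    """Sort key for PRIMARYID ties: numeric where possible, else a stable
    lexicographic fallback mapped above no numeric value."""
    num = pd.to_numeric(pid, errors="coerce")
    bad = num.isna()
    if bad.any():
        # non-numeric ids ordered lexicographically among themselves, above
        # every numeric id
        offset = float(num.max()) if num.notna().any() else 0.0
        num = num.copy()
        num[bad] = offset + pid[bad].rank(method="dense")
    return num


def _filter_children(records: RawRecordSet, keep: pd.Series | set,
                     log_key: str) -> RawRecordSet:
    keep_set = set(keep)
    demo = records.demo[records.demo["primaryid"].isin(keep_set)].reset_index(drop=True)
    children = {name: t[t["primaryid"].isin(keep_set)].reset_index(drop=True)
                for name, t in records.child_tables().items()}
    log = dict(records.log)
    log[log_key] = len(demo)
    return RawRecordSet(demo=demo, delete_ids=records.delete_ids, log=log,
                        **children)


def deduplicate(records: RawRecordSet) -> RawRecordSet:
    """Keep one version per CASEID: latest FDA_DT, ties broken by highest
    numeric PRIMARYID.  Child-table rows of dropped versions are removed."""
    demo = records.demo.copy()
    demo["_fda"] = pd.to_numeric(demo["fda_dt"], errors="coerce").fillna(-1)
    demo["_pid"] = _numeric_pid_key(demo["primaryid"])
    demo = demo.sort_values(["caseid", "_fda", "_pid"], kind="mergesort")
    retained = demo.drop_duplicates("caseid", keep="last")["primaryid"]
    return _filter_children(records, retained, "n_after_dedup")


def apply_deletes(records: RawRecordSet) -> RawRecordSet:
    """Remove reports listed in the quarterly delete files (applied after
    deduplication, so a deleted retained version removes its case)."""
    if not records.delete_ids:
        out = _filter_children(records, set(records.demo["primaryid"]),
                               "n_after_deletes")
        return out
    keep = set(records.demo["primaryid"]) - records.delete_ids
    return _filter_children(records, keep, "n_after_deletes")


def _normalize_ages(age: pd.Series, unit: pd.Series,
                    log: dict) -> pd.Series:
    value = pd.to_numeric(age, errors="coerce")
    factor = unit.str.strip().str.upper().map(AGE_UNIT_TO_YEARS)
    years = value * factor
    implausible = years.notna() & ((years < 0) | (years > MAX_PLAUSIBLE_AGE))
    log["n_age_implausible"] = int(implausible.sum())
    log["n_age_unknown_unit"] = int((value.notna() & factor.isna()).sum())
    return years.mask(implausible)


def build_case_reports(records: RawRecordSet) -> list[CaseReport]:
    """Normalize deduplicated, delete-filtered records to one
    :class:`CaseReport` per report carrying a primary-suspect drug.

    Reports with no PS-coded drug are excluded (and counted in the ingest
    log); reports with several PS rows keep the lowest drug sequence number.
    Ages are converted to years from their FAERS unit code; values outside
    [0, 150] years are set to missing and counted.
    """
    log = records.log
    demo = records.demo
    ps = records.drug[records.drug["role_cod"].str.strip().str.upper() == "PS"].copy()
    ps["_seq"] = pd.to_numeric(ps.get("drug_seq", "1"), errors="coerce").fillna(np.inf)
    ps = ps.sort_values(["primaryid", "_seq"], kind="mergesort")
    n_multi = int(ps.duplicated("primaryid").sum())
    if n_multi:
        logger.info("%d reports with multiple PS drugs; keeping lowest drug_seq",
                    n_multi)
    log["n_multiple_ps"] = n_multi
    ps = ps.drop_duplicates("primaryid", keep="first")

    merged = demo.merge(ps[["primaryid", "drugname"] +
                           (["drug_seq"] if "drug_seq" in ps.columns else [])],
                        on="primaryid", how="inner")
    log["n_no_ps_drug"] = len(demo) - len(merged)

    def _set_dict(frame: pd.DataFrame, col: str, upper: bool) -> dict:
        d: dict[str, set] = {}
        for pid, v in zip(frame["primaryid"].to_numpy(),
                          frame[col].to_numpy()):
            v = v.strip()
            if v:
                d.setdefault(pid, set()).add(v.upper() if upper else v)
        return {k: frozenset(v) for k, v in d.items()}

    reac_d = _set_dict(records.reac, "pt", upper=False)
    outc_d = _set_dict(records.outc, "outc_cod", upper=True)

    ther = records.ther.copy()
    if "dsg_drug_seq" in ther.columns and "drug_seq" in merged.columns:
        key = merged[["primaryid", "drug_seq"]].rename(
            columns={"drug_seq": "dsg_drug_seq"})
        ther = ther.merge(key, on=["primaryid", "dsg_drug_seq"], how="inner")
    ther["_start"] = pd.to_datetime(
        pd.Series(_parse_date_series(ther["start_dt"]), dtype=object),
        errors="coerce")
    ther = ther.dropna(subset=["_start"])
    # earliest therapy start: first exposure is the pharmacological anchor
    ther_d = {pid: ts.date() for pid, ts
              in ther.groupby("primaryid")["_start"].min().items()}

    age_years = _normalize_ages(merged.get("age", pd.Series("", index=merged.index)),
                                merged.get("age_cod", pd.Series("", index=merged.index)),
                                log).to_numpy()
    fda_dates = _parse_date_series(merged["fda_dt"]).to_numpy()
    event_dates = (_parse_date_series(merged["event_dt"]).to_numpy()
                   if "event_dt" in merged.columns
                   else np.full(len(merged), None, dtype=object))

    sex_raw = merged.get("sex", pd.Series("", index=merged.index))
    sex_up = sex_raw.str.strip().str.upper()
    sex = sex_up.where(sex_up.isin(["F", "M"]), "UNK").to_numpy()

    pids = merged["primaryid"].to_numpy()
    caseids = merged["caseid"].to_numpy()
    names = merged["drugname"].to_numpy()
    countries = (merged["occr_country"].to_numpy()
                 if "occr_country" in merged.columns
                 else np.full(len(merged), "", dtype=object))
    occps = (merged["occp_cod"].to_numpy() if "occp_cod" in merged.columns
             else np.full(len(merged), "", dtype=object))

    reports: list[CaseReport] = []
    empty: frozenset[str] = frozenset()
    norm_cache: dict[str, str] = {}
    for i in range(len(merged)):
        fda = fda_dates[i]
        if fda is None:
            continue
        pid = pids[i]
        name = names[i]
        norm = norm_cache.get(name)
        if norm is None:
            norm = norm_cache[name] = normalize_drug_name(name)
        a = age_years[i]
        reports.append(CaseReport(
            primary_id=pid, case_id=caseids[i], fda_date=fda,
            event_date=event_dates[i], sex=sex[i],
            age_years=None if np.isnan(a) else float(a),
            country=countries[i] or None,
            reporter_occupation=occps[i] or None,
            outcomes=outc_d.get(pid, empty), drug_name=name,
            drug_name_norm=norm,
            therapy_start=ther_d.get(pid), reactions=reac_d.get(pid, empty)))
    log["n_case_reports"] = len(reports)
    return reports


def ingest_bundle(source) -> tuple[list[CaseReport], dict]:
    """Full ingest funnel: parse -> deduplicate -> apply deletes -> normalize.

    ``source`` is a bundle directory path or an in-memory FaersBundle.
    Returns the case reports and the stage-count log."""
    if isinstance(source, (str, Path)):
        raw = parse_bundle(source)
    else:
        raw = from_bundle(source)
    raw = apply_deletes(deduplicate(raw))
    reports = build_case_reports(raw)
    return reports, raw.log


def reports_to_frame(reports: Iterable[CaseReport]) -> pd.DataFrame:
    """Tabular view of case reports (sets kept as sorted ';'-joined strings)."""
    rows = [{
        "primary_id": r.primary_id, "case_id": r.case_id,
        "fda_date": r.fda_date.isoformat(),
        "event_date": r.event_date.isoformat() if r.event_date else "",
        "sex": r.sex,
        "age_years": "" if r.age_years is None else r.age_years,
        "country": r.country or "", "reporter_occupation": r.reporter_occupation or "",
        "outcomes": ";".join(sorted(r.outcomes)),
        "drug_name": r.drug_name, "drug_name_norm": r.drug_name_norm,
        "therapy_start": r.therapy_start.isoformat() if r.therapy_start else "",
        "reactions": ";".join(sorted(r.reactions)),
    } for r in reports]
    return pd.DataFrame(rows)


def frame_to_reports(frame: pd.DataFrame) -> list[CaseReport]:
    def _d(s):
        return _dt.date.fromisoformat(s) if s else None

    out = []
    for row in frame.fillna("").itertuples(index=False):
        out.append(CaseReport(
            primary_id=str(row.primary_id), case_id=str(row.case_id),
            fda_date=_dt.date.fromisoformat(row.fda_date),
            event_date=_d(row.event_date), sex=row.sex,
            age_years=float(row.age_years) if str(row.age_years) != "" else None,
            country=row.country or None,
            reporter_occupation=row.reporter_occupation or None,
            outcomes=frozenset(x for x in str(row.outcomes).split(";") if x),
            drug_name=row.drug_name, drug_name_norm=row.drug_name_norm,
            therapy_start=_d(row.therapy_start),
            reactions=frozenset(x for x in str(row.reactions).split(";") if x)))
    return out
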