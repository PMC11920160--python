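"""Cohort construction: target-event flagging and chemotherapy exclusion.

The study population is every deduplicated report whose primary-suspect drug
is NOT an antineoplastic agent (WHO ATC class L01); within it, a report is a
case when its reaction set contains the target MedDRA preferred term
(default "Agranulocytosis", matched exactly and case-insensitively — no
standardized-query expansion to related terms such as neutropenia).
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .ingest import CaseReport, normalize_drug_name

logger = logging.getLogger("ncdia")

CHEMO_ATC_PREFIX = "L01"
DEFAULT_TARGET_PT = "Agranulocytosis"


class AtcMap:
    """Total lookup from normalized drug name to ATC code(s).

    Unmapped names return an empty tuple — never an error — so that reports
    whose drug lacks an ATC assignment stay in the reference population while
    being absent from class-level aggregation.
    """

    def __init__(self, mapping: Mapping[str, Sequence[str]] | None = None):
        self._map: dict[str, tuple[str, ...]] = {}
        if mapping:
            for name, codes in mapping.items():
                key = normalize_drug_name(name)
                if isinstance(codes, str):
                    codes = (codes,)
                self._map[key] = tuple(dict.fromkeys(
                    tuple(self._map.get(key, ())) + tuple(codes)))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AtcMap":
        """Two-column TSV (drug_name, atc_code); multiple rows per name allowed."""
        frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        frame.columns = [c.strip().lower() for c in frame.columns]
        m = cls()
        for row in frame.itertuples(index=False):
            key = normalize_drug_name(row.drug_name)
            m._map[key] = tuple(dict.fromkeys(
                m._map.get(key, ()) + (row.atc_code.strip().upper(),)))
        return m

    def codes(self, drug_name: str) -> tuple[str, ...]:
        return self._map.get(normalize_drug_name(drug_name), ())

    def is_chemo(self, drug_name: str) -> bool:
        """True when ANY mapped code starts with L01 (conservative exclusion)."""
        return any(c.startswith(CHEMO_ATC_PREFIX) for c in self.codes(drug_name))

    def classes(self, drug_name: str, level: int = 2) -> tuple[str, ...]:
        """ATC classes at the given level (level 2 = first 3 characters),
        excluding chemotherapy codes."""
        width = {1: 1, 2: 3, 3: 4, 4: 5, 5: 7}[level]
        return tuple(dict.fromkeys(
            c[:width] for c in self.codes(drug_name)
            if not c.startswith(CHEMO_ATC_PREFIX)))

    def __len__(self) -> int:
        return len(self._map)


@dataclasses.dataclass
class Cohort:
    """Chemotherapy-excluded report set with per-report case flags."""

    reports: list[CaseReport]
    is_case: np.ndarray
    target_pt: str
    atc_map: AtcMap
    n_excluded_chemo: int = 0

    @property
    def n_reports(self) -> int:
        return len(self.reports)

    @property
    def n_cases(self) -> int:
        return int(self.is_case.sum())

    @property
    def n_noncases(self) -> int:
        return self.n_reports - self.n_cases

    def frame(self) -> pd.DataFrame:
        """Vectorization-friendly view used by the signal / onset /
        mortality stages."""
        return pd.DataFrame({
            "primary_id": [r.primary_id for r in self.reports],
            "drug_norm": [r.drug_name_norm for r in self.reports],
            "is_case": self.is_case,
            "sex": [r.sex for r in self.reports],
            "age_years": [np.nan if r.age_years is None else r.age_years
                          for r in self.reports],
            "fda_year": [r.fda_date.year for r in self.reports],
            "death": [("DE" in r.outcomes) for r in self.reports],
        })


def build_cohort(reports: Iterable[CaseReport], atc_map: AtcMap,
                 target_pt: str = DEFAULT_TARGET_PT) -> Cohort:
    """Drop chemotherapy (ATC L01) reports and flag target-event cases."""
    reports = list(reports)
    if not reports:
        logger.warning("building cohort from an empty report list")
    target = target_pt.strip().lower()
    kept: list[CaseReport] = []
    flags: list[bool] = []
    n_chemo = 0
    for r in reports:
        if atc_map.is_chemo(r.drug_name_norm):
            n_chemo += 1
            continue
        kept.append(r)
        flags.append(any(pt.strip().lower() == target for pt in r.reactions))
    return Cohort(reports=kept, is_case=np.array(flags, dtype=bool),
                  target_pt=target_pt, atc_map=atc_map,
                  n_excluded_chemo=n_chemo)
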