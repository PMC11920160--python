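"""Three-tier risk classification of positive-signal drugs.

Signaled drugs are classified from an externally curated annotation table
(label/compendium review — an input, not a computation here):

* KNOWN — agranulocytosis is a documented adverse effect of the drug;
* POSSIBLE — agranulocytosis is not documented but other hematologic
  reactions are (febrile neutropenia, neutropenia, leukopenia, decreased
  white-cell count, aplastic anemia);
* NEW_POTENTIAL — no documented hematologic adverse effects at all.

A positive-signal drug missing from the annotation table lands in an
explicit "unannotated" bucket; it is never silently defaulted.
"""

from __future__ import annotations

import dataclasses
import enum
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .ingest import normalize_drug_name
from .signals import SignalResult, rank_by_ror


class RiskTier(enum.Enum):
    KNOWN = "Known"
    POSSIBLE = "Possible"
    NEW_POTENTIAL = "New potential"


@dataclasses.dataclass(frozen=True)
class DrugAnnotation:
    drug: str
    agranulocytosis_documented: bool
    other_hematologic_documented: bool
    case_report_found: bool = False


def classify_drug(ann: DrugAnnotation) -> RiskTier:
    """Rule precedence: documented agranulocytosis dominates."""
    if ann.agranulocytosis_documented:
        return RiskTier.KNOWN
    if ann.other_hematologic_documented:
        return RiskTier.POSSIBLE
    return RiskTier.NEW_POTENTIAL


@dataclasses.dataclass
class TierTable:
    tiers: dict[RiskTier, list[SignalResult]]
    unannotated: list[SignalResult]

    @property
    def counts(self) -> dict[str, int]:
        out = {t.value: len(v) for t, v in self.tiers.items()}
        out["Unannotated"] = len(self.unannotated)
        return out

    def frame(self) -> pd.DataFrame:
        rows = []
        for tier, results in self.tiers.items():
            for r in results:
                rows.append({"drug": r.name, "tier": tier.value,
                             "n_reports": r.n_reports, "ror": r.ror,
                             "ci_low": r.ci_low, "ci_high": r.ci_high})
        for r in self.unannotated:
            rows.append({"drug": r.name, "tier": "Unannotated",
                         "n_reports": r.n_reports, "ror": r.ror,
                         "ci_low": r.ci_low, "ci_high": r.ci_high})
        return pd.DataFrame(rows)


def classify_all(signals: Iterable[SignalResult],
                 annotations: Mapping[str, DrugAnnotation] | Iterable[DrugAnnotation]
                 ) -> TierTable:
    """Partition the positive-signal drugs into tiers, ROR-ranked within each.

    Keys of the annotation mapping are matched on normalized drug names.
    """
    if not isinstance(annotations, Mapping):
        annotations = {a.drug: a for a in annotations}
    ann = {normalize_drug_name(k): v for k, v in annotations.items()}
    tiers: dict[RiskTier, list[SignalResult]] = {t: [] for t in RiskTier}
    unannotated: list[SignalResult] = []
    for res in signals:
        if not res.is_positive:
            continue
        a = ann.get(normalize_drug_name(res.name))
        if a is None:
            unannotated.append(res)
        else:
            tiers[classify_drug(a)].append(res)
    return TierTable(tiers={t: rank_by_ror(v) for t, v in tiers.items()},
                     unannotated=rank_by_ror(unannotated))


def read_annotations(path: str | Path) -> dict[str, DrugAnnotation]:
    """TSV columns: drug, agran_documented, hematologic_documented
    [, case_report] with 0/1 or true/false values."""
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    frame.columns = [c.strip().lower() for c in frame.columns]

    def _b(v: str) -> bool:
        return str(v).strip().lower() in ("1", "true", "yes", "y")

    out = {}
    for row in frame.itertuples(index=False):
        a = DrugAnnotation(
            drug=row.drug,
            agranulocytosis_documented=_b(row.agran_documented),
            other_hematologic_documented=_b(row.hematologic_documented),
            case_report_found=_b(getattr(row, "case_report", "0")))
        out[normalize_drug_name(row.drug)] = a
    return out
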