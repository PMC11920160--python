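import datetime as dt

import pandas as pd
import pytest

from ncdia import (AtcMap, CaseReport, GeneratorConfig, build_cohort,
                   default_drug_panel, generate_bundle, ingest_bundle)

# Published summary counts used as fixture inputs: deaths / non-deaths per
# period, and the gender x outcome breakdown of the same cohort.
PERIOD_COUNTS = [
    ("2004-2010", 262, 1937),
    ("2011-2015", 245, 2111),
    ("2016-2020", 361, 3414),
    ("2021-2024", 188, 2395),
]
GENDER_COUNTS = {"F": (514, 4497), "M": (467, 4625), "UNK": (75, 735)}


def atc_map_from_bundle(bundle) -> AtcMap:
    return AtcMap({row.drug: (row.atc_code,)
                   for row in bundle.truth.drug_table.itertuples(index=False)})


def make_report(primary_id="1001", case_id="1", sex="F", age=50.0,
                outcomes=(), reactions=("Agranulocytosis",),
                drug="Widgetol", fda=dt.date(2020, 3, 1),
                event=dt.date(2020, 2, 1), start=dt.date(2020, 1, 1),
                country="US"):
    from ncdia.ingest import normalize_drug_name
    return CaseReport(
        primary_id=primary_id, case_id=case_id, fda_date=fda,
        event_date=event, sex=sex, age_years=age, country=country,
        reporter_occupation="MD", outcomes=frozenset(outcomes),
        drug_name=drug, drug_name_norm=normalize_drug_name(drug),
        therapy_start=start, reactions=frozenset(reactions))


@pytest.fixture(scope="session")
def small_config() -> GeneratorConfig:
    drugs = default_drug_panel(
        8, [("Signalol", "N05AH99", 8.0), ("Chemocillin", "L01XX05", 5.0)])
    return GeneratorConfig(
        n_reports=2000, drugs=drugs, duplicate_rate=0.15, delete_rate=0.03,
        partial_date_fraction=0.1, seed=42,
        quarters=[(2018, 4), (2019, 1), (2023, 1)])


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return generate_bundle(small_config)


@pytest.fixture(scope="session")
def small_cohort(small_bundle):
    reports, _ = ingest_bundle(small_bundle)
    return build_cohort(reports, atc_map_from_bundle(small_bundle))


@pytest.fixture()
def tiny_bundle_dir(tmp_path):
    """A hand-written single-quarter bundle exercising the ASCII dialect."""
    q = tmp_path / "2023q1"
    q.mkdir()
    (q / "DEMO23Q1.txt").write_text(
        "primaryid$caseid$caseversion$fda_dt$event_dt$age$age_cod$sex$occr_country$occp_cod\n"
        "10011$1001$1$20230110$20230101$50$YR$F$US$MD\n"
        "10021$1002$1$20230215$202301$24$MON$M$FR$PH\n"
        "10031$1003$1$20230301$20230220$$$$$\n")
    (q / "DRUG23Q1.txt").write_text(
        "primaryid$caseid$drug_seq$role_cod$drugname\n"
        "10011$1001$1$PS$Widgetol\n"
        "10011$1001$2$SS$Gadgetin\n"
        "10021$1002$1$PS$Gadgetin\n"
        "10031$1003$1$SS$Widgetol\n")
    (q / "REAC23Q1.txt").write_text(
        "primaryid$caseid$pt\n"
        "10011$1001$Agranulocytosis\n"
        "10011$1001$Pyrexia\n"
        "10021$1002$Nausea\n"
        "10031$1003$Agranulocytosis\n")
    (q / "OUTC23Q1.txt").write_text(
        "primaryid$caseid$outc_cod\n"
        "10011$1001$DE\n"
        "10021$1002$HO\n")
    (q / "THER23Q1.txt").write_text(
        "primaryid$caseid$dsg_drug_seq$start_dt\n"
        "10011$1001$1$20221201\n"
        "10021$1002$1$20230105\n")
    return tmp_path
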