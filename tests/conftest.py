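"""Shared fixtures: small synthetic databases and hand-built record factories."""

from __future__ import annotations

import pytest

from pvsignal.case_selection import select_cohort
from pvsignal.cleaning import deduplicate
from pvsignal.dates import PartialDate
from pvsignal.records import (
    Database,
    DrugEntry,
    IndicationEntry,
    OutcomeEntry,
    ReactionEntry,
    ReportCase,
    TherapyEntry,
)
from pvsignal.synthetic import default_paper_config, generate_database


@pytest.fixture(scope="session")
def small_db():
    """A 500-report synthetic database with its ground truth (seed 11)."""
    cfg = default_paper_config(seed=11, n_reports=500)
    return generate_database(cfg)


@pytest.fixture(scope="session")
def small_clean(small_db):
    db, _truth = small_db
    return deduplicate(db)


@pytest.fixture(scope="session")
def small_cohort(small_clean):
    return select_cohort(small_clean, "aspirin")


def make_report(
    pid,
    case_id=None,
    version=1,
    receipt="20180601",
    event="20180501",
    sex="UNK",
    reporter="unknown",
    country="",
    age=None,
    age_unit="",
):
    from pvsignal.dates import parse_partial_date
    from pvsignal.faers_io import region_for_country

    return ReportCase(
        primary_id=pid,
        case_id=case_id if case_id is not None else pid,
        case_version=version,
        receipt_date=parse_partial_date(receipt),
        event_date=parse_partial_date(event),
        age_value=age,
        age_unit=age_unit,
        sex=sex,
        reporter=reporter,
        country=country,
        region=region_for_country(country),
    )


def make_aspirin_case(
    pid,
    indication="Prophylaxis (NEC)",
    reactions=("Melaena",),
    outcomes=("HO",),
    role="PS",
    **case_kwargs,
):
    """One report with aspirin + indication + reactions, as a Database slice."""
    db = Database()
    db.cases.append(make_report(pid, **case_kwargs))
    db.drugs.append(DrugEntry(pid, 1, "ASPIRIN", role))
    db.indications.append(IndicationEntry(pid, 1, indication))
    for pt in reactions:
        db.reactions.append(ReactionEntry(pid, pt))
    for code in outcomes:
        db.outcomes.append(OutcomeEntry(pid, code))
    return db


def merge(*parts: Database) -> Database:
    out = Database()
    for part in parts:
        out.cases += part.cases
        out.drugs += part.drugs
        out.reactions += part.reactions
        out.indications += part.indications
        out.therapies += part.therapies
        out.outcomes += part.outcomes
    return out


def cohort_of(db: Database, drug="aspirin"):
    clean = deduplicate(db)
    return select_cohort(clean, drug), clean
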